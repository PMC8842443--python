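"""Reading and writing the pipeline's on-disk formats.

Kymographs and B-scan cubes travel as grayscale TIFF with a JSON metadata
sidecar; markers, boundary truth and cohort tables as headed CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flux import CellMarkerSet, Kymograph
from .oct import BScan


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_kymograph(path, kymo: Kymograph, seed: "int | None" = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, kymo.image.astype(np.float32))
    meta = {
        "scan_rate_hz": kymo.scan_rate_hz,
        "pixel_pitch_um": kymo.pixel_pitch_um,
        "fov_deg": kymo.fov_deg,
        "t0_scan": kymo.t0_scan,
    }
    if seed is not None:
        meta["seed"] = seed
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_kymograph(path) -> Kymograph:
    path = Path(path)
    image = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return Kymograph(
        image=image,
        scan_rate_hz=meta["scan_rate_hz"],
        pixel_pitch_um=meta["pixel_pitch_um"],
        fov_deg=meta.get("fov_deg", 0.71),
        t0_scan=meta.get("t0_scan", 0),
    )


def write_markers(path, markers: CellMarkerSet) -> None:
    pd.DataFrame(
        {
            "scan_index": markers.scan_index,
            "space_px": markers.space_px,
            "grader_id": markers.grader_id,
        }
    ).to_csv(path, index=False)


def read_markers(path, **kwargs) -> CellMarkerSet:
    df = pd.read_csv(path)
    grader = str(df["grader_id"].iloc[0]) if len(df) else "unknown"
    return CellMarkerSet(
        df["scan_index"].to_numpy(float),
        df["space_px"].to_numpy(float),
        grader_id=grader,
        **kwargs,
    )


def write_bscan_cube(path, bscans: "list[BScan]") -> None:
    path = Path(path)
    stack = np.stack([b.image.astype(np.float32) for b in bscans])
    tifffile.imwrite(path, stack)
    _sidecar(path).write_text(
        json.dumps({"axial_pitch_um": bscans[0].axial_pitch_um})
    )


def read_bscan_cube(path) -> "list[BScan]":
    path = Path(path)
    stack = np.atleast_3d(tifffile.imread(path))
    if stack.ndim == 2:
        stack = stack[None]
    meta = json.loads(_sidecar(path).read_text())
    return [BScan(image=im, axial_pitch_um=meta["axial_pitch_um"]) for im in stack]


def write_boundary_truth(path, ilm: np.ndarray, rpe: np.ndarray) -> None:
    pd.DataFrame(
        {"column": np.arange(len(ilm)), "ilm_row": ilm, "rpe_row": rpe}
    ).to_csv(path, index=False)


def read_boundary_truth(path) -> "tuple[np.ndarray, np.ndarray]":
    df = pd.read_csv(path)
    return df["ilm_row"].to_numpy(float), df["rpe_row"].to_numpy(float)
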