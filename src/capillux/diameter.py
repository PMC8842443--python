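"""Capillary lumen diameter from RBC width in space-time images.

Cells traveling single file deform to fill the patent lumen, so the vertical
(spatial) extent of a dark RBC trace measures the inner lumen diameter.
Three boxed width measures (15-ms boxes) are averaged, converted to um with
an age-adjusted pixel pitch (the growing mouse eye magnifies the retinal
image), and corrected for the angle between the scan line and the vessel by
cos(angle).  Vessels below 7 um qualify as capillaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .flux import CellMarkerSet, Kymograph

__all__ = [
    "DiameterMeasurement",
    "MagnificationTable",
    "mean_rbc_width",
    "pixel_pitch_for_age",
    "correct_diameter",
    "classify_capillary",
    "measure_rbc_widths",
    "diameter_from_widths",
]

#: Placeholder single-row calibration (um of retina per degree of scan angle).
#: Synthetic fixtures always carry their own pixel pitch; real analyses must
#: supply the instrument's age-resolved calibration table.
DEFAULT_UM_PER_DEGREE = 34.0


@dataclass
class MagnificationTable:
    """Age-resolved retinal magnification: (age_weeks, um_per_degree) rows."""

    age_weeks: np.ndarray
    um_per_degree: np.ndarray

    def __post_init__(self) -> None:
        self.age_weeks = np.atleast_1d(np.asarray(self.age_weeks, float))
        self.um_per_degree = np.atleast_1d(np.asarray(self.um_per_degree, float))
        if self.age_weeks.size == 0:
            raise ValueError("magnification table must not be empty")
        if self.age_weeks.shape != self.um_per_degree.shape:
            raise ValueError("table columns must have equal length")
        if np.any(np.diff(self.age_weeks) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.um_per_degree <= 0):
            raise ValueError("all scales must be positive")

    @classmethod
    def constant(cls, um_per_degree: float = DEFAULT_UM_PER_DEGREE):
        return cls(np.asarray([0.0]), np.asarray([um_per_degree]))

    @classmethod
    def from_csv(cls, path) -> "MagnificationTable":
        df = pd.read_csv(path)
        return cls(df["age_weeks"].to_numpy(), df["um_per_degree"].to_numpy())


@dataclass
class DiameterMeasurement:
    """One capillary's diameter determination."""

    widths_px: tuple[float, float, float]
    angle_deg: float
    age_weeks: float
    pixel_pitch_um: float
    diameter_um: float
    box_width_ms: float = 15.0


def mean_rbc_width(widths_px) -> float:
    """Average of exactly three manual (or boxed) RBC width measures in px."""
    widths = np.atleast_1d(np.asarray(widths_px, dtype=float))
    if widths.size != 3:
        raise ValueError("exactly 3 width measures are required")
    if not np.all(np.isfinite(widths)) or np.any(widths <= 0):
        raise ValueError("width measures must be finite and positive")
    return float(widths.mean())


def pixel_pitch_for_age(
    age_weeks: float,
    table: MagnificationTable,
    fov_deg: float,
    n_px: int,
) -> float:
    """Age-adjusted pixel pitch (um/px) via linear interpolation of the table.

    Ages outside the table range clamp to the nearest row.  The pitch is
    ``interp(age) * fov_deg / n_px``.
    """
    if fov_deg <= 0 or n_px <= 0:
        raise ValueError("fov_deg and n_px must be positive")
    scale = float(np.interp(age_weeks, table.age_weeks, table.um_per_degree))
    return scale * fov_deg / n_px


def correct_diameter(width_um: float, angle_deg: float) -> float:
    """Angle-correct an apparent width: diameter = width * cos(angle).

    The scan line crosses the vessel at ``angle_deg`` from orthogonal; at 90
    degrees the line runs parallel to the vessel and the width is
    unmeasurable.
    """
    if not (0 <= angle_deg < 90):
        raise ValueError("angle_deg must lie in [0, 90)")
    return width_um * math.cos(math.radians(angle_deg))


def classify_capillary(diameter_um: float) -> bool:
    """True iff the vessel qualifies as a capillary (diameter < 7 um, strict)."""
    if diameter_um <= 0:
        raise ValueError("diameter_um must be positive")
    return diameter_um < 7.0


def measure_rbc_widths(
    kymo: Kymograph,
    markers: CellMarkerSet,
    box_width_ms: float = 15.0,
    n_boxes: int = 3,
) -> np.ndarray:
    """Automated boxed width measurement on simulator fixtures.

    Boxes of ``box_width_ms`` are placed on the ``n_boxes`` temporally
    earliest non-overlapping cells; within each box the width is the full
    vertical extent of the thresholded dark trace (max - min occupied row
    + 1).  Stalled scans (no markers) yield no diameter, mirroring the
    requirement that an RBC be present.
    """
    if len(markers) == 0:
        raise ValueError("no cells available: stalled scans yield no diameter")
    half = 0.5 * box_width_ms / 1000.0 * kymo.scan_rate_hz
    chosen: list[float] = []
    for s in markers.scan_index:
        if all(abs(s - prev) >= 2 * half for prev in chosen):
            chosen.append(float(s))
        if len(chosen) == n_boxes:
            break
    if len(chosen) < n_boxes:
        raise ValueError(
            f"only {len(chosen)} non-overlapping cells available, need {n_boxes}"
        )
    widths = []
    for s in chosen:
        lo = max(0, int(round(s - half)))
        hi = min(kymo.n_scans, int(round(s + half)))
        box = kymo.image[:, lo:hi].astype(float)
        inverted = box.max() - box
        thr = threshold_otsu(inverted) if np.ptp(inverted) > 0 else np.inf
        occupied = np.nonzero((inverted > thr).any(axis=1))[0]
        if occupied.size == 0:
            raise ValueError("no dark trace found inside a measurement box")
        widths.append(float(occupied.max() - occupied.min() + 1))
    return np.asarray(widths)


def diameter_from_widths(
    widths_px,
    pixel_pitch_um: float,
    angle_deg: float,
    age_weeks: float = 0.0,
) -> DiameterMeasurement:
    """Combine three widths into an angle-corrected lumen diameter in um."""
    mean_px = mean_rbc_width(widths_px)
    width_um = mean_px * pixel_pitch_um
    diam = correct_diameter(width_um, angle_deg)
    w = tuple(float(x) for x in np.atleast_1d(np.asarray(widths_px, float)))
    return DiameterMeasurement(
        widths_px=w,  # type: ignore[arg-type]
        angle_deg=angle_deg,
        age_weeks=age_weeks,
        pixel_pitch_um=pixel_pitch_um,
        diameter_um=diam,
    )
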