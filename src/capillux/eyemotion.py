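"""Eye displacement and velocity from 1-D line-scan registration.

Because the scanner holds one line across the vessel, residual eye motion
along that line shifts the whole spatial profile.  Blocks of scans are
averaged into 1-D profiles and registered to the first block by maximizing
cross-correlation with parabolic sub-pixel refinement; the measured motion
is thus confined to the axis orthogonal to flow.  Velocity is the first
difference of displacement times the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .flux import Kymograph

__all__ = [
    "EyeMotionTrace",
    "register_profiles",
    "register_linescan",
    "blocks_to_scans",
    "eye_velocity",
    "eye_motion_trace",
]


@dataclass
class EyeMotionTrace:
    """Mean-zeroed displacement and derived velocity series."""

    block_scans: int
    block_center_scan: np.ndarray
    displacement_block_um: np.ndarray     # per-block, mean-zeroed
    displacement_um: np.ndarray           # per-scan interpolation, mean-zeroed
    velocity_um_s: np.ndarray             # per-scan
    flat_blocks: np.ndarray = field(default_factory=lambda: np.empty(0, bool))


def register_profiles(
    reference: np.ndarray,
    moving: np.ndarray,
    max_shift_px: "int | None" = None,
) -> tuple[float, bool]:
    """Shift of ``moving`` relative to ``reference`` in pixels.

    Positive means the moving profile is displaced toward higher row index.
    Cross-correlation of mean-subtracted profiles with parabolic sub-pixel
    peak interpolation.  A flat (zero-variance) profile cannot be registered
    and reports shift 0 with the flat flag set.
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        return 0.0, True
    ref = ref - ref.mean()
    mov = mov - mov.mean()
    corr = signal.correlate(mov, ref, mode="full")
    lags = np.arange(-(ref.size - 1), ref.size)
    if max_shift_px is not None:
        sel = np.abs(lags) <= max_shift_px
        corr, lags = corr[sel], lags[sel]
    k = int(np.argmax(corr))
    shift = float(lags[k])
    if 0 < k < corr.size - 1:
        denom = corr[k - 1] - 2 * corr[k] + corr[k + 1]
        if denom != 0:
            shift += 0.5 * (corr[k - 1] - corr[k + 1]) / denom
    return shift, False


def register_linescan(
    kymo: Kymograph,
    block_scans: int = 16,
    max_shift_px: "int | None" = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block displacement of the spatial profile, in pixels.

    Each block of ``block_scans`` columns is averaged into one profile and
    registered to the first block.  Returns ``(block_center_scan, shift_px,
    flat_flags)``.
    """
    if block_scans < 1:
        raise ValueError("block_scans must be >= 1")
    n_blocks = kymo.n_scans // block_scans
    if n_blocks < 2:
        raise ValueError("kymograph must contain at least 2 blocks")
    if max_shift_px is None:
        max_shift_px = kymo.n_space_px // 4
    cols = n_blocks * block_scans
    profiles = (
        kymo.image[:, :cols]
        .reshape(kymo.n_space_px, n_blocks, block_scans)
        .mean(axis=2)
    )
    ref = profiles[:, 0]
    shifts = np.zeros(n_blocks)
    flats = np.zeros(n_blocks, dtype=bool)
    for b in range(n_blocks):
        shifts[b], flats[b] = register_profiles(
            ref, profiles[:, b], max_shift_px=max_shift_px
        )
    centers = (np.arange(n_blocks) + 0.5) * block_scans
    return centers, shifts, flats


def blocks_to_scans(
    block_center_scan: np.ndarray, shifts: np.ndarray, n_scans: int
) -> np.ndarray:
    """Linear interpolation of per-block shifts to a per-scan series."""
    return np.interp(np.arange(n_scans), block_center_scan, shifts)


def eye_velocity(displacement_um: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Velocity (um/s) as first-differenced displacement times the rate.

    The study's velocity formula (displacement x scanning rate) reads the
    displacement as the per-sample increment, which first differencing
    supplies; the first element is 0.  For per-block displacement pass the
    block rate (scan rate / block_scans).
    """
    d = np.atleast_1d(np.asarray(displacement_um, dtype=float))
    v = np.zeros_like(d)
    if d.size > 1:
        v[1:] = np.diff(d) * sample_rate_hz
    return v


def eye_motion_trace(
    kymo: Kymograph,
    block_scans: int = 16,
    max_shift_px: "int | None" = None,
) -> EyeMotionTrace:
    """Full pipeline: register, convert to um, zero the mean, differentiate."""
    centers, shifts, flats = register_linescan(
        kymo, block_scans=block_scans, max_shift_px=max_shift_px
    )
    disp_block = shifts * kymo.pixel_pitch_um
    disp_block = disp_block - disp_block.mean()  # average displacement set to 0
    disp_scan = blocks_to_scans(centers, disp_block, kymo.n_scans)
    disp_scan = disp_scan - disp_scan.mean()
    vel = eye_velocity(disp_scan, kymo.scan_rate_hz)
    return EyeMotionTrace(
        block_scans=block_scans,
        block_center_scan=centers,
        displacement_block_um=disp_block,
        displacement_um=disp_scan,
        velocity_um_s=vel,
        flat_blocks=flats,
    )
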