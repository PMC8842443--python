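"""Synthetic study data with known ground truth.

Three generators emulate the study's acquisition so that every downstream
stage is testable without any real recordings:

* :func:`simulate_kymograph` — a space-time line scan of a single-file
  capillary at the scanner geometry (15 450 scans/s, 0.71 deg field of view,
  20-s capture), with cardiac-modulated RBC arrivals, lumen/vessel-angle
  geometry, eye motion and sensor noise, plus ground-truth cell markers.
* :func:`simulate_bscan` — an OCT B-scan as a piecewise-constant axial
  intensity model (dark vitreous, bright retina, brighter RPE band, dark
  choroid) with multiplicative speckle, plus the true ILM and OS–RPE rows.
* :func:`simulate_cohort` — longitudinal glucose/weight/flux/diameter/
  thickness tables for a euglycemic and a hyperglycemic group of mice,
  parameterized directly from the study's printed population statistics.

Arrival model
-------------
Cell arrivals follow a cardiac-modulated rate
``lambda(t) = mean_flux * (1 + depth * sin(2 pi f_cardiac t))``.  Because
cells travel single file, two cells cannot occupy the imaging beam at once,
and observed capillary traffic is far more regular than a Poisson stream:
by default the gap after each cell is the dead time ``tau`` (the RBC dwell
time) plus a gamma variate of shape ``gamma_shape`` whose mean is chosen so
the conditional mean gap equals ``1 / lambda(t)``.  This keeps the long-run
rate equal to ``lambda`` while enforcing the physical minimum spacing and
the sub-Poisson regularity of nose-to-tail flow.
``enforce_single_file=False`` gives the plain inhomogeneous Poisson process
instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .flux import DEFAULT_SCAN_RATE_HZ, RBC_LENGTH_UM, CellMarkerSet, Kymograph
from .oct import BScan

__all__ = [
    "EyeMotionParams",
    "KymoSimParams",
    "OctSimParams",
    "CohortSimParams",
    "CohortTable",
    "simulate_arrival_times",
    "render_kymograph",
    "simulate_kymograph",
    "simulate_bscan",
    "simulate_oct_cube",
    "simulate_cohort",
]


@dataclass
class EyeMotionParams:
    """Residual eye motion along the scanned line.

    Modeled as a sinusoid (cardiac/respiratory component) plus linear drift.
    The study constrains eye speed only to be roughly two orders of magnitude
    below RBC speed; the defaults honor that separation (peak sinusoid
    velocity 2*pi*f*A ~ 15 um/s against RBC speeds of ~1450 um/s).
    """

    amplitude_um: float = 2.0
    freq_hz: float = 1.2
    drift_um_s: float = 0.3
    phase_rad: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("amplitude_um must be >= 0")

    def displacement_um(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        wave = self.amplitude_um * np.sin(
            2 * np.pi * self.freq_hz * t + self.phase_rad
        )
        drift = self.drift_um_s * (t - (t[-1] / 2 if t.size else 0.0))
        return wave + drift


@dataclass
class KymoSimParams:
    """Geometry and physiology of one simulated line-scan acquisition.

    Defaults reproduce the study conditions: 20-s captures at 15 450 scans/s
    over a 0.71 deg line, ~4.5 cardiac cycles per second, 7.25-um cells in a
    4.1-um lumen, mean flux near the observed population mean of ~100
    cells/s.
    """

    duration_s: float = 20.0
    scan_rate_hz: float = DEFAULT_SCAN_RATE_HZ
    n_space_px: int = 64
    pixel_pitch_um: float = 0.38
    mean_flux_cells_s: float = 100.0
    cardiac_freq_hz: float = 4.5
    cardiac_mod_depth: float = 0.2
    rbc_length_um: float = RBC_LENGTH_UM
    lumen_diameter_um: float = 4.1
    vessel_angle_deg: float = 0.0
    rbc_speed_um_s: float = 1100.0
    gamma_shape: float = 6.0
    stall: bool = False
    noise_sd: float = 0.02
    background: float = 1.0
    cell_depth: float = 0.55
    band_depth: float = 0.08
    eye_motion: EyeMotionParams = field(default_factory=EyeMotionParams)
    enforce_single_file: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.scan_rate_hz <= 2 * self.mean_flux_cells_s:
            raise ValueError(
                "scan_rate_hz must exceed twice the mean flux (Nyquist)"
            )
        if not (0 <= self.cardiac_mod_depth < 1):
            raise ValueError("cardiac_mod_depth must lie in [0, 1)")
        if self.lumen_diameter_um >= 7:
            raise ValueError("capillaries are defined as lumen < 7 um")
        if not (0 <= self.vessel_angle_deg < 90):
            raise ValueError("vessel_angle_deg must lie in [0, 90)")
        if self.rbc_speed_um_s <= 0:
            raise ValueError("rbc_speed_um_s must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.enforce_single_file and self.mean_flux_cells_s > 0:
            peak = self.mean_flux_cells_s * (1 + self.cardiac_mod_depth)
            if peak * self.dwell_s >= 1.0:
                raise ValueError(
                    "peak flux times dwell time must stay below 1 for "
                    "single-file flow; raise rbc_speed_um_s or lower flux"
                )

    @property
    def dwell_scans(self) -> int:
        """Scans a cell occupies the beam: round(L / v * rate), >= 1."""
        return max(
            1,
            int(round(self.rbc_length_um / self.rbc_speed_um_s * self.scan_rate_hz)),
        )

    @property
    def dwell_s(self) -> float:
        return self.dwell_scans / self.scan_rate_hz

    @property
    def n_scans(self) -> int:
        return int(round(self.duration_s * self.scan_rate_hz))

    @property
    def cell_extent_px(self) -> float:
        """Vertical (spatial) cell extent in pixels, angle-corrected.

        The line scan crosses the vessel at ``vessel_angle_deg`` from
        orthogonal, so the apparent width is the lumen divided by
        cos(angle).
        """
        cos = math.cos(math.radians(self.vessel_angle_deg))
        return self.lumen_diameter_um / (self.pixel_pitch_um * cos)


def simulate_arrival_times(params: KymoSimParams) -> np.ndarray:
    """Draw RBC arrival times (fractional scan indices) for one recording.

    Sorted, within ``[0, n_scans)``, reproducible under a fixed seed.  See
    the module docstring for the arrival model.
    """
    params.validate()
    lam0 = params.mean_flux_cells_s
    if lam0 == 0:
        return np.empty(0)
    depth = params.cardiac_mod_depth
    f = params.cardiac_freq_hz
    rng = np.random.default_rng(params.seed)
    duration = params.duration_s

    def lam(t: float) -> float:
        return lam0 * (1.0 + depth * math.sin(2 * math.pi * f * t))

    times: list[float] = []
    if not params.enforce_single_file:
        lam_max = lam0 * (1 + depth)
        t = 0.0
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t >= duration:
                break
            if rng.uniform() * lam_max <= lam(t):
                times.append(t)
    else:
        tau = params.dwell_s
        m = params.gamma_shape
        # gap after a cell at time t: tau + Gamma(m, theta(t)) with
        # conditional mean 1/lambda(t); modulation is slow relative to gaps
        t = 0.0
        first = True
        while True:
            rate = max(lam(t), 1e-12)
            theta = (1.0 / rate - tau) / m
            gap = tau + rng.gamma(m, theta)
            if first:
                # random phase within the first gap (no cell is pinned at t=0)
                gap *= rng.uniform()
                first = False
            t += gap
            if t >= duration:
                break
            times.append(t)
    return np.asarray(times) * params.scan_rate_hz


def render_kymograph(
    arrivals: np.ndarray, params: KymoSimParams
) -> tuple[Kymograph, CellMarkerSet]:
    """Render arrivals into a kymograph image plus ground-truth markers.

    Cells are dark ellipses on a bright background (phase-contrast inverse
    cell contrast): horizontal semi-extent = dwell scans, vertical extent =
    angle-corrected lumen width in pixels.  The vessel band is drawn slightly
    dark and shifted per scan by the eye-motion trace; Gaussian sensor noise
    is added last.  A stalled vessel renders a static dark cell and returns
    an empty marker set.
    """
    params.validate()
    arrivals = np.sort(np.atleast_1d(np.asarray(arrivals, dtype=float)))
    n_rows, n_cols = params.n_space_px, params.n_scans
    extent = params.cell_extent_px
    if extent > n_rows:
        raise ValueError("angle-corrected cell extent exceeds n_space_px")
    image = np.full((n_rows, n_cols), params.background, dtype=float)

    scan_t = np.arange(n_cols) / params.scan_rate_hz
    disp_px = params.eye_motion.displacement_um(scan_t) / params.pixel_pitch_um
    band_center = n_rows / 2.0 + disp_px

    # vessel band (the capillary lumen) is slightly darker than background
    rows = np.arange(n_rows)[:, None]
    half = extent / 2.0
    band_mask = np.abs(rows - band_center[None, :]) <= half
    image[band_mask] -= params.band_depth

    a_r = max((extent - 1) / 2.0 + 0.49, 0.5)
    a_c = max((params.dwell_scans - 1) / 2.0 + 0.49, 0.5)

    def draw_cell(center_col: float, center_row: float) -> None:
        c_lo = max(0, int(math.floor(center_col - a_c - 1)))
        c_hi = min(n_cols, int(math.ceil(center_col + a_c + 2)))
        r_lo = max(0, int(math.floor(center_row - a_r - 1)))
        r_hi = min(n_rows, int(math.ceil(center_row + a_r + 2)))
        if c_hi <= c_lo or r_hi <= r_lo:
            return
        rr = np.arange(r_lo, r_hi)[:, None]
        cc = np.arange(c_lo, c_hi)[None, :]
        inside = ((rr - center_row) / a_r) ** 2 + ((cc - center_col) / a_c) ** 2 <= 1.0
        image[r_lo:r_hi, c_lo:c_hi][inside] = (
            params.background - params.band_depth - params.cell_depth
        )

    marker_scan: list[float] = []
    marker_space: list[float] = []
    if params.stall:
        row = float(band_center[0])
        for c in range(0, n_cols, max(1, int(2 * a_c))):
            draw_cell(c, row)
        image[band_mask] = np.minimum(
            image[band_mask], params.background - params.band_depth
        )
        # stalled cell: one static dark band, zero passages
        stall_rows = np.abs(rows - band_center[None, :]) <= a_r
        image[stall_rows] = params.background - params.band_depth - params.cell_depth
    else:
        for s in arrivals:
            if not (0 <= s < n_cols):
                continue
            row = float(np.interp(s, np.arange(n_cols), band_center))
            draw_cell(s, row)
            marker_scan.append(float(s))
            marker_space.append(row)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed + 1)
        image += rng.normal(0.0, params.noise_sd, size=image.shape)

    kymo = Kymograph(
        image=image,
        scan_rate_hz=params.scan_rate_hz,
        pixel_pitch_um=params.pixel_pitch_um,
    )
    markers = CellMarkerSet(
        np.asarray(marker_scan), np.asarray(marker_space), n_scans=n_cols
    )
    return kymo, markers


def simulate_kymograph(
    params: KymoSimParams,
) -> tuple[Kymograph, CellMarkerSet, np.ndarray]:
    """Convenience wrapper: arrivals + render.  Returns (kymo, markers, arrivals)."""
    arrivals = (
        np.empty(0) if params.stall else simulate_arrival_times(params)
    )
    kymo, markers = render_kymograph(arrivals, params)
    return kymo, markers, arrivals


# ---------------------------------------------------------------------------
# OCT B-scan simulation


@dataclass
class OctSimParams:
    """Piecewise-constant axial model of a retinal B-scan.

    Intensities top to bottom: vitreous (dark), retina between the ILM and
    the OS–RPE boundary (bright), an RPE band (brightest), choroid (dark).
    Default geometry gives a 110-px retina at 2 um/px axial pitch = 220 um,
    near the euglycemic mean thickness.
    """

    n_cols: int = 200
    n_rows: int = 256
    axial_pitch_um: float = 2.0
    ilm_profile: np.ndarray | None = None
    rpe_profile: np.ndarray | None = None
    layer_contrast: float = 0.55
    rpe_band_px: int = 6
    speckle_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ilm_profile is None:
            self.ilm_profile = np.full(self.n_cols, 60.0)
        if self.rpe_profile is None:
            self.rpe_profile = np.asarray(self.ilm_profile, dtype=float) + 110.0
        self.ilm_profile = np.asarray(self.ilm_profile, dtype=float)
        self.rpe_profile = np.asarray(self.rpe_profile, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.ilm_profile.shape != (self.n_cols,) or self.rpe_profile.shape != (
            self.n_cols,
        ):
            raise ValueError("boundary profiles must have length n_cols")
        if np.any(self.ilm_profile <= 0) or np.any(
            self.rpe_profile >= self.n_rows
        ):
            raise ValueError("boundaries must lie strictly inside the image")
        if np.any(self.ilm_profile >= self.rpe_profile):
            raise ValueError("ILM must lie above the OS-RPE boundary everywhere")

    @property
    def thickness_true_um(self) -> np.ndarray:
        return (self.rpe_profile - self.ilm_profile) * self.axial_pitch_um


def simulate_bscan(params: OctSimParams) -> tuple[BScan, np.ndarray, np.ndarray]:
    """Render one B-scan; returns ``(bscan, ilm_rows, rpe_rows)``.

    Fractional boundary rows are rendered with linear partial-pixel mixing so
    sub-pixel ground truth remains meaningful.  Speckle is multiplicative
    Gaussian, clipped at zero.
    """
    params.validate()
    vitreous, retina, rpe_bright, choroid = (
        0.05,
        0.05 + params.layer_contrast,
        0.95,
        0.12,
    )
    rows = np.arange(params.n_rows, dtype=float)[:, None]
    ilm = params.ilm_profile[None, :]
    rpe = params.rpe_profile[None, :]
    rpe_end = rpe + params.rpe_band_px

    # fractional coverage of each region per pixel (anti-aliased boundaries)
    def frac_below(boundary: np.ndarray) -> np.ndarray:
        return np.clip(rows + 0.5 - boundary, 0.0, 1.0)

    f_ilm = frac_below(ilm)     # fraction of pixel below the ILM
    f_rpe = frac_below(rpe)     # fraction below the OS-RPE boundary
    f_end = frac_below(rpe_end)
    image = (
        vitreous * (1 - f_ilm)
        + retina * (f_ilm - f_rpe)
        + rpe_bright * (f_rpe - f_end)
        + choroid * f_end
    )
    if params.speckle_sd > 0:
        rng = np.random.default_rng(params.seed)
        image = image * (
            1.0 + params.speckle_sd * rng.standard_normal(image.shape)
        )
        image = np.clip(image, 0.0, None)
    bscan = BScan(image=image, axial_pitch_um=params.axial_pitch_um)
    return bscan, params.ilm_profile.copy(), params.rpe_profile.copy()


def simulate_oct_cube(
    params: OctSimParams, n_bscans: int = 8
) -> tuple[list[BScan], np.ndarray, np.ndarray]:
    """A cube of B-scans sharing geometry, each with independent speckle."""
    scans = []
    for k in range(n_bscans):
        p = OctSimParams(
            n_cols=params.n_cols,
            n_rows=params.n_rows,
            axial_pitch_um=params.axial_pitch_um,
            ilm_profile=params.ilm_profile.copy(),
            rpe_profile=params.rpe_profile.copy(),
            layer_contrast=params.layer_contrast,
            rpe_band_px=params.rpe_band_px,
            speckle_sd=params.speckle_sd,
            seed=params.seed + 1000 * (k + 1),
        )
        bscan, _, _ = simulate_bscan(p)
        scans.append(bscan)
    return scans, params.ilm_profile.copy(), params.rpe_profile.copy()


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CohortSimParams:
    """Population parameters for the two-group longitudinal cohort.

    Means and SDs default to the study's printed group statistics: glucose
    461.51 +/- 93.74 (hyperglycemic) vs 180.79 +/- 39.43 mg/dL (euglycemic)
    censored at the 600 mg/dL meter cap, flux 99.85 +/- 58.53 vs 102.77 +/-
    65.12 cells/s, lumen diameter 4.2 +/- 0.6 vs 4.1 +/- 0.5 um, thickness
    213.7 +/- 3.79 vs 221.06 +/- 5.79 um, week-to-week capillary flux CV of
    27% (hyperglycemic) and 32% (euglycemic), and a ~1.5% stall probability
    per capillary visit.
    """

    n_mice_per_group: int = 9
    weeks: tuple[int, ...] = tuple(range(3, 19))
    flux_weeks: tuple[int, ...] = (5, 7, 9, 11, 13, 15, 17)
    thickness_weeks: tuple[int, ...] = (4, 8, 12, 16, 20)
    n_capillaries_per_mouse: int = 10
    glucose_eu_mean_sd: tuple[float, float] = (180.79, 39.43)
    glucose_hy_mean_sd: tuple[float, float] = (461.51, 93.74)
    glucose_cap: float = 600.0
    hyper_cutoff: float = 250.0
    weight_eu_mean_sd: tuple[float, float] = (24.80, 3.87)
    weight_hy_mean_sd: tuple[float, float] = (23.45, 3.53)
    flux_mean_sd_eu: tuple[float, float] = (102.77, 65.12)
    flux_mean_sd_hy: tuple[float, float] = (99.85, 58.53)
    diam_mean_sd_eu: tuple[float, float] = (4.1, 0.5)
    diam_mean_sd_hy: tuple[float, float] = (4.2, 0.6)
    diam_range: tuple[float, float] = (2.8, 7.0)
    week_to_week_cv_eu: float = 0.32
    week_to_week_cv_hy: float = 0.27
    flux_diameter_slope: float = 45.0  # cells/s per um, weak positive coupling
    stall_prob: float = 0.015
    thickness_mean_sd_eu: tuple[float, float] = (221.06, 5.79)
    thickness_mean_sd_hy: tuple[float, float] = (213.7, 3.79)
    qi_probs: tuple[float, ...] = (0.01, 0.03, 0.20, 0.38, 0.38)
    seed: int = 0

    def __post_init__(self) -> None:
        for pair in (
            self.glucose_eu_mean_sd,
            self.glucose_hy_mean_sd,
            self.weight_eu_mean_sd,
            self.weight_hy_mean_sd,
            self.flux_mean_sd_eu,
            self.flux_mean_sd_hy,
            self.diam_mean_sd_eu,
            self.diam_mean_sd_hy,
            self.thickness_mean_sd_eu,
            self.thickness_mean_sd_hy,
        ):
            if pair[1] < 0:
                raise ValueError("all SDs must be >= 0")
        if not (0 <= self.stall_prob <= 1):
            raise ValueError("stall_prob must lie in [0, 1]")
        if abs(sum(self.qi_probs) - 1.0) > 1e-9 or len(self.qi_probs) != 5:
            raise ValueError("qi_probs must be 5 probabilities summing to 1")


@dataclass
class CohortTable:
    """Longitudinal cohort tables.

    ``mice``: one row per mouse-week (glucose, weight);
    ``vessels``: one row per capillary visit (flux, diameter, QI, stall);
    ``thickness``: one row per OCT session.
    """

    mice: pd.DataFrame
    vessels: pd.DataFrame
    thickness: pd.DataFrame


def _truncated_normal(
    rng: np.random.Generator,
    target_mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
    match_mean: bool = True,
) -> np.ndarray:
    """Truncated-normal draws whose post-truncation mean equals the target.

    The location parameter is shifted (solved numerically) so that truncation
    to ``[lo, hi]`` does not bias the requested mean; with ``match_mean``
    False the raw location is the target mean.
    """
    if sd == 0:
        return np.full(size, float(np.clip(target_mean, lo, hi)))

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))

    mu = target_mean
    if match_mean and (trunc_mean(target_mean) != target_mean):
        lo_b = target_mean - 6 * sd
        hi_b = target_mean + 6 * sd
        try:
            mu = optimize.brentq(
                lambda m: trunc_mean(m) - target_mean, lo_b, hi_b, xtol=1e-8
            )
        except ValueError:
            mu = target_mean
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def simulate_cohort(params: CohortSimParams) -> CohortTable:
    """Generate the full longitudinal cohort with known group truth.

    Hyperglycemic glucose is censored at the meter cap (600 mg/dL) and drawn
    above the 250 mg/dL cutoff from week 5 onward, so the designation rule
    holds by construction.  Capillary flux combines a per-capillary baseline
    (truncated at zero) with multiplicative week-to-week variability at the
    printed CV; the between-capillary SD is derived so the marginal SD
    matches the printed population SD.  Stalls occur independently per visit
    at ``stall_prob`` and record a flux of exactly zero.
    """
    rng = np.random.default_rng(params.seed)
    mice_rows = []
    vessel_rows = []
    thick_rows = []
    groups = (
        ("euglycemic", params.glucose_eu_mean_sd, params.weight_eu_mean_sd,
         params.flux_mean_sd_eu, params.diam_mean_sd_eu,
         params.week_to_week_cv_eu, params.thickness_mean_sd_eu),
        ("hyperglycemic", params.glucose_hy_mean_sd, params.weight_hy_mean_sd,
         params.flux_mean_sd_hy, params.diam_mean_sd_hy,
         params.week_to_week_cv_hy, params.thickness_mean_sd_hy),
    )
    for group, glu, wt, flux_ms, diam_ms, cv, thick_ms in groups:
        tag = "eu" if group == "euglycemic" else "hy"
        # residual between-capillary SD such that the marginal SD matches the
        # printed one after the diameter coupling and week-to-week CV
        flux_mean, flux_sd = flux_ms
        within_var = (cv * flux_mean) ** 2
        diam_var = params.flux_diameter_slope**2 * diam_ms[1] ** 2
        between_sd = math.sqrt(max(flux_sd**2 - within_var - diam_var, 1.0))
        for m in range(params.n_mice_per_group):
            mouse_id = f"{tag}{m + 1:02d}"
            for week in params.weeks:
                if group == "hyperglycemic":
                    if week >= 5:
                        # truncated below the cutoff (designation holds by
                        # construction), censored at the meter cap
                        raw = _truncated_normal(
                            rng, glu[0], glu[1],
                            params.hyper_cutoff + 1e-9, np.inf,
                            1, match_mean=False,
                        )[0]
                        g = float(min(raw, params.glucose_cap))
                    else:
                        # rising phase before sustained hyperglycemia
                        g = float(
                            np.clip(rng.normal(250.0, 60.0), 0, params.glucose_cap)
                        )
                else:
                    g = float(np.clip(rng.normal(*glu), 0, params.glucose_cap))
                w = float(max(rng.normal(*wt), 1.0))
                mice_rows.append(
                    dict(mouse_id=mouse_id, group=group, week=week,
                         glucose_mgdl=g, weight_g=w)
                )
            cap_diam = _truncated_normal(
                rng, diam_ms[0], diam_ms[1],
                params.diam_range[0], params.diam_range[1] - 0.01,
                params.n_capillaries_per_mouse,
            )
            cap_base_flux = _truncated_normal(
                rng, flux_mean, between_sd, 0.0, np.inf,
                params.n_capillaries_per_mouse,
            ) + params.flux_diameter_slope * (cap_diam - diam_ms[0])
            cap_base_flux = np.clip(cap_base_flux, 0.5, None)
            for c in range(params.n_capillaries_per_mouse):
                cap_id = f"{mouse_id}-c{c + 1:02d}"
                for week in params.flux_weeks:
                    stalled = bool(rng.uniform() < params.stall_prob)
                    if stalled:
                        flux = 0.0
                    else:
                        flux = float(
                            max(cap_base_flux[c] * (1.0 + cv * rng.standard_normal()), 0.5)
                        )
                    diam = float(
                        np.clip(
                            cap_diam[c] + rng.normal(0, 0.05),
                            params.diam_range[0],
                            params.diam_range[1] - 1e-6,
                        )
                    )
                    qi = int(rng.choice(5, p=params.qi_probs)) + 1
                    vessel_rows.append(
                        dict(mouse_id=mouse_id, group=group,
                             capillary_id=cap_id, week=week,
                             flux_cells_s=flux, diameter_um=diam,
                             quality_index=qi, stalled=stalled)
                    )
            for week in params.thickness_weeks:
                thick_rows.append(
                    dict(mouse_id=mouse_id, group=group, week=week,
                         thickness_um=float(rng.normal(*thick_ms)))
                )
    return CohortTable(
        mice=pd.DataFrame(mice_rows),
        vessels=pd.DataFrame(vessel_rows),
        thickness=pd.DataFrame(thick_rows),
    )
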