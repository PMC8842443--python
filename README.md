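# capillux

Quantification of retinal capillary hemodynamics and retinal thickness from
in-vivo mouse imaging: red blood cell (RBC) flux, velocity and stalls from
high-speed line-scan (kymograph) recordings of single-file capillaries,
capillary lumen diameter from deformed-RBC widths, residual eye motion by
1-D registration, total retinal thickness by graph shortest-path OCT layer
segmentation, and the cohort statistics used to compare hyperglycemic and
euglycemic animals longitudinally.

The package is aimed at researchers analyzing adaptive-optics scanning
light ophthalmoscope (AOSLO) point-scan recordings and OCT volumes of the
rodent retina, and at anyone who needs a tested, reproducible reference
implementation of these measurements.  A first-class synthetic-data module
generates all three input kinds (kymographs, B-scans, cohort tables) with
known ground truth, so the entire pipeline is verifiable without any
animal data.

## The measurements

For a line scan captured at scan rate *f* (default 15 450 scans/s) across a
capillary, with grader-marked cell centroids at scan indices *s₁ < s₂ < …*:

- **per-second flux** — cell count per 1-s window (cells/s);
- **instantaneous flux** — `Flux_i = f / (s_{i+1} − s_i)`, placed at the
  pair midpoint;
- **instantaneous velocity** — `V_i = L / Δt_dwell` with the RBC length
  constrained to `L = 7.25 µm` by capillary rheology and `Δt_dwell` the
  time the cell occupies the beam;
- **stall** — zero cells in the analysis window;
- **lumen diameter** — mean of three boxed RBC width measures (15-ms
  boxes), converted with an age-adjusted pixel pitch and corrected by
  `cos(angle)` for the scan-line/vessel angle; vessels `< 7 µm` count as
  capillaries;
- **eye velocity** — first-differenced registered displacement × sampling
  rate.

Each OCT B-scan is treated as a graph: pixels are nodes, 8-neighbor edges
are weighted `2 − (g_a + g_b) + w_min` from the normalized axial gradient
`g`, and Dijkstra's shortest left-to-right path traces a boundary.  The
vitreous–ILM boundary is segmented first, then the OS–RPE boundary below
it; total retinal thickness is `(rpe − ilm) × axial pitch`, averaged per
imaging session.

The statistics layer implements hyperglycemia designation (two consecutive
weekly readings > 250 mg/dL, meter capped at 600 mg/dL), stall rates,
two-tailed unpaired Student's *t* tests, OLS regressions reported as
Pearson R², adjusted Fisher–Pearson skew, and Bland–Altman agreement
against the grader-mean reference with exact two-sided normal
tolerance-factor confidence intervals for the limits of agreement.

## Worked example

```sh
capillux demo --seed 1 --out demo-run
```

simulates a two-group cohort (9 mice/group), one 2-s kymograph and one OCT
B-scan, analyzes them end to end, and prints (abridged):

```
"euglycemic":    { "glucose_mean_mgdl": 176.31, "flux_mean_cells_s": 109.45,
                   "diameter_mean_um": 4.10, "stall_rate_pct": 1.47,
                   "thickness_mean_um": 220.93 }
"hyperglycemic": { "glucose_mean_mgdl": 442.70, "flux_mean_cells_s": 98.50,
                   "diameter_mean_um": 4.19, "stall_rate_pct": 0.81,
                   "thickness_mean_um": 214.66 }
"thickness_p": 3.6e-08
"flux_vs_diameter": { "slope_cells_s_per_um": 43.39, "r2": 0.157 }
"demo_kymograph": { "per_second_flux": [103.0, 99.0], "n_markers": 202 }
"demo_bscan": { "mean_thickness_um": 220.1, "true_thickness_um": 220.0 }
```

Reading: the hyperglycemic group carries ~2.5× the blood glucose of
controls yet shows similar capillary flux, diameter and stall rate; its
retina is ~6–7 µm thinner (*p* ≪ 0.001); flux correlates only weakly with
lumen diameter; and the segmented B-scan thickness matches the generator's
ground truth to a tenth of a micron.  Library usage mirrors the CLI:
`simulate_kymograph`, `flux_per_second`, `instantaneous_flux`,
`segment_bscan`, `bland_altman`, `simulate_cohort`, … (see module
docstrings).

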