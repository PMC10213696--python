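# Methods

## The measurement model

The analysis rests on one empirical law: inside the region of interest
(ROI) spanned by the electrode array, the natural logarithm of the
number of adhered cells is linear in the electrode-averaged interfacial
capacitance change,

    ln N_m = α·ΔC_m + K,                      (log-linear calibration)

with α in 1/aF and K dimensionless. Treating the average capacitance
growth factor S_avg (aF/h) as the constant rate of change of ΔC_m turns
this into an exponential temporal model N(t) = A·e^{α·S_avg·t} with
A = e^K. That generalized form inherits the regression intercept, so
its t = 0 prediction is biased by any intercept error; it is kept as a
diagnostic only. The headline fit instead pins the exponential to the
measured counts at two times (boundary conditions N_0 at t_0, N_f at
t_n):

    N(t) = Γ·e^{α·S_avg·t} + β,
    Γ = (N_f − N_0)/(e^{α·S_avg·t_n} − e^{α·S_avg·t_0}),
    β = N_0 − Γ·e^{α·S_avg·t_0}.

α and S_avg enter as measured constants; Γ and β are determined by the
boundary conditions in closed form, never refit. Model adequacy is
summarized by R² on the linear count scale and adjusted R² with k = 3
— k = 3 is kept as the field's reporting convention for this model
family even though Γ and β are not free regression parameters, so the
adjustment is conservative rather than statistically motivated. The
doubling time t_d solves N(t_0 + t_d) = 2N_0; it is reported as
undefined (null, `within_window=false`) whenever no positive root
exists or the root falls beyond the analysis window, with the
extrapolated root retained separately.

Key assumptions, inherited by everything downstream: α and K are
time-invariant over the window; ΔC_m grows at an approximately constant
rate S_avg; cell migration across the ROI boundary is negligible. The
30-h analysis window (default) reflects ROI saturation at longer times;
all data beyond it are truncated before any statistic is computed.

## Trend extraction and the growth-factor distribution

Each electrode's ΔC trace is zero-referenced at its first stored sample
(the stand-in for subtracting a pre-start capacitance measurement).
The electrode average is smoothed with a third-order Savitzky-Golay
filter whose window is the largest odd integer ≤ n−1 for n samples —
for the even n the rule was stated for, exactly n−1; for odd n, n−2 is
the minimal extension. A window that long makes the trend effectively a
global cubic fit; the window is config-overridable for exploration.
Edge samples are filled by the same local polynomial (`mode="interp"`).

The growth-factor distribution pools ordinary-least-squares slopes of
1-h segments stepped every 0.5 h (segments start at the window origin;
trailing partial segments are dropped; slopes are in aF/h, the
seconds→hours conversion happening exactly once). The default
"per-pixel" method SG-fits each electrode trace with the same window
rule and pools all segment slopes; "average-trace" uses only the
averaged trend, and "per-pixel-derivative" (pointwise SG first
derivatives) is exposed as a variant without any fidelity claim. S_avg
is the arithmetic mean of the pooled slopes and σ their sample standard
deviation — always from the raw slopes; the Freedman-Diaconis histogram
(capped at 200 bins for degenerate spreads) is cosmetic.

Because all segment slopes from one electrode derive from a single
near-global cubic, they are strongly dependent: the effective replicate
count for S_avg is the number of electrodes, not the number of pooled
slopes. The standard error of S_avg and the "significant growth" flag
(|z| > 2) therefore use σ/√n_electrodes. A z-test against the pooled
slope count would overstate precision by ~√58 and reject a true null
about half the time.

Normality of the pooled slopes is tested (Shapiro-Wilk up to 5000
slopes, D'Agostino K² beyond; a zero-variance sample gets the verdict
"degenerate") and reported only — the analysis proceeds under the
normality assumption regardless of the verdict.

## Cell counting

Frames are preprocessed by a percentile contrast stretch (1st–99th →
full dtype range; a constant frame passes unchanged) and unsharp
masking (σ = 2 px, amount 1). False-color rendering is a display
transform and is excluded from the quantitative path. The template is
the element-wise mean of odd-sided patches centered on user-designated
cells of a reference frame (in tests, on generator ground-truth
centers). Detection computes the ZNCC map at every valid position
(scikit-image's `match_template`), thresholds at 0.6, and applies
greedy non-maximum suppression in descending score order with exclusion
radius equal to the template half-size; score ties break by (row, col)
lexicographic order, making the detector fully deterministic. ZNCC
makes detection invariant to constant illumination shifts; a
zero-variance template is rejected. Coordinates are 0-based (row, col)
and the ROI rectangle is half-open — stated once, used everywhere. The
threshold, suppression radius and template size are config-exposed;
the defaults were chosen on the synthetic generator.

Counts are the detections whose centers fall inside the ROI. Pairing
counts with the trend uses nearest-timestamp matching within 150 s
(half the 5-min imaging cadence); unmatched and zero counts are dropped
with warnings, and fewer than three surviving pairs is an error. N_0
and N_f default to the first/last measured counts inside the window
(raw, not smoothed); a short median window (`boundary_frames`) is
available to damp counter jitter.

## The synthetic generator

`SimulationParams` holds the ground truth: trajectory
N(t) = Γ·e^{α·S_avg·t} + β with Γ = N_0 − β (defaults: N_0 = 400 cells,
β = 0, S_avg = 3.38 aF/h, α = ln2/(26·3.38) ≈ 0.0079 1/aF, i.e. a 26-h
doubling), 30 h duration, 29-s capacitance cadence, 5-min imaging.
K defaults to ln N_0 so the ideal ΔC is exactly zero at t = 0,
consistent with the zero-referencing rule; with β = 0 the ideal ΔC_m is
exactly linear with slope S_avg. Counts stay real-valued everywhere
except frame rendering, where they are rounded — recovery tests can
therefore close the loop exactly.

Electrode traces are (1 + g_e)·ΔC_m(t) + RW_e(t) + ε_e(t): gain
heterogeneity g_e ~ Normal(0, 4.66) **centered to zero mean across the
array**, a zero-start random walk with 1.2 aF per-sample steps, and
5 aF white noise. Centering the gains is a deliberate design choice: a
common-mode gain factor is unidentifiable — the log-linear calibration
absorbs it into α — so the generator fixes the array-average
sensitivity at nominal, which also makes the electrode-averaged trace
an exact copy of the ground-truth ΔC_m under gain noise alone. The
gain spread is large (slopes from −12 to +19 aF/h across electrodes,
including negative trends) because that is what the reference pooled
statistics imply: σ ≈ 16.57 aF/h against a mean of 3.38 aF/h puts
~40% of the slope mass below zero, i.e. electrodes that individually
*lose* capacitance while the array average grows. Physically this
reads as strongly uneven local cell coverage. The three noise
magnitudes were calibrated once, jointly, so that the standard
analysis applied to generated data reproduces the reference pooled
slope distribution (mean ≈ 3.38, σ ≈ 16.57 aF/h) across seeds; the
split between gain, walk and white components is not uniquely
determined by those two targets, and the chosen split favors gain
(across-electrode) spread because random-walk spread of the same
magnitude would destroy the ln N/ΔC correlation that the reference
conditions simultaneously require. A useful structural fact, exploited
by the tests: trend errors inflate Ŝ_avg and deflate α̂ (or vice versa)
multiplicatively, so the product α·S_avg — the model's rate — is far
more accurate than either factor.

Micrographs are 8-bit frames (1 µm/px by default) with round(N(t))
isotropic Gaussian blobs (σ = 2 px, peak 120 over a background of 30
with 8 gray levels of Gaussian noise, SNR 15) placed uniformly inside
the ROI with an enforced 11-px minimum center separation via
grid-accelerated rejection sampling (an infeasible request raises a
placement error naming the frame). Optional distractor blobs outside
the ROI exercise the ROI discipline of the counter. Presets:
`paper_like`, `control` (constant N, sensor noise only — the
medium-only experiment), `noiseless` (all noise off). All randomness
flows from a single seed through separate capacitance/imaging streams;
identical seeds give byte-identical CSV and PNG output.

What the generator does **not** emulate: macrophage morphology and
phase-contrast texture (cells are Gaussian spots), cell migration and
motility, electrode-level physics (capacitance-to-frequency
transduction), focus drift, and any time variation of α or K. Passing
closed-loop tests therefore demonstrate the correctness and calibration
of the *analysis*, not robustness to real-microscopy nuisances.

## Numerical choices and problem sizes

* Alignment tolerance 150 s; the 29-s and 300-s grids are
  incommensurate, so pairing carries up to ±14.5 s of jitter — at the
  default signal scale this perturbs α by ~10⁻⁴ relative, which is why
  the exact-recovery tests pair on the capacitance grid directly.
* Boundary-condition residuals of the closed-form Γ, β are ~10⁻¹⁴
  relative; the degenerate cases (α·S_avg = 0, t_n = t_0, or a rate too
  small for e^{α·S·t_0} ≠ e^{α·S·t_n} in floats) raise errors, and the
  pipeline reports such runs with null model statistics instead of
  crashing (relevant for medium-only controls, whose counts are
  constant and whose R² is undefined).
* CSV floats are written with 12 significant digits (round-trip to
  1e-9); the JSON report is canonical (sorted keys, stable float
  formatting, NaN → null plus a warning entry).
* Replicate studies use 20 seeds of the full 30-h, 16-electrode,
  29-s-cadence configuration, counting a 30-min subset of the rendered
  frames (61 frames; analyses of this kind typically count a subset of
  the acquired images). Counter accuracy uses 50 frames of 100–350
  separated blobs.

## Known limitations

* With 16 electrodes and a near-global SG window, S_avg carries an
  irreducible sampling scatter of σ_across/4; recovering it to better
  than ~0.5 aF/h per run is not possible under the calibrated
  heterogeneity, and only the across-seed median is tested.
* The counter is a single-template matcher: it assumes one dominant
  cell appearance and separated cells. Overlapping or touching cells
  undercount; no segmentation or tracking is attempted.
* t_d describes the modeled population inside the ROI only; it is not
  an estimate of the cell line's doubling time.
* The per-pixel/derivative variants and the average-trace method give
  different σ for the same data (different pooling units); comparisons
  should fix the method.
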