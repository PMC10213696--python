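"""Synthetic experiment generator.

Produces the three linked artifacts the analysis consumes — a
ground-truth exponential cell trajectory, per-electrode capacitance
traces tied to it through the log-linear law ``ln N = α·ΔC + K``, and a
stack of timestamped micrographs whose in-ROI blob count follows the
trajectory — so that every downstream stage can be tested closed-loop
against known truth.

Noise model for the capacitance traces: per-electrode multiplicative
gain heterogeneity, a per-electrode random walk, and white detector
noise.  The gains are drawn Normal(0, gain_sd) and then centered to
zero mean across the array: a common-mode gain factor is unidentifiable
(it is absorbed into α by the log-linear calibration), so the
array-average sensitivity is fixed at nominal, which also makes the
electrode-averaged trace an exact — not merely unbiased — copy of the
ground-truth ΔC_m under gain noise alone.

The ``paper_like`` preset is calibrated so that the pooled
segment-slope distribution produced by the standard analysis has mean
≈ 3.38 aF/h and standard deviation ≈ 16.57 aF/h, the reference values
for a healthy macrophage proliferation run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .counting import CellCountSeries, Micrograph, MicrographStack, ROI
from .trends import AverageTrace, CapacitanceSeries

__all__ = [
    "ArraySpec",
    "SimulationParams",
    "SimulationTruth",
    "SyntheticExperiment",
    "PlacementError",
    "paper_like",
    "control",
    "noiseless",
    "roi_for",
    "measured_counts",
    "simulate_trajectory",
    "simulate_capacitance",
    "render_micrographs",
    "simulate_experiment",
]

_CAP_STREAM = 1
_IMG_STREAM = 2


class PlacementError(RuntimeError):
    """Raised when a frame cannot fit the requested number of blobs."""


@dataclass(frozen=True)
class ArraySpec:
    """Geometry of the electrode array that defines the ROI.

    Defaults describe a 4 x 4 grid of 30 x 30 µm sensing electrodes at a
    196 x 186 µm spatial pitch.
    """

    n_rows: int = 4
    n_cols: int = 4
    pitch_um: tuple[float, float] = (196.0, 186.0)
    electrode_um: float = 30.0

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 1:
            raise ValueError("array must contain at least one electrode")
        if min(*self.pitch_um, self.electrode_um) <= 0:
            raise ValueError("all lengths must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def roi_extent_um(self) -> tuple[float, float]:
        """(height, width) of the rectangle spanned by the array, in µm."""
        return (
            (self.n_rows - 1) * self.pitch_um[0] + self.electrode_um,
            (self.n_cols - 1) * self.pitch_um[1] + self.electrode_um,
        )


@dataclass
class SimulationParams:
    """Ground truth and noise settings for one synthetic experiment.

    The trajectory is ``N(t) = Γ·exp(α·S_avg·t) + β`` with
    ``Γ = N0 - beta_true`` (t in hours); capacitance follows by
    inverting the log-linear law.  ``K_true=None`` derives the intercept
    as ``ln N0`` so that the ground-truth ΔC is exactly 0 at t=0,
    consistent with zero-referencing each electrode at its first sample.
    """

    alpha: float = math.log(2) / (26.0 * 3.38)  # 1/aF; doubling in 26 h at S=3.38
    S_avg_true: float = 3.38  # aF/h
    K_true: float | None = None
    N0: float = 400.0
    beta_true: float = 0.0
    duration_h: float = 30.0
    cap_dt_s: float = 29.0
    img_dt_s: float = 300.0
    electrode_gain_sd: float = 4.66
    rw_step_sd_aF: float = 1.2
    white_sd_aF: float = 5.0
    seed: int = 0
    control_mode: bool = False
    # imaging / rendering
    um_per_px: float = 1.0
    margin_px: int = 40
    blob_sigma_px: float = 2.0
    blob_peak: float = 120.0
    background_level: float = 30.0
    background_noise_sd: float = 8.0
    min_separation_px: float = 11.0
    n_distractors: int = 0

    def __post_init__(self) -> None:
        scalars = [
            self.alpha, self.S_avg_true, self.N0, self.beta_true,
            self.duration_h, self.cap_dt_s, self.img_dt_s,
        ]
        if not all(np.isfinite(scalars)):
            raise ValueError("non-finite simulation parameter")
        if self.duration_h <= 0 or self.cap_dt_s <= 0 or self.img_dt_s <= 0:
            raise ValueError("durations and cadences must be positive")
        if min(self.electrode_gain_sd, self.rw_step_sd_aF, self.white_sd_aF,
               self.background_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.N0 < 1:
            raise ValueError("N0 must be >= 1")
        if self.gamma_true <= 0:
            raise ValueError("N0 - beta_true must be positive")

    @property
    def gamma_true(self) -> float:
        return self.N0 - self.beta_true

    @property
    def rate_per_h(self) -> float:
        """The exponential rate α·S_avg (1/h)."""
        return self.alpha * self.S_avg_true

    @property
    def K(self) -> float:
        return math.log(self.N0) if self.K_true is None else self.K_true

    def cap_timestamps_s(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h * 3600.0 + 0.5, self.cap_dt_s)

    def img_timestamps_s(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h * 3600.0 + 0.5, self.img_dt_s)

    def trajectory_at(self, t_h: np.ndarray) -> np.ndarray:
        """Exact real-valued cell count at times given in hours."""
        t_h = np.asarray(t_h, dtype=float)
        if self.control_mode:
            return np.full_like(t_h, float(self.N0))
        return self.gamma_true * np.exp(self.rate_per_h * t_h) + self.beta_true


def paper_like(seed: int = 0, **overrides) -> SimulationParams:
    """Preset emulating a healthy proliferation run on the 16-electrode
    array: 29-s capacitance cadence, 5-min imaging, 30 h, noise
    calibrated to a pooled-slope distribution with mean ≈ 3.38 aF/h and
    sd ≈ 16.57 aF/h."""
    return SimulationParams(seed=seed, **overrides)


def control(seed: int = 0, **overrides) -> SimulationParams:
    """Medium-only control: constant trajectory, sensor noise only."""
    overrides.setdefault("N0", 150.0)
    return SimulationParams(seed=seed, control_mode=True, **overrides)


def noiseless(seed: int = 0, **overrides) -> SimulationParams:
    """All noise sources off; used for exact closed-loop recovery."""
    return SimulationParams(
        seed=seed,
        electrode_gain_sd=0.0,
        rw_step_sd_aF=0.0,
        white_sd_aF=0.0,
        background_noise_sd=0.0,
        **overrides,
    )


def roi_for(spec: ArraySpec, params: SimulationParams) -> ROI:
    """Pixel ROI covering the electrode-array extent, inset by the margin."""
    h_um, w_um = spec.roi_extent_um
    h_px = int(round(h_um / params.um_per_px))
    w_px = int(round(w_um / params.um_per_px))
    m = params.margin_px
    return ROI(m, m + h_px, m, m + w_px)


def frame_shape_for(spec: ArraySpec, params: SimulationParams) -> tuple[int, int]:
    roi = roi_for(spec, params)
    return (roi.row1 + params.margin_px, roi.col1 + params.margin_px)


def simulate_trajectory(params: SimulationParams) -> CellCountSeries:
    """Exact cell trajectory sampled at the imaging timestamps.

    Values are real-valued; rounding to integers happens only when
    frames are rendered.
    """
    t_s = params.img_timestamps_s()
    n = params.trajectory_at(t_s / 3600.0)
    return CellCountSeries(t_s, n)


def true_average_trace(params: SimulationParams) -> AverageTrace:
    """Ground-truth ΔC_m(t) = (ln N(t) - K)/α on the capacitance grid."""
    t_s = params.cap_timestamps_s()
    n = params.trajectory_at(t_s / 3600.0)
    if np.any(n <= 0):
        raise ValueError("trajectory must be strictly positive")
    return AverageTrace(t_s, (np.log(n) - params.K) / params.alpha)


def simulate_capacitance(
    params: SimulationParams,
    traj: CellCountSeries | None = None,
    n_electrodes: int = 16,
) -> CapacitanceSeries:
    """Per-electrode ΔC traces around the ground-truth average.

    Electrode e measures ``(1 + g_e)·ΔC_m(t) + RW_e(t) + ε_e(t)`` with
    centered gains g_e, a zero-start random walk RW and white noise ε;
    each trace is then re-referenced to its own first sample, so the
    stored ΔC at t=0 is exactly 0.  Deterministic for a fixed seed.
    """
    if traj is not None and np.any(np.asarray(traj.counts) <= 0):
        raise ValueError("trajectory must be strictly positive")
    ideal = true_average_trace(params)
    dcm = ideal.delta_c_aF
    n = dcm.size
    rng = np.random.default_rng([params.seed, _CAP_STREAM])
    gains = rng.normal(0.0, params.electrode_gain_sd, n_electrodes)
    if n_electrodes > 1 and params.electrode_gain_sd > 0:
        gains -= gains.mean()
    steps = rng.normal(0.0, params.rw_step_sd_aF, (n_electrodes, n - 1))
    walks = np.concatenate(
        [np.zeros((n_electrodes, 1)), np.cumsum(steps, axis=1)], axis=1
    )
    white = rng.normal(0.0, params.white_sd_aF, (n_electrodes, n))
    traces = (1.0 + gains)[:, None] * dcm[None, :] + walks + white
    traces -= traces[:, :1]  # first sample is each electrode's own baseline
    return CapacitanceSeries(ideal.timestamps_s, traces)


def _place_points(
    n: int,
    bounds: tuple[float, float, float, float],
    min_sep: float,
    rng: np.random.Generator,
    occupied: dict[tuple[int, int], list[tuple[float, float]]],
    exclude: ROI | None = None,
    max_tries_per_point: int = 500,
) -> np.ndarray:
    """Rejection-sample n points with a minimum pairwise separation.

    ``occupied`` is a shared coarse grid of already-placed points; new
    points are appended to it.  ``exclude`` rejects points inside a
    rectangle (used for out-of-ROI distractors).
    """
    r0, r1, c0, c1 = bounds
    cell = max(min_sep, 1.0)
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_per_point * max(n, 1)
    while len(pts) < n:
        if tries > budget:
            raise PlacementError(
                f"could not place {n} blobs at min separation {min_sep}"
            )
        tries += 1
        r = rng.uniform(r0, r1)
        c = rng.uniform(c0, c1)
        if exclude is not None and exclude.contains(r, c):
            continue
        gi, gj = int(r // cell), int(c // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for rr, cc in occupied.get((gi + di, gj + dj), ()):
                    if (rr - r) ** 2 + (cc - c) ** 2 < min_sep**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts.append((r, c))
            occupied.setdefault((gi, gj), []).append((r, c))
    return np.array(pts).reshape(n, 2)


def _render_frame(
    shape: tuple[int, int],
    centers: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.full(shape, params.background_level, dtype=float)
    if params.background_noise_sd > 0:
        img += rng.normal(0.0, params.background_noise_sd, shape)
    sig = params.blob_sigma_px
    rad = int(4 * sig) + 1
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    h, w = shape
    for r, c in centers:
        ri, ci = int(round(r)), int(round(c))
        fr, fc = r - ri, c - ci
        patch = params.blob_peak * np.exp(
            -(((yy - fr) ** 2 + (xx - fc) ** 2)) / (2.0 * sig * sig)
        )
        r0, r1 = max(0, ri - rad), min(h, ri + rad + 1)
        c0, c1 = max(0, ci - rad), min(w, ci + rad + 1)
        img[r0:r1, c0:c1] += patch[
            r0 - (ri - rad) : patch.shape[0] - ((ri + rad + 1) - r1),
            c0 - (ci - rad) : patch.shape[1] - ((ci + rad + 1) - c1),
        ]
    return np.clip(img, 0.0, 255.0).astype(np.uint8)


def render_micrographs(
    traj: CellCountSeries,
    spec: ArraySpec,
    params: SimulationParams,
) -> tuple[MicrographStack, list[np.ndarray]]:
    """Render one 8-bit frame per trajectory timestamp.

    Each frame contains ``round(N(t))`` Gaussian blobs placed uniformly
    inside the ROI (inset by the blob radius so every intensity peak
    lies strictly inside), with an enforced minimum center separation,
    plus optional distractor blobs outside the ROI, on a noisy constant
    background.  Returns the stack and the ground-truth in-ROI centers
    per frame.
    """
    roi = roi_for(spec, params)
    shape = frame_shape_for(spec, params)
    if roi.row1 > shape[0] or roi.col1 > shape[1]:
        raise ValueError("ROI does not fit inside the frame")
    rng = np.random.default_rng([params.seed, _IMG_STREAM])
    inset = math.ceil(params.blob_sigma_px) + 1
    inner = (roi.row0 + inset, roi.row1 - inset, roi.col0 + inset, roi.col1 - inset)
    edge = max(inset, 8)
    outer = (edge, shape[0] - edge, edge, shape[1] - edge)
    frames: list[Micrograph] = []
    truth: list[np.ndarray] = []
    for t_s, n_real in zip(traj.timestamps_s, traj.counts):
        n_cells = int(round(n_real))
        occupied: dict[tuple[int, int], list[tuple[float, float]]] = {}
        try:
            pts = _place_points(
                n_cells, inner, params.min_separation_px, rng, occupied
            )
            distract = _place_points(
                params.n_distractors, outer, params.min_separation_px, rng,
                occupied, exclude=roi,
            )
        except PlacementError as exc:
            raise PlacementError(f"frame at t={t_s:.0f} s: {exc}") from exc
        centers = np.vstack([pts, distract]) if len(distract) else pts
        frames.append(Micrograph(_render_frame(shape, centers, params, rng), t_s))
        truth.append(pts)
    return MicrographStack(frames), truth


def measured_counts(
    exp: "SyntheticExperiment",
    n_template_cells: int = 25,
    half_size: int = 5,
    threshold: float = 0.6,
    reference_frame: int = 0,
):
    """Count the rendered frames with a truth-derived template.

    Extracts the matching template from the ground-truth blob centers of
    a reference frame (the stand-in for the analyst clicking cells on a
    reference image) and runs the standard counter over the whole stack.
    """
    from . import counting as _c

    cfg = _c.MatchConfig(threshold=threshold)
    ref = _c.preprocess_image(exp.images[reference_frame], cfg)
    pts = exp.truth.centers[reference_frame]
    if len(pts) == 0:
        raise ValueError("reference frame has no ground-truth cells")
    centers = [(int(round(r)), int(round(c))) for r, c in pts[:n_template_cells]]
    tpl = _c.extract_template(ref, centers, half_size)
    return _c.count_series(exp.images, tpl, exp.roi, cfg)


@dataclass
class SimulationTruth:
    """Everything the generator knows that the analysis must recover."""

    params: SimulationParams
    trajectory: CellCountSeries
    delta_c_true: AverageTrace
    centers: list[np.ndarray]


@dataclass
class SyntheticExperiment:
    capacitance: CapacitanceSeries
    images: MicrographStack
    truth: SimulationTruth
    roi: ROI


def simulate_experiment(
    params: SimulationParams,
    spec: ArraySpec | None = None,
    render: bool = True,
    img_stride: int = 1,
    out_dir: str | None = None,
) -> SyntheticExperiment:
    """Generate a complete synthetic experiment.

    ``img_stride`` renders only every k-th imaging timestamp (the
    analysis typically counts a subset of the acquired frames);
    ``render=False`` skips frame rendering entirely and leaves an empty
    stack, for capacitance-only studies.  With ``out_dir`` set, the
    capacitance CSV and the image stack are also written to disk in the
    pipeline's file formats; output is identical for identical seeds.
    """
    spec = spec or ArraySpec()
    traj_full = simulate_trajectory(params)
    cap = simulate_capacitance(params, traj_full, n_electrodes=spec.n_electrodes)
    if img_stride > 1:
        traj = CellCountSeries(
            traj_full.timestamps_s[::img_stride], traj_full.counts[::img_stride]
        )
    else:
        traj = traj_full
    if render:
        stack, centers = render_micrographs(traj, spec, params)
    else:
        stack, centers = MicrographStack([]), []
    truth = SimulationTruth(
        params=replace(params),
        trajectory=traj,
        delta_c_true=true_average_trace(params),
        centers=centers,
    )
    exp = SyntheticExperiment(cap, stack, truth, roi_for(spec, params))
    if out_dir is not None:
        from . import io as _io

        _io.write_experiment(exp, out_dir)
    return exp
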