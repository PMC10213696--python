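"""Capacitance trend extraction and the growth-factor distribution.

The sensor record is a per-electrode time series of capacitance changes
(ΔC, in attofarads) sampled on a shared grid.  The analysis averages the
electrodes, smooths the average with a third-order Savitzky-Golay (SG)
filter whose window spans nearly the whole record, and summarises growth
by the slopes of short overlapping segments of the smoothed trace.  The
pooled slope distribution yields the average capacitance growth factor
``S_avg`` (aF/h) and its spread ``sigma``.

Units: timestamps are stored in seconds; every slope and rate is per
hour.  The seconds-to-hours conversion happens exactly once, inside
:func:`segment_slopes`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

__all__ = [
    "CapacitanceSeries",
    "AverageTrace",
    "TrendCurve",
    "SlopeSample",
    "GrowthFactorDistribution",
    "NormalityResult",
    "compute_delta_c",
    "average_trace",
    "sg_window_length",
    "sg_trend",
    "segment_slopes",
    "slope_distribution",
    "normality_test",
]

SG_ORDER_DEFAULT = 3
SEGMENT_H_DEFAULT = 1.0
STEP_H_DEFAULT = 0.5


@dataclass
class CapacitanceSeries:
    """Per-electrode ΔC matrix on a common time grid.

    ``values`` has shape ``(n_electrodes, n_timestamps)`` and is in aF.
    """

    timestamps_s: np.ndarray
    values: np.ndarray
    electrode_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.timestamps_s.ndim != 1 or self.timestamps_s.size < 2:
            raise ValueError("need at least 2 timestamps")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.values.shape[1] != self.timestamps_s.size:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.timestamps_s.size} timestamps"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("capacitance values contain NaN/inf")
        if not self.electrode_ids:
            self.electrode_ids = [f"e{i:02d}" for i in range(self.n_electrodes)]
        if len(self.electrode_ids) != self.n_electrodes:
            raise ValueError("electrode_ids length mismatch")

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timestamps(self) -> int:
        return self.values.shape[1]

    def truncate(self, max_time_s: float) -> "CapacitanceSeries":
        """Keep samples with t <= max_time_s."""
        keep = self.timestamps_s <= max_time_s
        if keep.sum() < 2:
            raise ValueError("truncation leaves fewer than 2 samples")
        return CapacitanceSeries(
            self.timestamps_s[keep], self.values[:, keep], list(self.electrode_ids)
        )


@dataclass
class AverageTrace:
    """Electrode-averaged ΔC trace (the ``ΔC_m`` signal)."""

    timestamps_s: np.ndarray
    delta_c_aF: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.delta_c_aF = np.asarray(self.delta_c_aF, dtype=float)
        if self.timestamps_s.shape != self.delta_c_aF.shape:
            raise ValueError("length mismatch")


@dataclass
class TrendCurve:
    """SG-smoothed ΔC_m trace."""

    timestamps_s: np.ndarray
    delta_c_aF: np.ndarray
    sg_order: int
    sg_window: int

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.delta_c_aF = np.asarray(self.delta_c_aF, dtype=float)
        if self.timestamps_s.shape != self.delta_c_aF.shape:
            raise ValueError("length mismatch")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")


@dataclass(frozen=True)
class SlopeSample:
    """OLS slope of the smoothed trace over one segment, in aF/h."""

    t_start_h: float
    t_end_h: float
    slope_aF_per_h: float
    electrode_id: str = "average"


@dataclass
class GrowthFactorDistribution:
    """Pooled segment slopes with their summary statistics.

    ``S_avg_aF_per_h`` is the arithmetic mean of the stored slopes
    (exact, never recomputed from the histogram) and ``sigma_aF_per_h``
    the sample standard deviation.
    """

    slopes: list[SlopeSample]
    S_avg_aF_per_h: float
    sigma_aF_per_h: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    n_electrodes: int = 1
    method: str = "per-pixel"

    @property
    def n_slopes(self) -> int:
        return len(self.slopes)

    @property
    def slope_values(self) -> np.ndarray:
        return np.array([s.slope_aF_per_h for s in self.slopes])

    def standard_error(self) -> float:
        """Standard error of S_avg using electrodes as the independent unit.

        Segment slopes extracted from the same electrode trace share one
        near-global SG polynomial and are strongly dependent, so the
        number of electrodes — not the number of pooled slopes — is the
        effective replicate count.
        """
        return self.sigma_aF_per_h / np.sqrt(max(self.n_electrodes, 1))


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    verdict: str
    test_name: str


def compute_delta_c(
    raw: CapacitanceSeries, baseline: np.ndarray | None = None
) -> CapacitanceSeries:
    """Subtract each electrode's baseline capacitance.

    By default the baseline is the electrode's own first stored sample
    (so ΔC at t=0 is exactly 0); alternatively a pre-start reference
    vector with one value per electrode may be supplied.
    """
    if baseline is None:
        ref = raw.values[:, :1]
    else:
        ref = np.asarray(baseline, dtype=float)
        if ref.shape != (raw.n_electrodes,):
            raise ValueError(
                f"baseline has shape {ref.shape}, expected ({raw.n_electrodes},)"
            )
        ref = ref[:, None]
    return CapacitanceSeries(
        raw.timestamps_s, raw.values - ref, list(raw.electrode_ids)
    )


def average_trace(series: CapacitanceSeries) -> AverageTrace:
    """Unweighted arithmetic mean across electrodes at each timestamp."""
    return AverageTrace(series.timestamps_s, series.values.mean(axis=0))


def sg_window_length(n: int) -> int:
    """Window rule: the largest odd integer <= n-1.

    For an even number of samples this is exactly n-1; for odd n it is
    n-2, the minimal extension of the same rule.
    """
    w = n - 1 if (n - 1) % 2 == 1 else n - 2
    if w <= SG_ORDER_DEFAULT:
        raise ValueError(f"series too short for SG smoothing (n={n})")
    return w


def sg_trend(
    trace: AverageTrace,
    order: int = SG_ORDER_DEFAULT,
    window: int | None = None,
) -> TrendCurve:
    """Third-order Savitzky-Golay smoothing of the average trace.

    The default window follows the near-global rule (largest odd
    integer <= n-1), which makes the trend effectively a global cubic
    fit; edge samples are filled by the same local polynomial
    (``mode="interp"``).  The window may be overridden for exploration.
    """
    y = trace.delta_c_aF
    n = y.size
    if window is None:
        window = sg_window_length(n)
    if window % 2 == 0 or window <= order or window > n:
        raise ValueError(f"invalid SG window {window} for n={n}, order={order}")
    smoothed = savgol_filter(y, window_length=window, polyorder=order, mode="interp")
    return TrendCurve(trace.timestamps_s, smoothed, sg_order=order, sg_window=window)


def segment_slopes(
    trend: TrendCurve | AverageTrace,
    segment_h: float = SEGMENT_H_DEFAULT,
    step_h: float = STEP_H_DEFAULT,
    label: str = "average",
) -> list[SlopeSample]:
    """Slopes of overlapping segments of the smoothed trace.

    Segments start at t = 0, step_h, 2*step_h, ... (relative to the
    first sample) while ``start + segment_h <= span``; each segment
    covers samples with relative time in ``[start, start + segment_h)``
    and contributes its ordinary least-squares slope in aF per hour.
    Trailing partial segments are dropped.
    """
    t_h = np.asarray(trend.timestamps_s, dtype=float) / 3600.0
    y = np.asarray(trend.delta_c_aF, dtype=float)
    rel = t_h - t_h[0]
    span = rel[-1]
    if span < segment_h:
        raise ValueError(f"trace spans {span:.3g} h, shorter than one segment")
    out: list[SlopeSample] = []
    start = 0.0
    eps = 1e-9
    while start + segment_h <= span + eps:
        lo = np.searchsorted(rel, start - eps, side="left")
        hi = np.searchsorted(rel, start + segment_h - eps, side="left")
        if hi - lo < 2:
            raise ValueError(
                f"segment [{start}, {start + segment_h}) h contains "
                f"{hi - lo} samples; cannot regress"
            )
        tt = rel[lo:hi]
        yy = y[lo:hi]
        tbar = tt.mean()
        slope = float(np.dot(tt - tbar, yy - yy.mean()) / np.dot(tt - tbar, tt - tbar))
        out.append(
            SlopeSample(
                t_start_h=float(start),
                t_end_h=float(start + segment_h),
                slope_aF_per_h=slope,
                electrode_id=label,
            )
        )
        start += step_h
    return out


def _pointwise_slopes(
    y: np.ndarray, t_h: np.ndarray, order: int, window: int
) -> np.ndarray:
    dt_h = float(np.median(np.diff(t_h)))
    return savgol_filter(
        y, window_length=window, polyorder=order, deriv=1, delta=dt_h, mode="interp"
    )


def slope_distribution(
    series: CapacitanceSeries,
    method: str = "per-pixel",
    order: int = SG_ORDER_DEFAULT,
    window: int | None = None,
    segment_h: float = SEGMENT_H_DEFAULT,
    step_h: float = STEP_H_DEFAULT,
) -> GrowthFactorDistribution:
    """Pool capacitance growth factors into a distribution.

    method="per-pixel" (default): SG-fit each electrode's ΔC trace with
    the same window rule, extract overlapping-segment regression slopes
    per electrode, and pool everything.  method="average-trace": segment
    slopes of the SG trend of the electrode-averaged trace only.
    method="per-pixel-derivative": pointwise SG first derivatives of
    each electrode trace (a variant retained for comparison).

    ``S_avg`` is the arithmetic mean of the pooled slopes and ``sigma``
    their sample standard deviation.  Histogram bins follow the
    Freedman-Diaconis rule and are cosmetic; the statistics always come
    from the raw slopes.
    """
    n = series.n_timestamps
    win = sg_window_length(n) if window is None else window
    slopes: list[SlopeSample] = []
    if method == "per-pixel":
        for eid, tr in zip(series.electrode_ids, series.values):
            sm = savgol_filter(tr, window_length=win, polyorder=order, mode="interp")
            curve = TrendCurve(series.timestamps_s, sm, sg_order=order, sg_window=win)
            slopes.extend(segment_slopes(curve, segment_h, step_h, label=eid))
        n_units = series.n_electrodes
    elif method == "average-trace":
        trend = sg_trend(average_trace(series), order=order, window=win)
        slopes = segment_slopes(trend, segment_h, step_h, label="average")
        n_units = 1
    elif method == "per-pixel-derivative":
        t_h = series.timestamps_s / 3600.0
        for eid, tr in zip(series.electrode_ids, series.values):
            der = _pointwise_slopes(tr, t_h, order, win)
            slopes.extend(
                SlopeSample(float(t), float(t), float(s), electrode_id=eid)
                for t, s in zip(t_h - t_h[0], der)
            )
        n_units = series.n_electrodes
    else:
        raise ValueError(f"unknown method {method!r}")

    vals = np.array([s.slope_aF_per_h for s in slopes])
    s_avg = float(vals.mean())
    sigma = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if vals.size > 1 and np.ptp(vals) > 0:
        iqr = float(np.subtract(*np.percentile(vals, [75, 25])))
        if iqr > 0:  # Freedman-Diaconis width, capped for degenerate spreads
            width = 2.0 * iqr / vals.size ** (1.0 / 3.0)
            nbins = int(np.clip(math.ceil(np.ptp(vals) / width), 1, 200))
        else:
            nbins = 1
        counts, edges = np.histogram(vals, bins=nbins)
    else:
        counts, edges = np.histogram(vals, bins=1)
    return GrowthFactorDistribution(
        slopes=slopes,
        S_avg_aF_per_h=s_avg,
        sigma_aF_per_h=sigma,
        bin_edges=edges,
        bin_counts=counts,
        n_electrodes=n_units,
        method=method,
    )


def normality_test(dist: GrowthFactorDistribution) -> NormalityResult:
    """Test whether the pooled slopes are approximately normal.

    Shapiro-Wilk for up to 5000 slopes, D'Agostino K² beyond that.  The
    verdict is reported but never used to abort the analysis, which
    proceeds under the normality assumption regardless.
    """
    vals = dist.slope_values
    if vals.size < 8:
        raise ValueError("need at least 8 slopes for a normality test")
    if np.ptp(vals) == 0.0:
        return NormalityResult(float("nan"), float("nan"), "degenerate", "none")
    if vals.size <= 5000:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.shapiro(vals)
        name = "shapiro-wilk"
    else:
        stat, p = stats.normaltest(vals)
        name = "dagostino-k2"
    verdict = "approximately normal" if p >= 0.05 else "non-normal"
    return NormalityResult(float(stat), float(p), verdict, name)
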