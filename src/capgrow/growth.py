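"""Log-linear calibration and the exponential temporal growth model.

The number of cells in the ROI and the average interfacial capacitance
obey a log-linear law, ``ln N_m = α·ΔC_m + K``.  Treating the average
capacitance growth factor S_avg as the (constant) rate of change of
ΔC_m turns this into an exponential temporal model
``N(t) = A·exp(α·S_avg·t)``; pinning it to the measured counts at two
times t0 and tn (boundary conditions N0, Nf) gives the particular model

    N(t) = Γ·exp(α·S_avg·t) + β,

whose constants have the closed form

    Γ = (Nf − N0) / (exp(α·S_avg·tn) − exp(α·S_avg·t0)),
    β = N0 − Γ·exp(α·S_avg·t0).

α and S_avg enter as measured constants — there is no joint refit.  The
doubling time is the t_d > 0 with N(t0 + t_d) = 2·N0, when it exists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .counting import CellCountSeries
from .trends import TrendCurve

__all__ = [
    "PairedSeries",
    "LogLinearFit",
    "GeneralizedModel",
    "ParticularModel",
    "FitQuality",
    "DoublingTime",
    "InsufficientDataError",
    "align_series",
    "fit_loglinear",
    "build_generalized",
    "fit_particular",
    "predict",
    "goodness_of_fit",
    "doubling_time",
]

K_PREDICTORS = 3  # number of independent variables used for adjusted R²


class InsufficientDataError(ValueError):
    pass


@dataclass
class PairedSeries:
    """ln(cell count) and ΔC_m matched at common timestamps (hours)."""

    timestamps_h: np.ndarray
    ln_counts: np.ndarray
    delta_c_aF: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        self.ln_counts = np.asarray(self.ln_counts, dtype=float)
        self.delta_c_aF = np.asarray(self.delta_c_aF, dtype=float)
        if not (
            self.timestamps_h.shape == self.ln_counts.shape == self.delta_c_aF.shape
        ):
            raise ValueError("length mismatch")
        if self.timestamps_h.size < 3:
            raise InsufficientDataError("need at least 3 paired points")

    def __len__(self) -> int:
        return self.timestamps_h.size


@dataclass(frozen=True)
class LogLinearFit:
    """OLS fit of ln N on ΔC: slope α (1/aF) and intercept K."""

    alpha: float
    K: float
    pearson_r: float
    p_value: float
    n_points: int


@dataclass(frozen=True)
class GeneralizedModel:
    """N(t) = A·exp(α·S_avg·t) with A = e^K.

    Diagnostic only: because A inherits the regression intercept, this
    form typically misses the measured count at t=0; the particular
    model with boundary conditions is the headline fit.
    """

    A: float
    alpha: float
    S_avg: float

    def predict(self, t_h):
        return self.A * np.exp(self.alpha * self.S_avg * np.asarray(t_h, dtype=float))


@dataclass(frozen=True)
class ParticularModel:
    """Boundary-condition exponential model N(t) = Γ·e^{α·S_avg·t} + β."""

    Gamma: float
    beta: float
    alpha: float
    S_avg: float
    t0_h: float
    tn_h: float
    N0: float
    Nf: float

    @property
    def rate_per_h(self) -> float:
        return self.alpha * self.S_avg


@dataclass(frozen=True)
class FitQuality:
    r_squared: float
    adj_r_squared: float
    k: int
    n_points: int


@dataclass(frozen=True)
class DoublingTime:
    """Time for the initial in-ROI count to double under the model.

    ``t_d_h`` is None when the model never reaches 2·N0 or does not
    reach it inside the observation window (mirroring a "—" entry);
    ``t_d_extrapolated_h`` keeps the mathematical root when it exists
    beyond the window.
    """

    t_d_h: float | None
    within_window: bool
    t_d_extrapolated_h: float | None = None


def align_series(
    counts: CellCountSeries, trend: TrendCurve, tol_s: float = 150.0
) -> PairedSeries:
    """Pair each count with the nearest trend sample within a tolerance.

    The default tolerance, 150 s, is half the 5-min imaging cadence.
    Counts without a trend sample within the tolerance, and counts of
    zero (undefined under the log), are dropped with a warning.
    """
    if len(counts) == 0 or trend.timestamps_s.size == 0:
        raise InsufficientDataError("empty input series")
    tt = trend.timestamps_s
    ct = counts.timestamps_s
    idx = np.searchsorted(tt, ct)
    idx = np.clip(idx, 1, tt.size - 1)
    left = idx - 1
    idx = np.where(np.abs(tt[left] - ct) <= np.abs(tt[idx] - ct), left, idx)
    dt = np.abs(tt[idx] - ct)
    keep = dt <= tol_s
    n_far = int((~keep).sum())
    if n_far:
        warnings.warn(
            f"dropped {n_far} counts with no trend sample within {tol_s:.0f} s"
        )
    zero = counts.counts <= 0
    n_zero = int((zero & keep).sum())
    if n_zero:
        warnings.warn(f"dropped {n_zero} zero counts before taking logarithms")
    keep &= ~zero
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} usable pairs after alignment"
        )
    return PairedSeries(
        ct[keep] / 3600.0,
        np.log(counts.counts[keep]),
        trend.delta_c_aF[idx[keep]],
    )


def fit_loglinear(pairs: PairedSeries) -> LogLinearFit:
    """OLS of ln N on ΔC with the Pearson correlation and its p-value.

    The two-sided p-value uses the t-distribution with n−2 degrees of
    freedom.
    """
    if np.ptp(pairs.delta_c_aF) == 0.0:
        raise ValueError("ΔC is constant; regression degenerate")
    res = stats.linregress(pairs.delta_c_aF, pairs.ln_counts)
    return LogLinearFit(
        alpha=float(res.slope),
        K=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=len(pairs),
    )


def build_generalized(fit: LogLinearFit, S_avg: float) -> GeneralizedModel:
    """Lift the log-linear fit to the exponential temporal form A·e^{αS t}."""
    if not (np.isfinite(fit.alpha) and np.isfinite(fit.K) and np.isfinite(S_avg)):
        raise ValueError("non-finite inputs")
    return GeneralizedModel(A=math.exp(fit.K), alpha=fit.alpha, S_avg=S_avg)


def fit_particular(
    alpha: float,
    S_avg: float,
    N0: float,
    t0_h: float,
    Nf: float,
    tn_h: float,
) -> ParticularModel:
    """Solve the boundary-condition system for Γ and β in closed form."""
    if tn_h <= t0_h:
        raise ValueError("tn must exceed t0")
    if N0 <= 0 or Nf <= 0:
        raise ValueError("boundary counts must be positive")
    x = alpha * S_avg
    if x == 0.0 or not np.isfinite(x):
        raise ValueError("α·S_avg must be finite and nonzero (exponential degenerate)")
    e0 = math.exp(x * t0_h)
    en = math.exp(x * tn_h)
    if en == e0:  # rate too small to resolve over the window
        raise ValueError("α·S_avg·(tn−t0) vanishes; boundary system singular")
    gamma = (Nf - N0) / (en - e0)
    beta = N0 - gamma * e0
    return ParticularModel(
        Gamma=gamma, beta=beta, alpha=alpha, S_avg=S_avg,
        t0_h=t0_h, tn_h=tn_h, N0=N0, Nf=Nf,
    )


def predict(model: ParticularModel | GeneralizedModel, t_h):
    """Evaluate the model at time(s) t in hours; real-valued."""
    if isinstance(model, GeneralizedModel):
        return model.predict(t_h)
    t = np.asarray(t_h, dtype=float)
    out = model.Gamma * np.exp(model.rate_per_h * t) + model.beta
    return float(out) if np.isscalar(t_h) else out


def goodness_of_fit(model: ParticularModel, counts: CellCountSeries) -> FitQuality:
    """R² and adjusted R² of the model against measured counts.

    Both are computed on the linear count scale.  The adjustment uses
    k = 3 independent variables, the convention for this model family.
    """
    n = len(counts)
    if n < K_PREDICTORS + 2:
        raise InsufficientDataError(f"need at least {K_PREDICTORS + 2} observations")
    y = counts.counts
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("counts have zero variance; R² undefined")
    pred = predict(model, counts.timestamps_s / 3600.0)
    ss_res = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - K_PREDICTORS - 1)
    return FitQuality(r_squared=r2, adj_r_squared=adj, k=K_PREDICTORS, n_points=n)


def doubling_time(model: ParticularModel, window_end_h: float) -> DoublingTime:
    """Solve Γ·e^{α·S_avg·(t0+t_d)} + β = 2·N0 for t_d.

    Closed form: t_d = ln((2·N0 − β)/Γ)/(α·S_avg) − t0.  Undefined when
    the model never doubles (no positive root); reported as undefined
    with ``within_window=False`` when the root falls beyond the window.
    """
    if model.Gamma == 0.0:
        return DoublingTime(None, False)
    arg = (2.0 * model.N0 - model.beta) / model.Gamma
    if arg <= 0.0:
        return DoublingTime(None, False)
    t_abs = math.log(arg) / model.rate_per_h
    t_d = t_abs - model.t0_h
    if t_d <= 0.0 or not np.isfinite(t_d):
        return DoublingTime(None, False)
    if model.t0_h + t_d > window_end_h:
        return DoublingTime(None, False, t_d_extrapolated_h=t_d)
    return DoublingTime(t_d, True, t_d_extrapolated_h=t_d)
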