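"""File formats, configuration and the end-to-end pipeline.

On-disk formats are deliberately plain: a wide CSV for the capacitance
record (column ``time_s`` then one column per electrode, ``e00``…),
timestamped image filenames (``frame_t{seconds}.png`` or ``.tif``),
CSVs for counts/slopes/detections, YAML for configuration, and a
canonical JSON run report (sorted keys, 12-significant-digit floats,
NaN serialized as null) so that diffs between runs are meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import counting, growth, trends
from .counting import (
    CellCountSeries,
    MatchConfig,
    Micrograph,
    MicrographStack,
    ROI,
)
from .trends import CapacitanceSeries, TrendCurve

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineError",
    "ParseError",
    "read_capacitance_csv",
    "write_capacitance_csv",
    "read_counts_csv",
    "write_counts_csv",
    "write_detections_csv",
    "write_slopes_csv",
    "read_image_stack",
    "write_image_stack",
    "write_experiment",
    "analyze_series",
    "run_pipeline",
    "write_report",
    "read_report",
]

logger = logging.getLogger("capgrow")

FLOAT_FMT = "%.12g"
IMAGE_PATTERN_DEFAULT = r"frame_t(\d+)\.(png|tif|tiff)$"
LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R BT.601


class ParseError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# capacitance / counts CSV

def read_capacitance_csv(path: str | Path, mode: str = "delta") -> CapacitanceSeries:
    """Read the wide capacitance CSV.

    ``mode="delta"``: stored values are already ΔC.  ``mode="raw"``:
    values are absolute capacitance and each electrode's first sample is
    subtracted on load.  Line numbers in errors count the header as
    line 1.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    if df.columns[0] != "time_s":
        raise ParseError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: no electrode columns")
    na = df.isna().any(axis=1)
    if na.any():
        line = int(np.flatnonzero(na.to_numpy())[0]) + 2
        raise ParseError(f"{path}: missing value on line {line}")
    t = df["time_s"].to_numpy(dtype=float)
    dup = np.flatnonzero(np.diff(t) == 0)
    if dup.size:
        raise ParseError(f"{path}: duplicate timestamp on line {int(dup[0]) + 3}")
    if np.any(np.diff(t) < 0):
        bad = int(np.flatnonzero(np.diff(t) < 0)[0]) + 3
        raise ParseError(f"{path}: timestamps decrease on line {bad}")
    values = df.iloc[:, 1:].to_numpy(dtype=float).T
    series = CapacitanceSeries(t, values, list(df.columns[1:]))
    if mode == "raw":
        series = trends.compute_delta_c(series)
    elif mode != "delta":
        raise ValueError(f"unknown mode {mode!r}")
    return series


def write_capacitance_csv(series: CapacitanceSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": series.timestamps_s})
    for eid, row in zip(series.electrode_ids, series.values):
        df[eid] = row
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_counts_csv(path: str | Path) -> CellCountSeries:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "count"]:
        raise ParseError(f"{path}: expected columns time_s,count")
    return CellCountSeries(
        df["time_s"].to_numpy(dtype=float), df["count"].to_numpy(dtype=float)
    )


def write_counts_csv(counts: CellCountSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": counts.timestamps_s, "count": counts.counts}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def write_detections_csv(counts: CellCountSeries, path: str | Path) -> None:
    rows = []
    for i, (t, dets) in enumerate(zip(counts.timestamps_s, counts.detections or [])):
        for d in dets:
            rows.append((i, t, d.row, d.col, d.score))
    pd.DataFrame(
        rows, columns=["frame", "t_s", "row", "col", "score"]
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_slopes_csv(dist: trends.GrowthFactorDistribution, path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.electrode_id, s.t_start_h, s.t_end_h, s.slope_aF_per_h)
            for s in dist.slopes
        ],
        columns=["electrode_id", "t_start_h", "t_end_h", "slope_aF_per_h"],
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# image stacks

def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        w = np.array(LUMA_WEIGHTS)
        gray = arr[:, :, :3].astype(float) @ w
        return np.round(gray).astype(arr.dtype)
    raise ParseError(f"unsupported image shape {arr.shape}")


def read_image_stack(
    directory: str | Path, pattern: str = IMAGE_PATTERN_DEFAULT
) -> MicrographStack:
    """Read frames sorted by the timestamp embedded in their filename.

    8-bit PNG and 8/16-bit TIFF are accepted; RGB(A) inputs are
    converted to luminance with fixed BT.601 weights.
    """
    directory = Path(directory)
    rx = re.compile(pattern)
    matched: list[tuple[float, Path]] = []
    unparsable: list[str] = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in (".png", ".tif", ".tiff"):
            m = rx.search(p.name)
            if m:
                matched.append((float(m.group(1)), p))
            else:
                unparsable.append(p.name)
    if unparsable:
        raise ParseError(f"filenames do not match pattern {pattern!r}: {unparsable}")
    if not matched:
        raise ParseError(f"no frames matching {pattern!r} in {directory}")
    matched.sort(key=lambda tp: tp[0])
    frames = []
    for t_s, p in matched:
        arr = tifffile.imread(p) if p.suffix.lower() in (".tif", ".tiff") else iio.imread(p)
        frames.append(Micrograph(_to_grayscale(np.asarray(arr)), t_s))
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        byshape = {
            s: [p.name for (t, p), f in zip(matched, frames) if f.shape == s]
            for s in shapes
        }
        raise ParseError(f"mixed frame shapes: {byshape}")
    return MicrographStack(frames)


def write_image_stack(
    stack: MicrographStack, directory: str | Path, fmt: str = "png"
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in stack.frames:
        name = f"frame_t{int(round(f.timestamp_s))}.{fmt}"
        p = directory / name
        if fmt == "png":
            iio.imwrite(p, f.pixels)
        else:
            tifffile.imwrite(p, f.pixels)
        paths.append(p)
    return paths


def write_experiment(exp, out_dir: str | Path) -> None:
    """Write a synthetic experiment in the pipeline's file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_capacitance_csv(exp.capacitance, out / "capacitance.csv")
    if len(exp.images):
        write_image_stack(exp.images, out / "images")
    write_counts_csv(exp.truth.trajectory, out / "truth_counts.csv")
    meta = {
        "params": asdict(exp.truth.params),
        "roi": [exp.roi.row0, exp.roi.row1, exp.roi.col0, exp.roi.col1],
    }
    (out / "truth.json").write_text(json.dumps(meta, sort_keys=True, indent=2))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Settings for an end-to-end run.

    The 30-h analysis window reflects the observation that the ROI
    saturates with cells beyond that point; only data inside the window
    enters any statistic.
    """

    capacitance_csv: str = "capacitance.csv"
    capacitance_mode: str = "delta"
    image_dir: str = "images"
    image_pattern: str = IMAGE_PATTERN_DEFAULT
    roi: tuple[int, int, int, int] = (0, 1, 0, 1)
    template_frame_index: int = 0
    template_centers: list[tuple[int, int]] = field(default_factory=list)
    template_half_size: int = 5
    threshold: float = 0.6
    nms_radius: float | None = None
    preprocess: bool = True
    analysis_window_h: float = 30.0
    sg_order: int = 3
    sg_window: int | None = None
    segment_h: float = 1.0
    step_h: float = 0.5
    slope_method: str = "per-pixel"
    align_tol_s: float = 150.0
    count_stride: int = 1
    boundary_frames: int = 1  # median over this many frames at each end
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.analysis_window_h <= 0:
            raise ValueError("analysis window must be positive")
        if self.count_stride < 1 or self.boundary_frames < 1:
            raise ValueError("strides and frame windows must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "roi" in data and data["roi"] is not None:
            data["roi"] = tuple(data["roi"])
        if "template_centers" in data and data["template_centers"]:
            data["template_centers"] = [tuple(c) for c in data["template_centers"]]
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def match_config(self) -> MatchConfig:
        return MatchConfig(
            threshold=self.threshold,
            nms_radius=self.nms_radius,
            preprocess=self.preprocess,
        )


def _plain(obj):
    """Recursively convert numpy/tuple values to YAML/JSON-native types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    return obj


# ---------------------------------------------------------------------------
# run report

@dataclass
class RunReport:
    """All headline statistics of one run plus provenance."""

    alpha: float
    K: float
    pearson_r: float
    p_value: float
    S_avg: float
    sigma: float
    n_slopes: int
    n_electrodes: int
    Gamma: float
    beta: float
    R2: float
    adjR2: float
    t_d: float | None
    within_window: bool
    t_d_extrapolated: float | None
    N0: float
    Nf: float
    t0_h: float
    tn_h: float
    n_pairs: int
    growth_z: float
    growth_significant: bool
    normality_p: float
    normality_verdict: str
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _plain(asdict(self))


def _round_floats(obj, warnings_out: list[str], path: str = ""):
    if isinstance(obj, dict):
        return {k: _round_floats(v, warnings_out, f"{path}.{k}") for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, warnings_out, path) for v in obj]
    if isinstance(obj, float):
        if not np.isfinite(obj):
            warnings_out.append(f"non-finite value at {path.lstrip('.')} serialized as null")
            return None
        return float(f"{obj:.12g}")
    return obj


def write_report(report: RunReport | dict, path: str | Path) -> None:
    """Write the canonical JSON report (sorted keys, stable floats)."""
    data = report.to_dict() if isinstance(report, RunReport) else _plain(dict(report))
    warn: list[str] = []
    data = _round_floats(data, warn)
    if warn:
        data.setdefault("warnings", []).extend(warn)
    Path(path).write_text(json.dumps(data, sort_keys=True, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _boundary_count(counts: CellCountSeries, side: str, frames: int) -> float:
    vals = counts.counts[:frames] if side == "first" else counts.counts[-frames:]
    return float(np.median(vals))


def analyze_series(
    cap: CapacitanceSeries,
    counts: CellCountSeries,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Analysis core on in-memory series (already inside the window).

    Extracts the SG trend and the growth-factor distribution from the
    capacitance record, calibrates the log-linear law against the
    counts, fits the boundary-condition exponential model, and assembles
    the run report.
    """
    config = config or PipelineConfig()
    caught: list[str] = []
    trend = trends.sg_trend(
        trends.average_trace(cap), order=config.sg_order, window=config.sg_window
    )
    dist = trends.slope_distribution(
        cap,
        method=config.slope_method,
        order=config.sg_order,
        window=config.sg_window,
        segment_h=config.segment_h,
        step_h=config.step_h,
    )
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        pairs = growth.align_series(counts, trend, tol_s=config.align_tol_s)
    caught.extend(str(w.message) for w in wrec)
    fit = growth.fit_loglinear(pairs)
    positive = counts.counts > 0
    cc = CellCountSeries(counts.timestamps_s[positive], counts.counts[positive])
    n0 = _boundary_count(cc, "first", config.boundary_frames)
    nf = _boundary_count(cc, "last", config.boundary_frames)
    t0_h = float(cc.timestamps_s[0] / 3600.0)
    tn_h = float(cc.timestamps_s[-1] / 3600.0)
    nan = float("nan")
    try:
        pm = growth.fit_particular(fit.alpha, dist.S_avg_aF_per_h, n0, t0_h, nf, tn_h)
    except ValueError as exc:  # e.g. α·S_avg exactly zero in a flat control run
        caught.append(f"particular model degenerate: {exc}")
        pm = growth.ParticularModel(nan, nan, fit.alpha, dist.S_avg_aF_per_h,
                                    t0_h, tn_h, n0, nf)
    if np.isfinite(pm.Gamma):
        try:
            fq = growth.goodness_of_fit(pm, cc)
        except ValueError as exc:  # constant counts: R² undefined
            caught.append(f"goodness of fit undefined: {exc}")
            fq = growth.FitQuality(nan, nan, growth.K_PREDICTORS, len(cc))
        td = growth.doubling_time(pm, window_end_h=config.analysis_window_h)
    else:
        fq = growth.FitQuality(nan, nan, growth.K_PREDICTORS, len(cc))
        td = growth.DoublingTime(None, False)
    norm = trends.normality_test(dist)
    se = dist.standard_error()
    z = dist.S_avg_aF_per_h / se if se > 0 else float("inf")

    import scipy
    import skimage

    return RunReport(
        alpha=fit.alpha,
        K=fit.K,
        pearson_r=fit.pearson_r,
        p_value=fit.p_value,
        S_avg=dist.S_avg_aF_per_h,
        sigma=dist.sigma_aF_per_h,
        n_slopes=dist.n_slopes,
        n_electrodes=dist.n_electrodes,
        Gamma=pm.Gamma,
        beta=pm.beta,
        R2=fq.r_squared,
        adjR2=fq.adj_r_squared,
        t_d=td.t_d_h,
        within_window=td.within_window,
        t_d_extrapolated=td.t_d_extrapolated_h,
        N0=pm.N0,
        Nf=pm.Nf,
        t0_h=pm.t0_h,
        tn_h=pm.tn_h,
        n_pairs=fit.n_points,
        growth_z=float(z),
        growth_significant=bool(abs(z) > 2.0),
        normality_p=norm.p_value,
        normality_verdict=norm.verdict,
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "skimage": skimage.__version__,
            },
            "warnings": caught,
        },
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Chain counting, trend extraction and model fitting on one dataset.

    Both datasets are truncated to the analysis window first; every
    dropped frame or pair is logged.  Raises :class:`PipelineError`
    naming the failing stage.
    """
    window_s = config.analysis_window_h * 3600.0

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise PipelineError(f"stage {name!r}: {exc}") from exc

    def _load_cap():
        cap = read_capacitance_csv(config.capacitance_csv, config.capacitance_mode)
        n_before = cap.n_timestamps
        cap = cap.truncate(window_s)
        logger.info("capacitance: %d samples (%d beyond window dropped)",
                    cap.n_timestamps, n_before - cap.n_timestamps)
        return cap

    def _load_images():
        stack = read_image_stack(config.image_dir, config.image_pattern)
        kept = [f for f in stack.frames if f.timestamp_s <= window_s]
        dropped = len(stack) - len(kept)
        if dropped:
            logger.info("imaging: dropped %d frames beyond the window", dropped)
        kept = kept[:: config.count_stride]
        return MicrographStack(kept)

    def _count(stack):
        roi = ROI(*config.roi)
        ref = stack[config.template_frame_index]
        if config.preprocess:
            ref = counting.preprocess_image(ref, config.match_config())
        tpl = counting.extract_template(
            ref, [tuple(c) for c in config.template_centers], config.template_half_size
        )
        counts = counting.count_series(stack, tpl, roi, config.match_config())
        logger.info("counting: %s", np.array2string(counts.counts, threshold=10))
        return counts

    cap = stage("capacitance", _load_cap)
    stack = stage("imaging", _load_images)
    counts = stage("counting", _count, stack)
    report = stage("model", analyze_series, cap, counts, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        write_counts_csv(counts, out / "counts.csv")
        write_detections_csv(counts, out / "detections.csv")
        trend = trends.sg_trend(
            trends.average_trace(cap), order=config.sg_order, window=config.sg_window
        )
        pd.DataFrame(
            {"time_s": trend.timestamps_s, "delta_c_aF": trend.delta_c_aF}
        ).to_csv(out / "trend.csv", index=False, float_format=FLOAT_FMT)
    return report
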