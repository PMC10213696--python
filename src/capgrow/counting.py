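"""Template-matching cell counter for micrograph stacks.

Cells are detected by correlating an averaged exemplar patch (the
template) against each frame with zero-normalized cross-correlation
(ZNCC), thresholding the correlation map, applying greedy non-maximum
suppression, and counting the surviving detections whose centers fall
inside the region of interest spanned by the electrode array.

Conventions, used everywhere: coordinates are 0-based ``(row, col)``;
the ROI rectangle is half-open, ``[row0, row1) x [col0, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template
from skimage.filters import unsharp_mask

__all__ = [
    "Micrograph",
    "MicrographStack",
    "ROI",
    "Template",
    "Detection",
    "CellCountSeries",
    "MatchConfig",
    "preprocess_image",
    "extract_template",
    "detect_cells",
    "count_cells_in_roi",
    "count_series",
]


@dataclass
class Micrograph:
    """Single grayscale frame with its acquisition time."""

    pixels: np.ndarray
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("micrograph must be a non-empty 2-D array")
        if self.timestamp_s < 0:
            raise ValueError("timestamp must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MicrographStack:
    """Time-ordered stack of same-shape frames."""

    frames: list[Micrograph] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frames:
            shape = self.frames[0].shape
            bad = [i for i, f in enumerate(self.frames) if f.shape != shape]
            if bad:
                raise ValueError(f"frames {bad} differ in shape from frame 0 {shape}")
            ts = self.timestamps_s
            if np.any(np.diff(ts) <= 0):
                raise ValueError("frame timestamps must be strictly increasing")

    @property
    def timestamps_s(self) -> np.ndarray:
        return np.array([f.timestamp_s for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Micrograph:
        return self.frames[i]


@dataclass(frozen=True)
class ROI:
    """Half-open pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI is degenerate")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI must have non-negative origin")

    def validate_in(self, shape: tuple[int, int]) -> None:
        if self.row1 > shape[0] or self.col1 > shape[1]:
            raise ValueError(f"ROI {self} exceeds frame shape {shape}")

    def contains(self, row: float, col: float) -> bool:
        return self.row0 <= row < self.row1 and self.col0 <= col < self.col1

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0


@dataclass
class Template:
    """Averaged cell exemplar used as a correlation filter."""

    patch: np.ndarray
    n_source_cells: int = 1

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        if self.patch.ndim != 2:
            raise ValueError("template must be 2-D")
        if min(self.patch.shape) < 3:
            raise ValueError("template sides must be >= 3")
        if any(s % 2 == 0 for s in self.patch.shape):
            raise ValueError("template side lengths must be odd")
        if not np.all(np.isfinite(self.patch)):
            raise ValueError("template contains NaN/inf")

    @property
    def half_size(self) -> int:
        return self.patch.shape[0] // 2


@dataclass(frozen=True)
class Detection:
    """One flagged cell location with its correlation score."""

    row: int
    col: int
    score: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class CellCountSeries:
    """Per-frame in-ROI cell counts.

    Counts may be real-valued (a model trajectory) or integers (counter
    output); per-frame detections are kept when available.
    """

    timestamps_s: np.ndarray
    counts: np.ndarray
    detections: list[list[Detection]] | None = None

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.timestamps_s.shape != self.counts.shape:
            raise ValueError("length mismatch")
        if self.timestamps_s.size and np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    def __len__(self) -> int:
        return self.timestamps_s.size

    def truncate(self, max_time_s: float) -> "CellCountSeries":
        keep = self.timestamps_s <= max_time_s
        det = None
        if self.detections is not None:
            det = [d for d, k in zip(self.detections, keep) if k]
        return CellCountSeries(self.timestamps_s[keep], self.counts[keep], det)


@dataclass
class MatchConfig:
    """Counter settings; the paper-style defaults are config-exposed."""

    threshold: float = 0.6
    nms_radius: float | None = None  # default: template half-size
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    unsharp_sigma: float = 2.0
    unsharp_amount: float = 1.0
    preprocess: bool = True


def preprocess_image(img: Micrograph, cfg: MatchConfig | None = None) -> Micrograph:
    """Contrast stretch and unsharp masking.

    A percentile stretch (defaults: 1st-99th percentile mapped to the
    full dtype range) is followed by unsharp masking (Gaussian sigma
    2.0, amount 1.0).  A constant frame passes through unchanged.  The
    false-color step used for display is deliberately not part of the
    quantitative path.
    """
    cfg = cfg or MatchConfig()
    px = img.pixels
    dtype = px.dtype
    if np.issubdtype(dtype, np.integer):
        vmax = float(np.iinfo(dtype).max)
    else:
        vmax = float(px.max()) if px.max() > 0 else 1.0
    x = px.astype(float)
    lo, hi = np.percentile(x, cfg.stretch_percentiles)
    if hi > lo:
        x = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    else:  # constant image: stretch is the identity
        x = x / vmax
    x = unsharp_mask(x, radius=cfg.unsharp_sigma, amount=cfg.unsharp_amount)
    x = np.clip(x, 0.0, 1.0) * vmax
    if np.issubdtype(dtype, np.integer):
        x = np.round(x).astype(dtype)
    else:
        x = x.astype(dtype)
    return Micrograph(x, img.timestamp_s)


def extract_template(
    img: Micrograph, centers: list[tuple[int, int]], half_size: int
) -> Template:
    """Average aligned patches around the given cell centers.

    Each patch is the ``(2*half_size+1)``-square neighborhood of a
    center; the template is their element-wise mean.
    """
    if not centers:
        raise ValueError("need at least one center")
    h, w = img.shape
    side = 2 * half_size + 1
    bad = [
        (r, c)
        for r, c in centers
        if r - half_size < 0 or c - half_size < 0 or r + half_size >= h or c + half_size >= w
    ]
    if bad:
        raise ValueError(f"patches cross the frame border at centers {bad}")
    acc = np.zeros((side, side), dtype=float)
    for r, c in centers:
        acc += img.pixels[
            r - half_size : r + half_size + 1, c - half_size : c + half_size + 1
        ].astype(float)
    return Template(acc / len(centers), n_source_cells=len(centers))


def detect_cells(
    img: Micrograph,
    tpl: Template,
    threshold: float = 0.6,
    nms_radius: float | None = None,
) -> list[Detection]:
    """ZNCC template matching with greedy non-maximum suppression.

    The zero-normalized cross-correlation map is computed at every valid
    template position; positions scoring at least ``threshold`` become
    candidates; candidates are accepted greedily in descending score
    order (ties broken by (row, col) lexicographic order), each accepted
    detection suppressing candidates within Euclidean center distance
    <= ``nms_radius`` (default: the template half-size).
    """
    if float(tpl.patch.std()) == 0.0:
        raise ValueError("template has zero variance; correlation undefined")
    if tpl.patch.shape[0] > img.shape[0] or tpl.patch.shape[1] > img.shape[1]:
        raise ValueError("template larger than image")
    if nms_radius is None:
        nms_radius = float(tpl.half_size)
    score = match_template(img.pixels.astype(float), tpl.patch)
    cand = np.argwhere(score >= threshold)
    if cand.size == 0:
        return []
    vals = score[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -vals))

    h, w = score.shape
    rad = int(np.floor(nms_radius))
    yy, xx = np.ogrid[-rad : rad + 1, -rad : rad + 1]
    disk = (yy * yy + xx * xx) <= nms_radius * nms_radius
    suppressed = np.zeros((h, w), dtype=bool)
    half = tpl.half_size
    out: list[Detection] = []
    for k in order:
        i, j = int(cand[k, 0]), int(cand[k, 1])
        if suppressed[i, j]:
            continue
        out.append(Detection(row=i + half, col=j + half, score=float(vals[k])))
        r0, r1 = max(0, i - rad), min(h, i + rad + 1)
        c0, c1 = max(0, j - rad), min(w, j + rad + 1)
        suppressed[r0:r1, c0:c1] |= disk[
            r0 - (i - rad) : disk.shape[0] - ((i + rad + 1) - r1),
            c0 - (j - rad) : disk.shape[1] - ((j + rad + 1) - c1),
        ]
    return out


def count_cells_in_roi(detections: list[Detection], roi: ROI) -> int:
    """Number of detections whose center lies in the half-open ROI."""
    return sum(1 for d in detections if roi.contains(d.row, d.col))


def count_series(
    stack: MicrographStack,
    tpl: Template,
    roi: ROI,
    cfg: MatchConfig | None = None,
) -> CellCountSeries:
    """Preprocess, detect and count every frame of a stack."""
    cfg = cfg or MatchConfig()
    if len(stack) == 0:
        return CellCountSeries(np.empty(0), np.empty(0), [])
    roi.validate_in(stack[0].shape)
    counts = []
    dets: list[list[Detection]] = []
    for frame in stack.frames:
        work = preprocess_image(frame, cfg) if cfg.preprocess else frame
        d = detect_cells(work, tpl, threshold=cfg.threshold, nms_radius=cfg.nms_radius)
        dets.append(d)
        counts.append(count_cells_in_roi(d, roi))
    return CellCountSeries(stack.timestamps_s, np.array(counts, dtype=float), dets)
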