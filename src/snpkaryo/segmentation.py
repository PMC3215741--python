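"""Genomic segmentation of per-probe copy-number signal.

The tumor signal is first expressed relative to a reference — either the
matched normal of the same patient (paired mode) or the per-probe median of a
panel of healthy reference samples (baseline mode) — and the resulting ratio
series is partitioned by recursive binary splitting: at each step the
candidate breakpoint is the cut maximizing the two-sample t statistic between
the left and right probe values, and the split is accepted when both sides
hold at least ``min_markers`` probes and the two-sided t-test p-value falls at
or below ``split_alpha``.  Adjacent segments whose means no longer differ at
``merge_alpha`` are re-merged.  Defaults follow the common practice for this
class of segmenters: 10 minimum markers and p <= 0.001.

Regions of low marker density are handled by splitting a series at any
inter-probe gap exceeding ``max_gap`` so no segment can span a marker desert.

Pure top-down bisection has a known blind spot: a short lesion deep inside a
long flat series barely moves the full-halves t statistic, so the recursion
can stop before isolating it.  The sample-level driver therefore runs a local
edge pre-scan first — a two-window t statistic over adjacent ``min_markers``
windows — and cuts the series at strong local mean shifts before bisecting
each block; the merge pass re-joins any cut whose flanks do not differ at
``merge_alpha``, so false edges cost nothing.  :func:`segment_series` itself
remains pure bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatioSeries",
    "Segment",
    "SegmentationParams",
    "ProbeAlignmentError",
    "compute_ratio_series",
    "mask_low_density",
    "segment_series",
    "segment_with_precut",
    "detect_edges",
    "best_split",
    "segment_sample",
]


class ProbeAlignmentError(ValueError):
    """Tumor and reference probe tables do not share an identical probe map."""


#: Mean differences at or below this are treated as zero in the degenerate
#: (zero-variance) branches of the t statistics, so cumulative-sum rounding
#: on constant stretches cannot fabricate infinite t values.
MEAN_DIFF_ATOL = 1e-9


@dataclass
class RatioSeries:
    """One chromosome's ordered probe positions with tumor-minus-reference
    LRR values (log2 units)."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray
    mode: str  # "paired" | "baseline"
    excluded: bool = False  # flagged by mask_low_density when too few markers

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have equal length")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("ratio values must be finite")
        if self.mode not in ("paired", "baseline"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class SegmentationParams:
    min_markers: int = 10
    split_alpha: float = 0.001
    merge_alpha: float | None = 0.001  # None disables the re-merge pass
    max_gap: int = 100_000

    def __post_init__(self) -> None:
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        if not 0.0 < self.split_alpha < 1.0:
            raise ValueError("split_alpha must lie in (0, 1)")
        if self.merge_alpha is not None and not 0.0 < self.merge_alpha < 1.0:
            raise ValueError("merge_alpha must lie in (0, 1)")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")


@dataclass
class Segment:
    """A maximal run of probes with homogeneous signal.  Coordinates are
    1-based half-open, snapped to member probes (end = last probe + 1)."""

    chrom: str
    start: int
    end: int
    n_markers: int
    mean_lrr: float
    i0: int  # member probe index range within the source series, half-open
    i1: int


def _align(tumor: pd.DataFrame, other: pd.DataFrame, label: str) -> None:
    if len(tumor) != len(other):
        raise ProbeAlignmentError(
            f"{label}: probe count differs ({len(tumor)} vs {len(other)})"
        )
    for col in ("probe_id", "chrom", "pos"):
        a = tumor[col].to_numpy()
        b = other[col].to_numpy()
        bad = np.nonzero(a != b)[0]
        if bad.size:
            i = int(bad[0])
            raise ProbeAlignmentError(
                f"{label}: first discordant probe at row {i}: "
                f"{col} {a[i]!r} != {b[i]!r}"
            )


def compute_ratio_series(
    tumor: pd.DataFrame,
    reference: pd.DataFrame | list[pd.DataFrame],
    mode: str,
) -> list[RatioSeries]:
    """Tumor-minus-reference LRR per probe, one series per chromosome.

    Paired mode subtracts the matched normal probe-by-probe; baseline mode
    subtracts the per-probe median across a panel of reference samples.
    """
    if mode == "paired":
        if not isinstance(reference, pd.DataFrame):
            raise TypeError("paired mode requires a single reference DataFrame")
        _align(tumor, reference, "matched normal")
        ref_lrr = reference["lrr"].to_numpy(dtype=float)
    elif mode == "baseline":
        panel = [reference] if isinstance(reference, pd.DataFrame) else list(reference)
        if not panel:
            raise ValueError("baseline mode requires at least one reference sample")
        for k, ref in enumerate(panel):
            _align(tumor, ref, f"baseline sample {k}")
        ref_lrr = np.median(
            np.stack([r["lrr"].to_numpy(dtype=float) for r in panel]), axis=0
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    values = tumor["lrr"].to_numpy(dtype=float) - ref_lrr
    chroms = tumor["chrom"].to_numpy()
    pos = tumor["pos"].to_numpy(dtype=np.int64)
    out: list[RatioSeries] = []
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        out.append(RatioSeries(str(chrom), pos[m], values[m], mode))
    return out


def mask_low_density(
    series: RatioSeries, max_gap: int, min_markers: int = 10
) -> list[RatioSeries]:
    """Split a series at inter-probe gaps strictly greater than ``max_gap``.

    Sub-series with fewer than ``min_markers`` probes are flagged ``excluded``
    (kept for bookkeeping, skipped by segmentation).
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    if len(series) == 0:
        return [series]
    gaps = np.diff(series.positions)
    cuts = np.nonzero(gaps > max_gap)[0] + 1
    bounds = [0, *cuts.tolist(), len(series)]
    out = []
    for a, b in zip(bounds, bounds[1:]):
        sub = RatioSeries(
            series.chrom,
            series.positions[a:b],
            series.values[a:b],
            series.mode,
            excluded=(b - a) < min_markers,
        )
        out.append(sub)
    return out


def _prefix_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.cumsum(x), np.cumsum(x * x)


def best_split(
    values: np.ndarray, min_markers: int
) -> tuple[int, float, float] | None:
    """Best single breakpoint of ``values`` by pooled-variance two-sample t.

    Returns (cut index k splitting into values[:k] / values[k:], |t|, p) for
    the leftmost cut maximizing |t| over all cuts leaving >= min_markers
    probes on each side, or None when no admissible cut exists.  When the
    pooled variance vanishes the statistic degenerates: differing means give
    p = 0, identical means p = 1.
    """
    n = values.size
    if n < 2 * min_markers:
        return None
    cs, css = _prefix_stats(values)
    ks = np.arange(min_markers, n - min_markers + 1)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = cs[ks - 1]
    m1 = s1 / n1
    m2 = (cs[-1] - s1) / n2
    ss1 = css[ks - 1] - n1 * m1 * m1
    ss2 = (css[-1] - css[ks - 1]) - n2 * m2 * m2
    sp2 = (ss1 + ss2) / (n - 2)
    sp2 = np.maximum(sp2, 0.0)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = np.abs(m1 - m2)
    diff = np.where(diff <= MEAN_DIFF_ATOL, 0.0, diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, np.where(diff > 0, np.inf, 0.0))
    best = int(np.argmax(t))  # argmax returns the leftmost maximum
    t_best = float(t[best])
    k = int(ks[best])
    if np.isinf(t_best):
        p = 0.0
    elif t_best == 0.0:
        p = 1.0
    else:
        p = float(2.0 * stats.t.sf(t_best, df=n - 2))
    return k, t_best, p


def _pooled_t_p(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = x1.size, x2.size
    m1, m2 = float(np.mean(x1)), float(np.mean(x2))
    ss = float(np.sum((x1 - m1) ** 2) + np.sum((x2 - m2) ** 2))
    df = n1 + n2 - 2
    if df <= 0:
        return 1.0
    sp2 = ss / df
    diff = abs(m1 - m2)
    if diff <= MEAN_DIFF_ATOL:
        return 1.0
    if sp2 <= 0:
        return 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(t, df=df))


def _split_leaves(
    values: np.ndarray, params: SegmentationParams, offset: int = 0
) -> list[tuple[int, int]]:
    """Leaf index ranges of the recursive bisection of ``values`` (shifted by
    ``offset``), sorted."""
    leaves: list[tuple[int, int]] = []
    stack = [(0, values.size)]
    while stack:
        i0, i1 = stack.pop()
        res = best_split(values[i0:i1], params.min_markers)
        if res is None:
            leaves.append((i0, i1))
            continue
        k, _t, p = res
        if p <= params.split_alpha:
            stack.append((i0 + k, i1))
            stack.append((i0, i0 + k))
        else:
            leaves.append((i0, i1))
    leaves.sort()
    return [(i0 + offset, i1 + offset) for i0, i1 in leaves]


def _merge_leaves(
    values: np.ndarray,
    leaves: list[tuple[int, int]],
    merge_alpha: float | None,
) -> list[tuple[int, int]]:
    """Re-merge adjacent leaves whose means do not differ at merge_alpha."""
    if merge_alpha is None or len(leaves) < 2:
        return leaves
    merged = True
    while merged and len(leaves) > 1:
        merged = False
        out: list[tuple[int, int]] = [leaves[0]]
        for i0, i1 in leaves[1:]:
            j0, j1 = out[-1]
            p = _pooled_t_p(values[j0:j1], values[i0:i1])
            if p > merge_alpha:
                out[-1] = (j0, i1)
                merged = True
            else:
                out.append((i0, i1))
        leaves = out
    return leaves


def segment_series(series: RatioSeries, params: SegmentationParams) -> list[Segment]:
    """Recursive top-down binary segmentation of one ratio series.

    The output segments partition the series: they are disjoint, ordered and
    jointly cover every probe.
    """
    n = len(series)
    if n == 0:
        return []
    if n < params.min_markers:
        warnings.warn(
            f"{series.chrom}: series of {n} probes is shorter than "
            f"min_markers={params.min_markers}; returning a single segment",
            stacklevel=2,
        )
        return [_make_segment(series, 0, n)]

    leaves = _split_leaves(series.values, params)
    leaves = _merge_leaves(series.values, leaves, params.merge_alpha)
    return [_make_segment(series, i0, i1) for i0, i1 in leaves]


def detect_edges(values: np.ndarray, w: int, alpha: float) -> list[int]:
    """Candidate breakpoints from a local two-window t statistic.

    For every cut k the means of the ``w`` probes on each side are compared
    with a pooled-variance t (df = 2w - 2); cuts whose |t| reaches the
    two-sided critical value at ``alpha`` are kept, strongest first, with
    weaker candidates suppressed within w//2 probes of an accepted one.
    """
    n = values.size
    if n < 2 * w:
        return []
    cs = np.concatenate([[0.0], np.cumsum(values)])
    css = np.concatenate([[0.0], np.cumsum(values * values)])
    ks = np.arange(w, n - w + 1)
    s_l = cs[ks] - cs[ks - w]
    s_r = cs[ks + w] - cs[ks]
    ss_l = css[ks] - css[ks - w] - s_l * s_l / w
    ss_r = css[ks + w] - css[ks] - s_r * s_r / w
    sp2 = np.maximum(ss_l + ss_r, 0.0) / (2 * w - 2)
    denom = np.sqrt(sp2 * 2.0 / w)
    diff = np.abs(s_l - s_r) / w
    diff = np.where(diff <= MEAN_DIFF_ATOL, 0.0, diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, np.where(diff > 0, np.inf, 0.0))
    crit = stats.t.isf(alpha / 2.0, df=2 * w - 2)
    cand = np.nonzero(t >= crit)[0]
    if cand.size == 0:
        return []
    order = cand[np.argsort(t[cand])[::-1]]
    accepted: list[int] = []
    for idx in order:
        k = int(ks[idx])
        if all(abs(k - a) > w // 2 for a in accepted):
            accepted.append(k)
    return sorted(accepted)


def segment_with_precut(
    series: RatioSeries, params: SegmentationParams
) -> list[Segment]:
    """Edge pre-scan followed by per-block bisection and a global merge.

    This is the production path: local edges isolate short lesions that pure
    bisection dilutes, bisection resolves structure within blocks, and the
    merge pass removes any cut whose flanks do not differ at merge_alpha.
    """
    n = len(series)
    if n < params.min_markers:
        return segment_series(series, params)
    edges = detect_edges(series.values, params.min_markers, params.split_alpha)
    bounds = [0, *edges, n]
    leaves: list[tuple[int, int]] = []
    for a, b in zip(bounds, bounds[1:]):
        if b - a < 2 * params.min_markers:
            leaves.append((a, b))
        else:
            leaves.extend(_split_leaves(series.values[a:b], params, offset=a))
    leaves = _merge_leaves(series.values, leaves, params.merge_alpha)
    return [_make_segment(series, i0, i1) for i0, i1 in leaves]


def _make_segment(series: RatioSeries, i0: int, i1: int) -> Segment:
    return Segment(
        chrom=series.chrom,
        start=int(series.positions[i0]),
        end=int(series.positions[i1 - 1]) + 1,
        n_markers=i1 - i0,
        mean_lrr=float(np.mean(series.values[i0:i1])),
        i0=i0,
        i1=i1,
    )


def segment_sample(
    tumor: pd.DataFrame,
    reference: pd.DataFrame | list[pd.DataFrame],
    mode: str,
    params: SegmentationParams | None = None,
) -> list[Segment]:
    """Convenience driver: ratio series -> low-density masking -> segmentation
    for every chromosome of one sample."""
    params = params or SegmentationParams()
    segments: list[Segment] = []
    for series in compute_ratio_series(tumor, reference, mode):
        for sub in mask_low_density(series, params.max_gap, params.min_markers):
            if sub.excluded:
                continue
            segments.extend(segment_with_precut(sub, params))
    return segments
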