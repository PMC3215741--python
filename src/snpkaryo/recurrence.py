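"""Cohort-level recurrence analysis.

Given the filtered lesion tables of a cohort this module computes:

* per-chromosome lesion density (count normalized by chromosome length in Mb)
  with a chi-square goodness-of-fit test of the raw counts against an
  expectation proportional to chromosome length;
* cytoband annotation of lesions against a UCSC-style band map;
* known/novel annotation against a user-supplied interval database of known
  copy-number variants;
* the recurrence profile — for each unit (cytoband or elementary interval)
  the number of distinct samples carrying an overlapping lesion, plus the
  histogram of how many regions recur in k samples;
* the minimal affected region (MAR): the shortest genomic interval affected
  by any imbalance in a strict majority of the cohort, found by a sweep line
  over lesion endpoints;
* a hypergeometric overlap test between two cytoband sets (e.g. the bands
  affected in a training cohort versus an independent test cohort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lesions import CoordinateError

__all__ = [
    "CytobandMap",
    "RecurrenceProfile",
    "MarResult",
    "OverlapTestResult",
    "InvalidUniverseError",
    "chromosome_density",
    "map_to_cytobands",
    "annotate_known",
    "recurrence_profile",
    "define_mar",
    "overlap_significance",
]


class InvalidUniverseError(ValueError):
    """The stated universe is smaller than the union of the two band sets."""


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    s = str(chrom)
    if s.lower().startswith("chr"):
        s = s[3:]
    return (0, f"{int(s):09d}") if s.isdigit() else (1, s)


class CytobandMap:
    """Cytoband records tiling each chromosome, with derived full band names
    (e.g. chromosome "20" band "p13" -> "20p13").  Coordinates are 1-based
    half-open internally."""

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "start", "end", "band"}
        if not required.issubset(table.columns):
            raise ValueError(f"cytoband table must have columns {sorted(required)}")
        table = table.sort_values(["chrom", "start"], key=None).reset_index(drop=True)
        self.table = table
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._names: dict[str, np.ndarray] = {}
        for chrom, sub in table.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: band with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping cytobands")
            chrom_label = str(chrom)
            if chrom_label.lower().startswith("chr"):
                chrom_label = chrom_label[3:]
            self._starts[str(chrom)] = starts
            self._ends[str(chrom)] = ends
            self._names[str(chrom)] = np.array(
                [f"{chrom_label}{b}" for b in sub["band"]], dtype=object
            )

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    @property
    def n_bands(self) -> int:
        return int(self.table.shape[0])

    def band_names(self, chromosomes: list[str] | None = None) -> list[str]:
        chroms = chromosomes if chromosomes is not None else self.chromosomes
        out: list[str] = []
        for c in chroms:
            out.extend(self._names[c].tolist())
        return out

    def bands_for(self, chrom: str, start: int, end: int) -> list[str]:
        """All bands overlapping [start, end) by >= 1 bp, in genomic order."""
        if end <= start:
            raise ValueError(f"zero-length query {chrom}:{start}-{end}")
        if chrom not in self._starts:
            raise CoordinateError(f"chromosome {chrom!r} not in cytoband map")
        starts, ends = self._starts[chrom], self._ends[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        return self._names[chrom][i:j].tolist()


def map_to_cytobands(
    chrom: str, start: int, end: int, cytobands: CytobandMap
) -> list[str]:
    """Band names overlapping the lesion [start, end) by at least 1 bp."""
    return cytobands.bands_for(chrom, start, end)


def chromosome_density(
    lesions: pd.DataFrame, chrom_sizes: dict[str, int]
) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome lesion counts normalized by length (Mb) and a
    chi-square goodness-of-fit test against length-proportional expectation.

    Returns (density table, chi-square summary).  With a single chromosome the
    test is not applicable (df = 0) and the p-value is reported as None.
    """
    for chrom in lesions["chrom"].unique():
        if chrom not in chrom_sizes:
            raise CoordinateError(f"no chromosome size for {chrom!r}")
    chroms = sorted(chrom_sizes, key=_chrom_sort_key)
    counts = lesions["chrom"].value_counts()
    rows = []
    for chrom in chroms:
        n = int(counts.get(chrom, 0))
        mb = chrom_sizes[chrom] / 1e6
        rows.append({"chrom": chrom, "count": n, "length_mb": mb, "density": n / mb})
    table = pd.DataFrame(rows)
    median = float(table["density"].median())
    table["above_median"] = table["density"] > median

    if len(chroms) < 2 or table["count"].sum() == 0:
        chi2 = {"statistic": None, "df": 0, "pvalue": None, "applicable": False}
    else:
        total = table["count"].sum()
        lengths = table["length_mb"].to_numpy()
        expected = total * lengths / lengths.sum()
        stat, p = stats.chisquare(table["count"].to_numpy(), f_exp=expected)
        chi2 = {
            "statistic": float(stat),
            "df": len(chroms) - 1,
            "pvalue": float(p),
            "applicable": True,
        }
    return table, chi2


def _merged_intervals(df: pd.DataFrame) -> np.ndarray:
    """Merge [start, end) rows into disjoint intervals; returns (k, 2) array."""
    iv = df[["start", "end"]].to_numpy(dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0])]
    out = []
    for s, e in iv:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def annotate_known(
    lesions: pd.DataFrame,
    known_db: pd.DataFrame,
    min_overlap_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Flag each lesion known/novel against an interval database.

    A lesion is known when the fraction of its length covered by database
    intervals is at least ``min_overlap_fraction``.  Returns the annotated
    table and a summary with counts and integer percentages.
    """
    lesions = lesions.copy()
    if known_db is None or known_db.empty:
        warnings.warn("known-variant database is empty; all lesions flagged novel",
                      stacklevel=2)
        lesions["known"] = False
    else:
        merged = {
            str(chrom): _merged_intervals(sub)
            for chrom, sub in known_db.groupby("chrom")
        }
        flags = []
        for _, row in lesions.iterrows():
            iv = merged.get(str(row["chrom"]))
            start, end = int(row["start"]), int(row["end"])
            cov = 0
            if iv is not None and iv.size:
                i = int(np.searchsorted(iv[:, 1], start, side="right"))
                j = int(np.searchsorted(iv[:, 0], end, side="left"))
                for s, e in iv[i:j]:
                    cov += max(0, min(end, e) - max(start, s))
            flags.append(cov / (end - start) >= min_overlap_fraction)
        lesions["known"] = flags

    n = len(lesions)
    n_known = int(lesions["known"].sum())
    n_novel = n - n_known
    pct_known = 100.0 * n_known / n if n else 0.0
    summary = {
        "n_total": n,
        "n_known": n_known,
        "n_novel": n_novel,
        "pct_known_exact": pct_known,
        "pct_novel_exact": 100.0 - pct_known if n else 0.0,
        "pct_known": int(round(pct_known)) if n else 0,
        "pct_novel": int(round(100.0 - pct_known)) if n else 0,
    }
    return lesions, summary


@dataclass
class RecurrenceProfile:
    """Distinct-sample recurrence counts per unit plus the histogram of how
    many units recur in k samples (k = 1..cohort size)."""

    unit: str  # "cytoband" | "interval"
    counts: pd.DataFrame  # cytoband: [band, n_samples]; interval: [chrom, start, end, n_samples]
    histogram: dict[int, int]
    cohort_size: int


def _sample_coverage(
    lesions: pd.DataFrame,
) -> dict[str, list[tuple[int, int, int]]]:
    """Per chromosome, elementary intervals with the count of distinct
    samples whose (merged) lesions cover them.  Zero-count gaps are omitted."""
    out: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, sub in lesions.groupby("chrom"):
        events: dict[int, int] = {}
        for _, sample_sub in sub.groupby("sample_id"):
            for s, e in _merged_intervals(sample_sub):
                events[int(s)] = events.get(int(s), 0) + 1
                events[int(e)] = events.get(int(e), 0) - 1
        bounds = sorted(events)
        depth = 0
        spans: list[tuple[int, int, int]] = []
        for a, b in zip(bounds, bounds[1:]):
            depth += events[a]
            if depth > 0:
                spans.append((a, b, depth))
        out[str(chrom)] = spans
    return out


def _constant_runs(
    spans: list[tuple[int, int, int]]
) -> list[tuple[int, int, int]]:
    """Coalesce adjacent elementary intervals with equal count."""
    runs: list[list[int]] = []
    for s, e, c in spans:
        if runs and runs[-1][1] == s and runs[-1][2] == c:
            runs[-1][1] = e
        else:
            runs.append([s, e, c])
    return [tuple(r) for r in runs]


def recurrence_profile(
    lesions: pd.DataFrame,
    cohort_size: int,
    unit: str = "cytoband",
    cytobands: CytobandMap | None = None,
) -> RecurrenceProfile:
    """Count distinct samples (not lesions) per unit.

    ``unit="cytoband"`` counts samples with >= 1 lesion overlapping each band;
    ``unit="interval"`` builds maximal constant-count genomic runs from a
    sweep line over per-sample merged lesion intervals.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if unit == "cytoband":
        if cytobands is None:
            raise ValueError("cytoband unit requires a CytobandMap")
        per_band: dict[str, set[str]] = {}
        for _, row in lesions.iterrows():
            for band in cytobands.bands_for(
                row["chrom"], int(row["start"]), int(row["end"])
            ):
                per_band.setdefault(band, set()).add(row["sample_id"])
        counts = pd.DataFrame(
            [{"band": b, "n_samples": len(s)} for b, s in sorted(per_band.items())],
            columns=["band", "n_samples"],
        )
        ks = counts["n_samples"].tolist()
    elif unit == "interval":
        rows = []
        coverage = _sample_coverage(lesions)
        for chrom in sorted(coverage, key=_chrom_sort_key):
            for s, e, c in _constant_runs(coverage[chrom]):
                rows.append({"chrom": chrom, "start": s, "end": e, "n_samples": c})
        counts = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_samples"])
        ks = counts["n_samples"].tolist()
    else:
        raise ValueError(f"unknown unit {unit!r}")

    histogram = {k: 0 for k in range(1, cohort_size + 1)}
    for k in ks:
        histogram[int(k)] = histogram.get(int(k), 0) + 1
    return RecurrenceProfile(unit, counts, histogram, cohort_size)


@dataclass
class MarResult:
    """A minimal affected region: the shortest interval affected by any
    imbalance in a (strict-majority) share of the cohort."""

    chrom: str
    start: int
    end: int
    length: int
    n_affected: int
    cohort_size: int
    frequency: float
    mean_cn: float | None
    dominant_category: str | None
    status: str = "ok"


def define_mar(
    lesions: pd.DataFrame,
    cohort_size: int,
    min_fraction: float = 0.5,
) -> tuple[MarResult | None, list[MarResult]]:
    """Sweep-line MAR discovery.

    Candidate regions are maximal constant-count runs whose distinct-sample
    count strictly exceeds ``cohort_size * min_fraction``.  The MAR is the
    candidate with the highest count, ties broken by smallest length, then by
    genomic order.  Returns (MAR or None, all candidates sorted); when no
    position reaches the majority the MAR is None and the candidate list
    empty — an explanatory status, not an error.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    threshold = cohort_size * min_fraction
    coverage = _sample_coverage(lesions)

    candidates: list[MarResult] = []
    for chrom in sorted(coverage, key=_chrom_sort_key):
        spans = coverage[chrom]
        # coalesce at the candidate level: runs of count == c above threshold
        above = [(s, e, c) for s, e, c in spans if c > threshold]
        for s, e, c in _constant_runs(above):
            candidates.append(
                _make_mar(lesions, chrom, s, e, c, cohort_size)
            )

    if not candidates:
        return None, []

    candidates.sort(
        key=lambda m: (-m.n_affected, m.length, _chrom_sort_key(m.chrom), m.start)
    )
    return candidates[0], candidates


def _make_mar(
    lesions: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    count: int,
    cohort_size: int,
) -> MarResult:
    ov = lesions[
        (lesions["chrom"] == chrom)
        & (lesions["start"].astype(int) < end)
        & (lesions["end"].astype(int) > start)
    ]
    mean_cn: float | None = None
    dominant: str | None = None
    if not ov.empty and "cn_estimate" in ov.columns:
        per_sample = ov.groupby("sample_id")["cn_estimate"].mean()
        mean_cn = round(float(per_sample.mean()), 1)
    if not ov.empty and "category" in ov.columns:
        vc = ov["category"].value_counts()
        top = vc[vc == vc.max()].index.tolist()
        dominant = sorted(top)[0]
    return MarResult(
        chrom=chrom,
        start=int(start),
        end=int(end),
        length=int(end - start),
        n_affected=int(count),
        cohort_size=cohort_size,
        frequency=count / cohort_size,
        mean_cn=mean_cn,
        dominant_category=dominant,
    )


@dataclass(frozen=True)
class OverlapTestResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    percent_of_a: float  # exact value; report rounds to integer
    pvalue: float

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent_of_a))


def overlap_significance(
    bands_a: set[str] | list[str],
    bands_b: set[str] | list[str],
    universe_size: int,
) -> OverlapTestResult:
    """Hypergeometric enrichment of the overlap between two band sets.

    p = P(X >= |A∩B|) for X ~ Hypergeom(N=universe, K=|A|, n=|B|); the
    percentage is reported relative to |A|.
    """
    a, b = set(bands_a), set(bands_b)
    if universe_size < len(a | b):
        raise InvalidUniverseError(
            f"universe {universe_size} smaller than |A∪B| = {len(a | b)}"
        )
    k = len(a & b)
    pct = 100.0 * k / len(a) if a else 0.0
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return OverlapTestResult(len(a), len(b), k, universe_size, pct, min(p, 1.0))
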