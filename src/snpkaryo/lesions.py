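"""Lesion classification and filtering.

Segments become lesions by combining two independent readouts:

* the copy-number state from the segment mean LRR — gain at or above a gain
  threshold (default +0.15 log2 units), loss at or below a loss threshold
  (default -0.2), neutral otherwise, with the point copy-number estimate
  CN = 2 * 2**mean_lrr;
* the LOH state from the B-allele frequencies of germline-heterozygous SNPs
  inside the segment — LOH is called when at least ``min_informative`` such
  SNPs exist and at least ``min_hom_fraction`` of them have collapsed into the
  homozygous BAF bands (<= 0.1 or >= 0.9).

The two states map onto five lesion categories: amplification with/without
LOH, deletion with/without LOH, and copy-neutral LOH (acquired uniparental
disomy, aUPD).  A copy-neutral segment without LOH is no lesion.

Because an aUPD region is invisible in LRR (CN stays 2), copy-neutral LOH is
detected on a second channel: within each copy-neutral segment the mirrored
BAF series |BAF - 0.5| of the informative SNPs is segmented with the same
recursive splitter, and sub-regions that pass the LOH call while remaining
copy-neutral in LRR become aUPD lesions.

Filtering applies the study's exclusion rules: sex chromosomes and the
mitochondrion are dropped, copy-number lesions shorter than 1 kb and aUPD
regions shorter than 1 Mb are dropped, and lesions overlapping blacklisted
cytobands (T-cell-receptor rearrangement artifacts when the matched normal is
a T lymphocyte) are dropped.  Every rejection is logged with the rule name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import (
    RatioSeries,
    Segment,
    SegmentationParams,
    compute_ratio_series,
    segment_with_precut,
)

__all__ = [
    "CN_GAIN",
    "CN_NEUTRAL",
    "CN_LOSS",
    "CATEGORIES",
    "CATEGORY_COLORS",
    "LohParams",
    "LohCall",
    "FilterPolicy",
    "CoordinateError",
    "call_cn_state",
    "call_loh",
    "classify_five_state",
    "call_lesions",
    "apply_filters",
]

CN_GAIN = "gain"
CN_NEUTRAL = "neutral"
CN_LOSS = "loss"

AMP_LOH = "AMP_LOH"
AMP_NO_LOH = "AMP_NO_LOH"
AUPD = "AUPD"
DEL_LOH = "DEL_LOH"
DEL_NO_LOH = "DEL_NO_LOH"
NEUTRAL = "NEUTRAL"

CATEGORIES = (AMP_LOH, AMP_NO_LOH, AUPD, DEL_LOH, DEL_NO_LOH)

#: Karyoview color convention (RGB): light blue, dark blue, green, violet,
#: cyclamen.
CATEGORY_COLORS = {
    AMP_LOH: (135, 206, 250),
    AMP_NO_LOH: (0, 0, 139),
    AUPD: (0, 128, 0),
    DEL_LOH: (148, 0, 211),
    DEL_NO_LOH: (255, 116, 176),
}

LESION_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "n_markers",
    "mean_lrr",
    "cn_estimate",
    "cn_state",
    "loh",
    "category",
    "length",
    "n_informative",
]


class CoordinateError(ValueError):
    """A genomic coordinate refers to an unknown chromosome or is degenerate."""


def call_cn_state(
    mean_lrr: float,
    gain_threshold_lrr: float = 0.15,
    loss_threshold_lrr: float = -0.2,
) -> tuple[str, float]:
    """Copy-number state and point estimate from a segment mean LRR.

    cn_estimate = 2 * 2**mean_lrr, reported to one decimal.
    """
    if not loss_threshold_lrr < 0 < gain_threshold_lrr:
        raise ValueError("thresholds must satisfy loss < 0 < gain")
    cn = round(2.0 * 2.0 ** float(mean_lrr), 1)
    if mean_lrr >= gain_threshold_lrr:
        return CN_GAIN, cn
    if mean_lrr <= loss_threshold_lrr:
        return CN_LOSS, cn
    return CN_NEUTRAL, cn


@dataclass(frozen=True)
class LohParams:
    """LOH-calling thresholds.

    ``hom_band`` defines the homozygous BAF bands [0, hom_band] and
    [1-hom_band, 1]; ``min_hom_fraction`` of the informative (germline
    heterozygous) SNPs must fall in them; fewer than ``min_informative``
    informative SNPs yields loh=False with an "uninformative" status.
    """

    min_informative: int = 10
    min_hom_fraction: float = 0.9
    hom_band: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.min_hom_fraction <= 1.0:
            raise ValueError("min_hom_fraction must lie in (0, 1]")
        if not 0.0 <= self.hom_band < 0.5:
            raise ValueError("hom_band must lie in [0, 0.5)")
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")


@dataclass(frozen=True)
class LohCall:
    loh: bool
    n_informative: int
    status: str  # "ok" | "uninformative"


def _informative_positions_paired(
    normal: pd.DataFrame, chrom: str, start: int, end: int
) -> np.ndarray:
    m = (
        (normal["chrom"].to_numpy() == chrom)
        & (normal["pos"].to_numpy() >= start)
        & (normal["pos"].to_numpy() < end)
        & (normal["genotype"].to_numpy() == "AB")
    )
    return normal["pos"].to_numpy()[m]


def _informative_positions_baseline(
    panel: list[pd.DataFrame], chrom: str, start: int, end: int
) -> np.ndarray:
    """Unpaired proxy: SNPs heterozygous in at least half of the reference
    panel count as pseudo-informative (lower confidence than paired mode)."""
    het_count: np.ndarray | None = None
    pos: np.ndarray | None = None
    for ref in panel:
        m = (
            (ref["chrom"].to_numpy() == chrom)
            & (ref["pos"].to_numpy() >= start)
            & (ref["pos"].to_numpy() < end)
            & ref["baf"].notna().to_numpy()
        )
        sub = ref.loc[m]
        if pos is None:
            pos = sub["pos"].to_numpy()
            het_count = np.zeros(pos.size)
        het_count += (sub["genotype"].to_numpy() == "AB").astype(float)
    if pos is None:
        return np.array([], dtype=np.int64)
    return pos[het_count >= len(panel) / 2.0]


def call_loh(
    chrom: str,
    start: int,
    end: int,
    tumor: pd.DataFrame,
    normal: pd.DataFrame | None = None,
    panel: list[pd.DataFrame] | None = None,
    params: LohParams | None = None,
) -> LohCall:
    """LOH state of the region [start, end) on ``chrom``.

    Paired mode (``normal`` given) uses SNPs genotyped AB in the matched
    normal as informative markers; baseline mode (``panel`` given) falls back
    to SNPs heterozygous in at least half the reference panel.
    """
    params = params or LohParams()
    if normal is not None:
        info_pos = _informative_positions_paired(normal, chrom, start, end)
    elif panel:
        info_pos = _informative_positions_baseline(panel, chrom, start, end)
    else:
        raise ValueError("call_loh requires a matched normal or a baseline panel")

    n_info = int(info_pos.size)
    if n_info < params.min_informative:
        return LohCall(False, n_info, "uninformative")

    tmask = (tumor["chrom"].to_numpy() == chrom) & np.isin(
        tumor["pos"].to_numpy(), info_pos
    )
    baf = tumor.loc[tmask, "baf"].to_numpy(dtype=float)
    hom = (baf <= params.hom_band) | (baf >= 1.0 - params.hom_band)
    frac = float(np.mean(hom)) if baf.size else 0.0
    return LohCall(frac >= params.min_hom_fraction, n_info, "ok")


def classify_five_state(cn_state: str, loh: bool) -> str:
    """Total mapping of (copy-number state, LOH flag) onto the five lesion
    categories; a copy-neutral, heterozygosity-retaining segment is NEUTRAL
    (not a lesion)."""
    table = {
        (CN_GAIN, True): AMP_LOH,
        (CN_GAIN, False): AMP_NO_LOH,
        (CN_NEUTRAL, True): AUPD,
        (CN_NEUTRAL, False): NEUTRAL,
        (CN_LOSS, True): DEL_LOH,
        (CN_LOSS, False): DEL_NO_LOH,
    }
    key = (cn_state, bool(loh))
    if key not in table:
        raise ValueError(f"invalid (cn_state, loh) pair: {key!r}")
    return table[key]


def _lesion_row(
    sample_id: str,
    chrom: str,
    start: int,
    end: int,
    n_markers: int,
    mean_lrr: float,
    cn_est: float,
    cn_state: str,
    loh: bool,
    category: str,
    n_informative: int,
) -> dict:
    return {
        "sample_id": sample_id,
        "chrom": chrom,
        "start": start,
        "end": end,
        "n_markers": n_markers,
        "mean_lrr": mean_lrr,
        "cn_estimate": cn_est,
        "cn_state": cn_state,
        "loh": loh,
        "category": category,
        "length": end - start,
        "n_informative": n_informative,
    }


def _aupd_in_segment(
    seg: Segment,
    sample_id: str,
    tumor: pd.DataFrame,
    ratio_pos: np.ndarray,
    ratio_val: np.ndarray,
    normal: pd.DataFrame | None,
    panel: list[pd.DataFrame] | None,
    loh_params: LohParams,
    seg_params: SegmentationParams,
    gain_threshold_lrr: float,
    loss_threshold_lrr: float,
) -> list[dict]:
    """Copy-neutral LOH sub-regions inside a copy-neutral LRR segment.

    Segments the mirrored BAF series |BAF - 0.5| of the informative SNPs; a
    sub-region becomes an aUPD lesion when the LOH call fires and its mean
    ratio LRR stays copy-neutral.
    """
    if normal is not None:
        info_pos = _informative_positions_paired(normal, seg.chrom, seg.start, seg.end)
    else:
        info_pos = _informative_positions_baseline(panel, seg.chrom, seg.start, seg.end)
    if info_pos.size < 2 * seg_params.min_markers:
        return []
    tmask = (tumor["chrom"].to_numpy() == seg.chrom) & np.isin(
        tumor["pos"].to_numpy(), info_pos
    )
    sub = tumor.loc[tmask]
    mbaf = np.abs(sub["baf"].to_numpy(dtype=float) - 0.5)
    series = RatioSeries(seg.chrom, sub["pos"].to_numpy(), mbaf, "paired")
    rows: list[dict] = []
    for ss in segment_with_precut(series, seg_params):
        lc = call_loh(
            seg.chrom, ss.start, ss.end, tumor, normal=normal, panel=panel,
            params=loh_params,
        )
        if not lc.loh:
            continue
        m = (ratio_pos >= ss.start) & (ratio_pos < ss.end)
        if not m.any():
            continue
        mean_lrr = float(np.mean(ratio_val[m]))
        cn_state, cn_est = call_cn_state(
            mean_lrr, gain_threshold_lrr, loss_threshold_lrr
        )
        if cn_state != CN_NEUTRAL:
            continue  # copy-number change there is already a CN lesion's job
        rows.append(
            _lesion_row(
                sample_id, seg.chrom, ss.start, ss.end, int(m.sum()), mean_lrr,
                cn_est, cn_state, True, AUPD, lc.n_informative,
            )
        )
    return rows


def call_lesions(
    segments: list[Segment],
    sample_id: str,
    tumor: pd.DataFrame,
    normal: pd.DataFrame | None = None,
    panel: list[pd.DataFrame] | None = None,
    gain_threshold_lrr: float = 0.15,
    loss_threshold_lrr: float = -0.2,
    loh_params: LohParams | None = None,
    seg_params: SegmentationParams | None = None,
    detect_aupd: bool = True,
) -> pd.DataFrame:
    """Classify every segment of one sample into the five-state lesion table.

    Copy-neutral segments without segment-wide LOH are additionally scanned
    for internal copy-neutral LOH (aUPD) sub-regions on the mirrored-BAF
    channel; NEUTRAL segments with nothing found contribute no lesion.
    """
    loh_params = loh_params or LohParams()
    seg_params = seg_params or SegmentationParams()
    ratio: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if detect_aupd and segments:
        mode = "paired" if normal is not None else "baseline"
        reference = normal if normal is not None else panel
        for series in compute_ratio_series(tumor, reference, mode):
            ratio[series.chrom] = (series.positions, series.values)

    rows = []
    for seg in segments:
        cn_state, cn_est = call_cn_state(
            seg.mean_lrr, gain_threshold_lrr, loss_threshold_lrr
        )
        loh = call_loh(
            seg.chrom, seg.start, seg.end, tumor, normal=normal, panel=panel,
            params=loh_params,
        )
        category = classify_five_state(cn_state, loh.loh)
        if category == NEUTRAL:
            if detect_aupd:
                ratio_pos, ratio_val = ratio[seg.chrom]
                rows.extend(
                    _aupd_in_segment(
                        seg, sample_id, tumor, ratio_pos, ratio_val, normal,
                        panel, loh_params, seg_params,
                        gain_threshold_lrr, loss_threshold_lrr,
                    )
                )
            continue
        rows.append(
            _lesion_row(
                sample_id, seg.chrom, seg.start, seg.end, seg.n_markers,
                seg.mean_lrr, cn_est, cn_state, loh.loh, category,
                loh.n_informative,
            )
        )
    return pd.DataFrame(rows, columns=LESION_COLUMNS)


def _norm_chrom(name: str) -> str:
    s = str(name)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("M", "MT"):
        return "MT"
    return s.upper()


@dataclass(frozen=True)
class FilterPolicy:
    """The study's exclusion rules for called lesions."""

    excluded_chromosomes: frozenset[str] = frozenset({"X", "Y", "MT"})
    min_cnv_length: int = 1_000
    min_aupd_length: int = 1_000_000
    blacklist_cytobands: frozenset[str] = frozenset({"7p34", "7p14.1", "14q11.2"})

    def __post_init__(self) -> None:
        if self.min_cnv_length <= 0 or self.min_aupd_length <= 0:
            raise ValueError("minimum lengths must be > 0")

    def chromosome_excluded(self, chrom: str) -> bool:
        return _norm_chrom(chrom) in {_norm_chrom(c) for c in self.excluded_chromosomes}


def apply_filters(
    lesions: pd.DataFrame,
    policy: FilterPolicy | None = None,
    cytobands: "CytobandMap | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion rules; returns (kept lesions, rejection log).

    The rejection log has one row per dropped lesion with the name of the
    first rule that matched.  Filtering is idempotent: re-applying it to the
    kept set drops nothing.
    """
    policy = policy or FilterPolicy()
    keep_idx: list[int] = []
    rejections: list[dict] = []
    for idx, row in lesions.iterrows():
        rule = None
        length = int(row["end"]) - int(row["start"])
        if policy.chromosome_excluded(row["chrom"]):
            rule = "excluded_chromosome"
        elif row["category"] != AUPD and length < policy.min_cnv_length:
            rule = "min_cnv_length"
        elif row["category"] == AUPD and length < policy.min_aupd_length:
            rule = "min_aupd_length"
        elif policy.blacklist_cytobands and cytobands is not None:
            if row["chrom"] not in cytobands.chromosomes:
                raise CoordinateError(
                    f"lesion chromosome {row['chrom']!r} absent from cytoband map"
                )
            bands = cytobands.bands_for(row["chrom"], int(row["start"]), int(row["end"]))
            hit = set(bands) & set(policy.blacklist_cytobands)
            if hit:
                rule = "blacklist_cytoband"
        if rule is None:
            keep_idx.append(idx)
        else:
            rejections.append(
                {
                    "sample_id": row.get("sample_id", ""),
                    "chrom": row["chrom"],
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "category": row["category"],
                    "rule": rule,
                }
            )
    kept = lesions.loc[keep_idx].reset_index(drop=True)
    log = pd.DataFrame(
        rejections,
        columns=["sample_id", "chrom", "start", "end", "category", "rule"],
    )
    return kept, log
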