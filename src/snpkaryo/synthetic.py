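"""Synthetic SNP-array cohort generation.

Emulates the marker-level signal a genome-wide SNP array produces for a
tumor/matched-normal cohort: a near-diploid baseline with log-R-ratio (LRR)
centred at 0, B-allele-frequency (BAF) clusters at the allelic ratios implied
by genotype and copy number, and implanted somatic lesions — amplifications,
deletions and copy-neutral LOH (acquired uniparental disomy, aUPD).  The
signal convention is the standard one: a region at total copy number CN has
expected LRR = log2(CN/2), so CN 4 sits at +1 and a one-copy loss at -1.

Every downstream stage of the pipeline (segmentation, lesion calling,
recurrence analysis) is testable against the truth tables this module emits,
with no external data download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LRR_FLOOR",
    "NoiseModel",
    "TruthLesion",
    "ProbeMap",
    "Cohort",
    "SpecificationError",
    "build_probe_map",
    "simulate_sample",
    "simulate_cohort",
    "make_cytoband_table",
]

#: LRR assigned to homozygous deletions (CN=0), where log2(CN/2) diverges.
LRR_FLOOR = -5.0

TRUTH_COLUMNS = ["sample_id", "chrom", "start", "end", "cn", "loh"]
PROBE_COLUMNS = ["probe_id", "chrom", "pos", "lrr", "baf", "genotype"]


class SpecificationError(ValueError):
    """An invalid simulation specification (geometry, overlap, parameters)."""


@dataclass(frozen=True)
class NoiseModel:
    """Marker-level noise: Gaussian LRR noise and truncated-Gaussian BAF noise.

    Parameters
    ----------
    lrr_sd : float
        Standard deviation of additive Gaussian noise on LRR (log2 units).
    baf_sd : float
        Standard deviation of Gaussian noise on BAF, clipped to [0, 1].
    het_fraction : float
        Probability that a germline SNP is heterozygous (AB).
    """

    lrr_sd: float = 0.2
    baf_sd: float = 0.03
    het_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.lrr_sd < 0 or self.baf_sd < 0:
            raise SpecificationError("noise standard deviations must be >= 0")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise SpecificationError("het_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TruthLesion:
    """An implanted somatic lesion: half-open [start, end), total copy number
    ``cn`` and an LOH flag.

    A copy-neutral (CN=2) lesion must carry LOH — otherwise it is no lesion at
    all — and a lesion at CN<=1 has necessarily lost heterozygosity.
    """

    chrom: str
    start: int
    end: int
    cn: int
    loh: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SpecificationError(
                f"lesion end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.cn < 0:
            raise SpecificationError("copy number must be >= 0")
        if self.cn == 2 and not self.loh:
            raise SpecificationError("a CN=2 lesion must carry LOH (aUPD)")
        if self.cn <= 1 and not self.loh:
            raise SpecificationError("CN<=1 implies loss of heterozygosity")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProbeMap:
    """Ordered marker positions per chromosome plus marker kind (SNP vs
    copy-number-only) and chromosome lengths."""

    lengths: dict[str, int]
    positions: dict[str, np.ndarray]
    is_snp: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.lengths:
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            snp = np.asarray(self.is_snp[chrom], dtype=bool)
            if pos.size != snp.size:
                raise SpecificationError(f"{chrom}: positions/kind length mismatch")
            if pos.size and not np.all(np.diff(pos) > 0):
                raise SpecificationError(f"{chrom}: positions not strictly increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > self.lengths[chrom]):
                raise SpecificationError(f"{chrom}: probe outside chromosome bounds")
            self.positions[chrom] = pos
            self.is_snp[chrom] = snp

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def n_probes(self) -> int:
        return sum(int(p.size) for p in self.positions.values())

    def probe_ids(self, chrom: str) -> np.ndarray:
        kind = np.where(self.is_snp[chrom], "S", "C")
        return np.char.add(
            np.char.add(kind, f"_{chrom}_"),
            self.positions[chrom].astype(str),
        )


def build_probe_map(
    chromosome_spec: list[tuple[str, int]],
    spacing: int = 1000,
    snp_fraction: float = 0.5,
    seed: int | None = None,
    jitter: int | None = None,
) -> ProbeMap:
    """Place probes at regular ``spacing`` with uniform jitter < spacing/2.

    ``snp_fraction`` of the probes on each chromosome (rounded) are marked as
    SNP probes, chosen at random; the rest are copy-number-only probes.
    ``jitter`` defaults to spacing//4 and must stay below spacing/2 so that
    positions remain strictly increasing.
    """
    if spacing < 1:
        raise SpecificationError("spacing must be >= 1")
    if not 0.0 <= snp_fraction <= 1.0:
        raise SpecificationError("snp_fraction must lie in [0, 1]")
    if jitter is None:
        jitter = spacing // 4
    if not 0 <= jitter < spacing / 2:
        raise SpecificationError("jitter must satisfy 0 <= jitter < spacing/2")

    rng = np.random.default_rng(seed)
    lengths: dict[str, int] = {}
    positions: dict[str, np.ndarray] = {}
    is_snp: dict[str, np.ndarray] = {}
    for name, length in chromosome_spec:
        if length < spacing:
            raise SpecificationError(f"{name}: length {length} < spacing {spacing}")
        n = length // spacing
        base = np.arange(n, dtype=np.int64) * spacing + max(spacing // 2, 1)
        if jitter > 0:
            base = base + rng.integers(-jitter, jitter + 1, size=n)
        pos = np.clip(base, 1, length)
        snp = np.zeros(n, dtype=bool)
        n_snp = int(round(snp_fraction * n))
        if n_snp:
            snp[rng.choice(n, size=n_snp, replace=False)] = True
        lengths[name] = int(length)
        positions[name] = pos
        is_snp[name] = snp
    return ProbeMap(lengths=lengths, positions=positions, is_snp=is_snp)


def _check_lesions(pmap: ProbeMap, truth: list[TruthLesion]) -> None:
    by_chrom: dict[str, list[TruthLesion]] = {}
    for les in truth:
        if les.chrom not in pmap.lengths:
            raise SpecificationError(f"lesion chromosome {les.chrom!r} not in probe map")
        if les.end - 1 > pmap.lengths[les.chrom]:
            raise SpecificationError(
                f"lesion {les.chrom}:{les.start}-{les.end} exceeds chromosome length"
            )
        by_chrom.setdefault(les.chrom, []).append(les)
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda l: l.start)
        for a, b in zip(lst, lst[1:]):
            if b.start < a.end:
                raise SpecificationError(
                    f"overlapping lesions on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def _expected_lrr(cn: int, purity: float) -> float:
    mix = purity * cn + (1.0 - purity) * 2.0
    if mix <= 0:
        return LRR_FLOOR
    return math.log2(mix / 2.0)


def _call_genotype(baf: np.ndarray, is_snp: np.ndarray, nocall: np.ndarray) -> np.ndarray:
    geno = np.full(baf.shape, "", dtype=object)
    geno[is_snp] = "AB"
    geno[is_snp & (baf <= 0.2)] = "AA"
    geno[is_snp & (baf >= 0.8)] = "BB"
    geno[is_snp & nocall] = "NoCall"
    return geno


def simulate_sample(
    pmap: ProbeMap,
    truth: list[TruthLesion],
    noise: NoiseModel,
    matched_normal: bool = True,
    purity: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Simulate one tumor sample (and optionally its matched normal).

    The germline genotype of each SNP probe is drawn once (AB with probability
    ``noise.het_fraction``, else AA/BB equiprobably) and shared by tumor and
    normal.  Inside a lesion of copy number CN the tumor LRR is centred at
    log2(CN/2) (diluted by ``purity`` if < 1) and germline-heterozygous SNPs
    move to the BAF clusters implied by the surviving allele counts: with LOH
    one parental allele is lost entirely (BAF -> 0 or 1); without LOH both
    alleles survive and the B-allele count is drawn uniformly from 1..CN-1.
    """
    if not 0.0 < purity <= 1.0:
        raise SpecificationError("purity must lie in (0, 1]")
    _check_lesions(pmap, truth)
    if rng is None:
        rng = np.random.default_rng(seed)

    tumor_frames: list[pd.DataFrame] = []
    normal_frames: list[pd.DataFrame] = []
    for chrom in pmap.chromosomes:
        pos = pmap.positions[chrom]
        snp = pmap.is_snp[chrom]
        n = pos.size

        # germline state
        geno_code = np.zeros(n, dtype=np.int8)  # 0=AA 1=AB 2=BB; CN-only probes ignored
        u = rng.random(n)
        geno_code[u < noise.het_fraction] = 1
        geno_code[(u >= noise.het_fraction) & (u >= (1 + noise.het_fraction) / 2)] = 2
        germ_baf = np.where(geno_code == 1, 0.5, np.where(geno_code == 2, 1.0, 0.0))

        lrr_mean = np.zeros(n)
        baf_mean = germ_baf.copy()
        nocall = np.zeros(n, dtype=bool)

        for les in (l for l in truth if l.chrom == chrom):
            m = (pos >= les.start) & (pos < les.end)
            lrr_mean[m] = _expected_lrr(les.cn, purity)
            het = m & snp & (geno_code == 1)
            nhet = int(het.sum())
            if les.cn == 0:
                baf_mean[m & snp] = 0.5
                nocall[m & snp] = True
            elif nhet:
                if les.loh:
                    n_b = les.cn * rng.integers(0, 2, size=nhet)
                else:
                    n_b = rng.integers(1, les.cn, size=nhet)
                baf_mean[het] = n_b / les.cn

        def _render(lmean: np.ndarray, bmean: np.ndarray, ncall: np.ndarray) -> pd.DataFrame:
            lrr = lmean + (rng.normal(0.0, noise.lrr_sd, size=n) if noise.lrr_sd else 0.0)
            baf = bmean + (rng.normal(0.0, noise.baf_sd, size=n) if noise.baf_sd else 0.0)
            baf = np.clip(baf, 0.0, 1.0)
            baf = np.where(snp, baf, np.nan)
            return pd.DataFrame(
                {
                    "probe_id": pmap.probe_ids(chrom),
                    "chrom": chrom,
                    "pos": pos,
                    "lrr": lrr,
                    "baf": baf,
                    "genotype": _call_genotype(baf, snp, ncall),
                }
            )

        tumor_frames.append(_render(lrr_mean, baf_mean, nocall))
        if matched_normal:
            normal_frames.append(
                _render(np.zeros(n), germ_baf, np.zeros(n, dtype=bool))
            )

    tumor = pd.concat(tumor_frames, ignore_index=True)
    normal = pd.concat(normal_frames, ignore_index=True) if matched_normal else None
    return tumor, normal


@dataclass
class Cohort:
    """A simulated cohort: per-sample tumor/normal probe tables plus the truth
    table of implanted lesions."""

    pmap: ProbeMap
    samples: dict[str, tuple[pd.DataFrame, pd.DataFrame | None]]
    truth: pd.DataFrame
    carrier_ids: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _draw_private_lesions(
    pmap: ProbeMap,
    n_lesions: int,
    occupied: list[TruthLesion],
    forbidden: tuple[str, int, int] | None,
    rng: np.random.Generator,
    size_range: tuple[int, int] = (20_000, 200_000),
    cns: tuple[int, ...] = (1, 3, 4),
    aupd_rate: float = 0.15,
    aupd_size_range: tuple[int, int] = (1_000_000, 3_000_000),
) -> list[TruthLesion]:
    chroms = pmap.chromosomes
    out: list[TruthLesion] = []
    taken = list(occupied)
    for _ in range(n_lesions):
        for _attempt in range(1000):
            chrom = chroms[rng.integers(0, len(chroms))]
            if rng.random() < aupd_rate:
                lo, hi = aupd_size_range
                cn, loh = 2, True
            else:
                lo, hi = size_range
                cn = int(cns[rng.integers(0, len(cns))])
                loh = cn <= 1
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            length = pmap.lengths[chrom]
            if size >= length:
                continue
            start = int(rng.integers(1, length - size))
            end = start + size
            if forbidden is not None and chrom == forbidden[0]:
                if start < forbidden[2] and forbidden[1] < end:
                    continue
            clash = any(
                t.chrom == chrom and start < t.end and t.start < end for t in taken
            )
            if clash:
                continue
            les = TruthLesion(chrom, start, end, cn, loh)
            out.append(les)
            taken.append(les)
            break
        else:  # pragma: no cover - pathological geometry
            raise SpecificationError("could not place private lesion without overlap")
    return out


def simulate_cohort(
    pmap: ProbeMap,
    n_samples: int,
    shared_lesion: TruthLesion | None,
    carrier_fraction: float,
    private_lesions_per_sample: int,
    noise: NoiseModel,
    seed: int | None = None,
    purity: float = 1.0,
    matched_normals: bool = True,
) -> Cohort:
    """Simulate a cohort with one shared (recurrent) lesion implanted in
    exactly ``round(carrier_fraction * n_samples)`` samples plus
    ``private_lesions_per_sample`` independently drawn private lesions each.

    Private lesions never overlap one another within a sample, nor the shared
    locus in any sample, so the truth table's carrier count at the shared
    locus is exact by construction.
    """
    if n_samples < 1:
        raise SpecificationError("n_samples must be >= 1")
    if not 0.0 <= carrier_fraction <= 1.0:
        raise SpecificationError("carrier_fraction must lie in [0, 1]")
    if private_lesions_per_sample < 0:
        raise SpecificationError("private_lesions_per_sample must be >= 0")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    n_carriers = int(round(carrier_fraction * n_samples)) if shared_lesion else 0
    carrier_idx = (
        sorted(rng.choice(n_samples, size=n_carriers, replace=False).tolist())
        if n_carriers
        else []
    )
    carrier_set = {sample_ids[i] for i in carrier_idx}
    forbidden = (
        (shared_lesion.chrom, shared_lesion.start, shared_lesion.end)
        if shared_lesion
        else None
    )

    samples: dict[str, tuple[pd.DataFrame, pd.DataFrame | None]] = {}
    truth_rows: list[dict] = []
    for sid in sample_ids:
        lesions: list[TruthLesion] = []
        if shared_lesion and sid in carrier_set:
            lesions.append(shared_lesion)
        lesions.extend(
            _draw_private_lesions(
                pmap, private_lesions_per_sample, lesions, forbidden, rng
            )
        )
        tumor, normal = simulate_sample(
            pmap, lesions, noise, matched_normal=matched_normals, purity=purity, rng=rng
        )
        samples[sid] = (tumor, normal)
        for les in lesions:
            truth_rows.append(
                {
                    "sample_id": sid,
                    "chrom": les.chrom,
                    "start": les.start,
                    "end": les.end,
                    "cn": les.cn,
                    "loh": les.loh,
                }
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return Cohort(pmap=pmap, samples=samples, truth=truth, carrier_ids=sorted(carrier_set))


def make_cytoband_table(pmap: ProbeMap, bands_per_arm: int = 5) -> pd.DataFrame:
    """A simple cytoband table tiling each chromosome of a synthetic genome.

    The first half of each chromosome is the p arm, the second the q arm, each
    divided into ``bands_per_arm`` equal bands named e.g. ``1p3`` counting
    outward from the centromere, mirroring real nomenclature.  Coordinates are
    1-based half-open, matching the pipeline's internal convention.
    """
    rows = []
    for chrom, length in pmap.lengths.items():
        mid = length // 2
        arms = [("p", 1, mid + 1), ("q", mid + 1, length + 1)]
        for arm, a_start, a_end in arms:
            edges = np.linspace(a_start, a_end, bands_per_arm + 1).astype(int)
            idx = range(bands_per_arm, 0, -1) if arm == "p" else range(1, bands_per_arm + 1)
            for i, k in enumerate(idx):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(edges[i]),
                        "end": int(edges[i + 1]),
                        "band": f"{arm}{k}",
                        "stain": "gneg",
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])
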