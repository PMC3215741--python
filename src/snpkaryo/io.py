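"""File formats and configuration.

All genomic coordinates are 1-based half-open internally, so a region's
length is ``end - start``; BED export subtracts 1 from both bounds (BED being
0-based half-open, the length is preserved).  UCSC cytoBand and BED inputs
(0-based half-open) are shifted by +1 on both bounds at read time.

Readers validate and reject rather than coerce: unsorted probe files, BAF
values outside [0, 1] or malformed rows raise errors naming the offending
line.  Every writer produces files its own reader accepts.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .lesions import CATEGORY_COLORS, FilterPolicy, LohParams, LESION_COLUMNS
from .recurrence import CytobandMap
from .segmentation import SegmentationParams
from .synthetic import NoiseModel, TruthLesion, PROBE_COLUMNS, TRUTH_COLUMNS

__all__ = [
    "ValidationError",
    "ConfigError",
    "read_probe_file",
    "write_probe_file",
    "read_lesion_file",
    "write_lesion_file",
    "read_truth_table",
    "write_truth_table",
    "read_cytoband_file",
    "write_cytoband_file",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_known_bed",
    "convert_lesions_to_bed",
    "lesions_from_bed",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


class ValidationError(ValueError):
    """Input data violates the format contract (with the offending line)."""


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


# ---------------------------------------------------------------------------
# probe files

def read_probe_file(path: str | Path) -> pd.DataFrame:
    """Read a per-probe TSV (gzip-transparent) and validate it.

    Columns: probe_id, chrom, pos, lrr, baf, genotype (baf/genotype empty for
    copy-number-only probes).  Records must already be sorted by (chromosome
    grouped, position strictly increasing); unsorted input is an error, never
    silently re-sorted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"probe_id": str, "chrom": str, "genotype": str},
            keep_default_na=True,
        )
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"{path}: cannot parse probe file: {exc}") from exc
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    df["genotype"] = df["genotype"].fillna("")

    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna()
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # +1 header +1 one-based
        raise ValidationError(f"{path}: non-numeric position at line {line}")
    df["pos"] = pos.astype(np.int64)

    baf = df["baf"].to_numpy(dtype=float)
    out_of_range = np.nonzero(~np.isnan(baf) & ((baf < 0.0) | (baf > 1.0)))[0]
    if out_of_range.size:
        line = int(out_of_range[0]) + 2
        raise ValidationError(f"{path}: BAF outside [0, 1] at line {line}")

    chroms = df["chrom"].to_numpy()
    seen: dict[str, int] = {}
    prev_pos = None
    prev_chrom = None
    for i, (c, p) in enumerate(zip(chroms, df["pos"].to_numpy())):
        if c != prev_chrom:
            if c in seen:
                raise ValidationError(
                    f"{path}: chromosome {c!r} not contiguous at line {i + 2}"
                )
            seen[c] = i
            prev_chrom = c
            prev_pos = p
        else:
            if p <= prev_pos:
                raise ValidationError(
                    f"{path}: positions not strictly increasing at line {i + 2}"
                )
            prev_pos = p
    return df[PROBE_COLUMNS]


def write_probe_file(df: pd.DataFrame, path: str | Path) -> None:
    """Write a probe table as TSV (gzip when the path ends in .gz)."""
    df = df[PROBE_COLUMNS].copy()
    df["lrr"] = df["lrr"].map(lambda v: f"{v:.6f}")
    df["baf"] = df["baf"].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# lesion / truth tables

def write_lesion_file(lesions: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in LESION_COLUMNS if c in lesions.columns]
    lesions[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_lesion_file(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    required = {"sample_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if (df["end"] <= df["start"]).any():
        raise ValidationError(f"{path}: lesion with end <= start")
    return df


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})


# ---------------------------------------------------------------------------
# UCSC-style annotation files

def read_cytoband_file(path: str | Path) -> CytobandMap:
    """Read UCSC cytoBand.txt (0-based half-open) into the internal 1-based
    half-open convention."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str, "stain": str},
    )
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64) + 1
    return CytobandMap(df)


def write_cytoband_file(table: pd.DataFrame, path: str | Path) -> None:
    """Write an internal cytoband table back to UCSC convention."""
    out = table.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    out["end"] = out["end"].astype(np.int64) - 1
    out[["chrom", "start", "end", "band", "stain"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}: expected 2 columns at line {lineno}")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_known_bed(path: str | Path) -> pd.DataFrame:
    """Known-variant BED (0-based half-open) -> internal 1-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64) + 1
    return df


# ---------------------------------------------------------------------------
# BED export of lesions

BED9_HEADER = (
    '#track name="lesions" itemRgb="On"\n'
    "#chrom\tstart\tend\tname\tscore\tstrand\tthickStart\tthickEnd\titemRgb\n"
)


def convert_lesions_to_bed(lesions: pd.DataFrame, style: str = "bed9") -> str:
    """Render lesions as BED9 text with the karyoview color convention.

    Internal 1-based half-open [start, end) becomes BED [start-1, end-1), so
    the printed length is preserved.  The name column encodes
    ``sample_id:category`` so the text round-trips through
    :func:`lesions_from_bed`.
    """
    if style != "bed9":
        raise ValueError(f"unsupported BED style {style!r}")
    lines = [BED9_HEADER.rstrip("\n")]
    for _, row in lesions.iterrows():
        start = int(row["start"]) - 1
        end = int(row["end"]) - 1
        rgb = ",".join(map(str, CATEGORY_COLORS.get(row["category"], (0, 0, 0))))
        name = f"{row['sample_id']}:{row['category']}"
        lines.append(
            f"{row['chrom']}\t{start}\t{end}\t{name}\t0\t.\t{start}\t{end}\t{rgb}"
        )
    return "\n".join(lines) + "\n"


def lesions_from_bed(text: str) -> pd.DataFrame:
    """Parse BED9 text produced by :func:`convert_lesions_to_bed` back into a
    (minimal) lesion table in internal coordinates."""
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValidationError(f"BED line with fewer than 4 columns: {line!r}")
        sid, _, category = parts[3].partition(":")
        rows.append(
            {
                "sample_id": sid,
                "chrom": parts[0],
                "start": int(parts[1]) + 1,
                "end": int(parts[2]) + 1,
                "category": category,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "category"])


# ---------------------------------------------------------------------------
# configuration

@dataclass
class GenomeConfig:
    chromosomes: list[dict]  # [{name, length}]
    spacing: int = 1000
    snp_fraction: float = 0.5
    jitter: int | None = None


@dataclass
class SharedLesionConfig:
    chrom: str = ""
    start: int = 0
    end: int = 0
    cn: int = 4
    loh: bool = False

    def to_lesion(self) -> TruthLesion | None:
        if not self.chrom:
            return None
        return TruthLesion(self.chrom, self.start, self.end, self.cn, self.loh)


@dataclass
class CohortConfig:
    n_samples: int = 20
    carrier_fraction: float = 0.55
    private_lesions_per_sample: int = 5
    purity: float = 1.0
    shared_lesion: SharedLesionConfig = field(default_factory=SharedLesionConfig)


@dataclass
class CallingConfig:
    gain_threshold_lrr: float = 0.15
    loss_threshold_lrr: float = -0.2
    loh: LohParams = field(default_factory=LohParams)


@dataclass
class MarConfig:
    min_fraction: float = 0.5


@dataclass
class TrainTestConfig:
    enabled: bool = False
    train_fraction: float = 0.5


@dataclass
class PipelineConfig:
    genome: GenomeConfig = None  # required
    noise: NoiseModel = field(default_factory=NoiseModel)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    calling: CallingConfig = field(default_factory=CallingConfig)
    filters: FilterPolicy = field(default_factory=FilterPolicy)
    mar: MarConfig = field(default_factory=MarConfig)
    train_test: TrainTestConfig = field(default_factory=TrainTestConfig)
    mode: str = "paired"  # "paired" | "baseline"
    n_baseline: int = 10  # healthy reference samples for baseline mode
    seed: int = 0
    write_probe_files: bool = False


_BLOCKS: dict[str, type] = {
    "genome": GenomeConfig,
    "noise": NoiseModel,
    "cohort": CohortConfig,
    "segmentation": SegmentationParams,
    "calling": CallingConfig,
    "filters": FilterPolicy,
    "mar": MarConfig,
    "train_test": TrainTestConfig,
}

_NESTED: dict[str, dict[str, type]] = {
    "cohort": {"shared_lesion": SharedLesionConfig},
    "calling": {"loh": LohParams},
}


def _build(cls: type, data: dict, path: str, nested: dict[str, type] | None = None) -> Any:
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = dict(data)
    for key, sub_cls in (nested or {}).items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = _build(sub_cls, kwargs[key], f"{path}.{key}")
    if cls is FilterPolicy:
        for key in ("excluded_chromosomes", "blacklist_cytobands"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown keys anywhere in the document are rejected; every block is
    validated against its owning type's invariants at load time.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    scalar_keys = {"mode", "n_baseline", "seed", "write_probe_files"}
    unknown = set(data) - set(_BLOCKS) - scalar_keys
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    if "genome" not in data:
        raise ConfigError(f"{path}: a 'genome' block is required")

    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name] or {}, name, _NESTED.get(name))
    for key in scalar_keys:
        if key in data:
            kwargs[key] = data[key]
    cfg = PipelineConfig(**kwargs)
    if cfg.mode not in ("paired", "baseline"):
        raise ConfigError(f"{path}: mode must be 'paired' or 'baseline'")
    return cfg


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
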