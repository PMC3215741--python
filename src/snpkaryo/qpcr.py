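"""Calibrator-free qPCR relative copy-number quantitation.

In a duplex TaqMan copy-number assay each well measures a target Ct (FAM) and
a reference Ct (VIC) from a gene present at two copies in a diploid genome.
Per well, dCt = Ct_target - Ct_reference; replicate wells of a sample give a
mean dCt and a sample standard deviation sigma_dCt used for QC (pass when
sigma_dCt < 0.15 cycles).

Without a calibrator sample the analysis anchors the scale on the cohort
itself: the median mean-dCt across QC-passing samples is assumed to represent
the reference copy number (2), and each sample's estimate is

    CN_i = reference_cn * 2 ** (anchor - dCt_i)

so one cycle less of dCt doubles the estimate.  Integer copy numbers are the
rounded estimates; the "amplified" readout is integer CN >= 3 by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "InsufficientReplicatesError",
    "NoAnchorError",
    "aggregate_wells",
    "copy_number_no_calibrator",
    "concordance",
    "simulate_wells",
]

WELL_COLUMNS = ["sample_id", "replicate", "ct_fam", "ct_vic"]
CALL_COLUMNS = ["sample_id", "mean_dct", "sd_dct", "cn_estimate", "cn_integer", "qc_pass"]


class InsufficientReplicatesError(ValueError):
    """A sample has fewer than the minimum number of replicate wells."""


class NoAnchorError(ValueError):
    """No QC-passing sample exists to anchor the calibrator-free scale."""


def aggregate_wells(
    wells: pd.DataFrame,
    min_replicates: int = 2,
    qc_sd: float = 0.15,
) -> pd.DataFrame:
    """Per-sample mean dCt, replicate standard deviation and QC flag.

    sigma_dCt uses the n-1 (sample) standard deviation, appropriate for the
    small replicate counts typical of these plates.
    """
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    for col in ("ct_fam", "ct_vic"):
        ct = wells[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(ct)) or np.any(ct <= 0) or np.any(ct >= 45):
            raise ValueError(f"{col}: Ct values must lie in (0, 45)")

    rows = []
    for sid, sub in wells.groupby("sample_id", sort=False):
        if sub["replicate"].duplicated().any():
            raise ValueError(f"{sid}: duplicate replicate indices")
        if len(sub) < min_replicates:
            raise InsufficientReplicatesError(
                f"{sid}: {len(sub)} replicate(s), need >= {min_replicates}"
            )
        dct = sub["ct_fam"].to_numpy(dtype=float) - sub["ct_vic"].to_numpy(dtype=float)
        sd = float(np.std(dct, ddof=1))
        rows.append(
            {
                "sample_id": sid,
                "n_replicates": len(sub),
                "mean_dct": float(np.mean(dct)),
                "sd_dct": sd,
                "qc_pass": sd < qc_sd,
            }
        )
    return pd.DataFrame(rows)


def copy_number_no_calibrator(
    calls: pd.DataFrame, reference_cn: float = 2.0
) -> tuple[pd.DataFrame, float]:
    """Calibrator-free copy-number estimates anchored on the QC-passing
    median dCt (assumed to sit at ``reference_cn`` copies).

    Returns the augmented table and the anchor dCt used.
    """
    qc = calls[calls["qc_pass"]]
    if qc.empty:
        raise NoAnchorError("no QC-passing sample to anchor the scale")
    anchor = float(qc["mean_dct"].median())
    out = calls.copy()
    out["cn_estimate"] = reference_cn * 2.0 ** (anchor - out["mean_dct"].astype(float))
    out["cn_integer"] = out["cn_estimate"].round().astype(int)
    return out, anchor


def concordance(
    array_amplified: dict[str, bool] | pd.Series,
    qpcr_calls: pd.DataFrame,
    amplified_threshold: int = 3,
) -> dict:
    """Fraction of samples where the array and qPCR agree on the binary
    "amplified" readout (qPCR amplified when integer CN >= threshold).

    Reported both over all samples and restricted to QC-passing ones (it is
    ambiguous whether failing replicates should count, so both are given).
    """
    flags = pd.Series(array_amplified)
    calls = qpcr_calls.set_index("sample_id")
    common = [s for s in calls.index if s in flags.index]
    if not common:
        raise ValueError("no common samples between array flags and qPCR calls")
    agree = []
    agree_qc = []
    for sid in common:
        qp_amp = bool(calls.loc[sid, "cn_integer"] >= amplified_threshold)
        ok = qp_amp == bool(flags[sid])
        agree.append(ok)
        if bool(calls.loc[sid, "qc_pass"]):
            agree_qc.append(ok)
    return {
        "n_samples": len(common),
        "n_concordant": int(sum(agree)),
        "fraction_concordant": sum(agree) / len(common),
        "n_qc_pass": len(agree_qc),
        "fraction_concordant_qc_pass": (
            sum(agree_qc) / len(agree_qc) if agree_qc else float("nan")
        ),
    }


def simulate_wells(
    truth_cns: dict[str, int],
    n_replicates: int = 4,
    ct_noise_sd: float = 0.05,
    reference_ct: float = 26.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a duplex plate: a sample at true copy number CN has expected
    dCt = -log2(CN/2) relative to a diploid sample, plus Gaussian Ct noise on
    both dyes."""
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for sid, cn in truth_cns.items():
        if cn <= 0:
            raise ValueError(f"{sid}: true copy number must be > 0")
        target_mean = reference_ct - np.log2(cn / 2.0)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": sid,
                    "replicate": rep,
                    "ct_fam": target_mean + rng.normal(0.0, ct_noise_sd),
                    "ct_vic": reference_ct + rng.normal(0.0, ct_noise_sd),
                }
            )
    return pd.DataFrame(rows, columns=WELL_COLUMNS)
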