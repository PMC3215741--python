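"""End-to-end pipeline driver.

Ties the stages together in dependency order: simulate (or load) a cohort ->
ratio series vs matched normal or healthy baseline panel -> low-density
masking -> segmentation -> five-state lesion calling -> exclusion filters ->
cohort recurrence, density and MAR discovery -> optional train/test cytoband
overlap test.  Every count the report cites is recorded in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from .lesions import apply_filters, call_lesions
from .recurrence import (
    CytobandMap,
    chromosome_density,
    define_mar,
    overlap_significance,
    recurrence_profile,
)
from .segmentation import segment_sample
from .synthetic import Cohort, build_probe_map, make_cytoband_table, simulate_cohort, simulate_sample

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("snpkaryo")
__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _config_digest(config: skio.PipelineConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _mar_to_dict(mar) -> dict | None:
    return None if mar is None else dataclasses.asdict(mar)


def run_pipeline(
    config: skio.PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run every stage on a synthetic cohort defined by ``config``.

    Returns the run manifest (also written to ``outdir/manifest.json``).
    ``seed`` overrides ``config.seed`` when given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    started = datetime.now(timezone.utc).isoformat()
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": _config_digest(config),
        "seed": seed,
        "started": started,
        "counts": {},
        "stages": [],
    }

    stage = "simulate"
    try:
        chrom_spec = [(c["name"], int(c["length"])) for c in config.genome.chromosomes]
        pmap = build_probe_map(
            chrom_spec,
            spacing=config.genome.spacing,
            snp_fraction=config.genome.snp_fraction,
            seed=seed,
            jitter=config.genome.jitter,
        )
        shared = config.cohort.shared_lesion.to_lesion()
        cohort = simulate_cohort(
            pmap,
            n_samples=config.cohort.n_samples,
            shared_lesion=shared,
            carrier_fraction=config.cohort.carrier_fraction,
            private_lesions_per_sample=config.cohort.private_lesions_per_sample,
            noise=config.noise,
            seed=seed + 1,
            purity=config.cohort.purity,
            matched_normals=(config.mode == "paired"),
        )
        panel: list[pd.DataFrame] = []
        if config.mode == "baseline":
            rng = np.random.default_rng(seed + 2)
            for _ in range(config.n_baseline):
                healthy, _n = simulate_sample(
                    pmap, [], config.noise, matched_normal=False, rng=rng
                )
                panel.append(healthy)
        cyto_table = make_cytoband_table(pmap)
        cytobands = CytobandMap(cyto_table)
        skio.write_chrom_sizes(pmap.lengths, outdir / "chrom.sizes")
        skio.write_cytoband_file(cyto_table, outdir / "cytoBand.txt")
        skio.write_truth_table(cohort.truth, outdir / "truth.tsv")
        if config.write_probe_files:
            probe_dir = outdir / "probes"
            probe_dir.mkdir(exist_ok=True)
            for sid, (tumor, normal) in cohort.samples.items():
                skio.write_probe_file(tumor, probe_dir / f"{sid}.tumor.tsv.gz")
                if normal is not None:
                    skio.write_probe_file(normal, probe_dir / f"{sid}.normal.tsv.gz")
        manifest["counts"]["n_samples"] = cohort.n_samples
        manifest["counts"]["n_probes_per_sample"] = pmap.n_probes
        manifest["counts"]["n_truth_lesions"] = int(len(cohort.truth))
        manifest["stages"].append(stage)
        logger.info("simulate: %d samples, %d probes each", cohort.n_samples, pmap.n_probes)

        stage = "segment+call"
        all_lesions = []
        n_segments = 0
        for sid, (tumor, normal) in cohort.samples.items():
            if config.mode == "paired":
                segments = segment_sample(tumor, normal, "paired", config.segmentation)
                loh_ref = {"normal": normal}
            else:
                segments = segment_sample(tumor, panel, "baseline", config.segmentation)
                loh_ref = {"panel": panel}
            n_segments += len(segments)
            lesions = call_lesions(
                segments,
                sid,
                tumor,
                gain_threshold_lrr=config.calling.gain_threshold_lrr,
                loss_threshold_lrr=config.calling.loss_threshold_lrr,
                loh_params=config.calling.loh,
                **loh_ref,
            )
            all_lesions.append(lesions)
        non_empty = [f for f in all_lesions if not f.empty]
        lesions = (
            pd.concat(non_empty, ignore_index=True)
            if non_empty
            else all_lesions[0]
        )
        manifest["counts"]["n_segments"] = n_segments
        manifest["counts"]["lesions_before_filter"] = int(len(lesions))
        manifest["stages"].append(stage)
        logger.info("segment+call: %d segments, %d lesions", n_segments, len(lesions))

        stage = "filter"
        kept, rejections = apply_filters(lesions, config.filters, cytobands)
        skio.write_lesion_file(kept, outdir / "lesions.tsv")
        rejections.to_csv(outdir / "rejections.tsv", sep="\t", index=False)
        manifest["counts"]["lesions_after_filter"] = int(len(kept))
        manifest["counts"]["rejections_by_rule"] = (
            rejections["rule"].value_counts().to_dict() if len(rejections) else {}
        )
        manifest["stages"].append(stage)
        logger.info("filter: %d kept, %d rejected", len(kept), len(rejections))

        stage = "cohort"
        density, chi2 = chromosome_density(kept, pmap.lengths)
        density.to_csv(outdir / "chromosome_density.tsv", sep="\t", index=False)
        profile = recurrence_profile(
            kept, cohort.n_samples, unit="cytoband", cytobands=cytobands
        )
        profile.counts.to_csv(outdir / "recurrence_cytoband.tsv", sep="\t", index=False)
        manifest["counts"]["recurrence_histogram"] = {
            str(k): v for k, v in profile.histogram.items() if v
        }
        manifest["chi_square"] = chi2
        manifest["stages"].append(stage)

        stage = "mar"
        mar, candidates = define_mar(kept, cohort.n_samples, config.mar.min_fraction)
        mar_report = {
            "mar": _mar_to_dict(mar),
            "candidates": [_mar_to_dict(c) for c in candidates],
        }
        (outdir / "mar.json").write_text(json.dumps(mar_report, indent=2))
        if candidates:
            pd.DataFrame([_mar_to_dict(c) for c in candidates]).to_csv(
                outdir / "mar_candidates.tsv", sep="\t", index=False
            )
        manifest["mar"] = _mar_to_dict(mar)
        manifest["stages"].append(stage)
        if mar:
            logger.info(
                "mar: %s:%d-%d in %d/%d samples",
                mar.chrom, mar.start, mar.end, mar.n_affected, mar.cohort_size,
            )

        if config.train_test.enabled:
            stage = "train_test_overlap"
            sids = cohort.sample_ids
            n_train = int(round(config.train_test.train_fraction * len(sids)))
            train_ids, test_ids = set(sids[:n_train]), set(sids[n_train:])

            def affected_bands(ids: set[str]) -> set[str]:
                sub = kept[kept["sample_id"].isin(ids)]
                bands: set[str] = set()
                for _, row in sub.iterrows():
                    bands.update(
                        cytobands.bands_for(row["chrom"], int(row["start"]), int(row["end"]))
                    )
                return bands

            result = overlap_significance(
                affected_bands(train_ids),
                affected_bands(test_ids),
                cytobands.n_bands,
            )
            overlap = dataclasses.asdict(result)
            overlap["percent_rounded"] = result.percent_rounded
            (outdir / "overlap_test.json").write_text(json.dumps(overlap, indent=2))
            manifest["overlap_test"] = overlap
            manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
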