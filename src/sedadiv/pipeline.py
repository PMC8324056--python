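"""End-to-end pipeline runner.

Stages execute in the pinned order: filtering -> QC scoring -> gating ->
diversity -> regional pool -> driver models, with every threshold and
seed echoed to the run log and all outputs written as TSV.  A rerun with
an identical configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from sedadiv import __version__
from sedadiv import diversity as dv
from sedadiv import drivers as dr
from sedadiv import filtering as fl
from sedadiv import pool as rp
from sedadiv import qc as q
from sedadiv.io import (
    PipelineConfig,
    read_counts_tsv,
    read_reference,
    read_table,
    write_table,
    write_taxon_table,
)

log = logging.getLogger("sedadiv")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured inputs; returns all result tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:12]
    log.info("sedadiv %s | config %s | seed %d", __version__, cfg_hash, config.seed)
    log.info("thresholds: %s", {k: v for k, v in asdict(config).items()
                                if not isinstance(v, str)})

    stage = "read inputs"
    try:
        raw = read_counts_tsv(config.counts_path)
        refdb = read_reference(config.reference_fasta, config.taxonomy_path,
                               config.blacklist_synthetic,
                               config.blacklist_false_positives)
        lakes = read_table(config.lakes_path)
        proxy = read_table(config.proxy_path)
        ages = None
        truth = Path(config.counts_path).parent / "truth_samples.tsv"
        if truth.exists():
            t = read_table(truth)
            ages = t.set_index(["lake_id", "sample_id"])["age"].astype(float)
        if ages is None:
            raise ValueError("no sample age table found next to counts")

        stage = "filtering"
        stages = fl.harmonize(
            raw, refdb,
            min_reads=config.min_reads,
            min_total_reads=config.min_total_reads,
            min_total_replicates=config.min_total_replicates,
        )
        log.info("filtering: raw=%d postfilter=%d identified=%d retained=%d final=%d",
                 len(raw), len(stages["postfilter"]), len(stages["identified"]),
                 len(stages["retained"]), len(stages["final"]))

        stage = "qc"
        qc = q.sample_qc_table(
            raw, stages["postfilter"], stages["clean"],
            n_replicates=config.n_replicates,
            mtq_threshold=config.mtq_threshold,
            maq_threshold=config.maq_threshold,
        )
        write_table(qc, out / "sample_qc.tsv")
        passed = qc[qc["passed"] & (qc["sample_type"] == "sample")]
        log.info("qc: %d/%d samples passed; %d negative controls, %d passed",
                 len(passed), (qc["sample_type"] == "sample").sum(),
                 (qc["sample_type"] == "neg_control").sum(),
                 int(qc[qc["sample_type"] == "neg_control"]["passed"].sum()))

        stage = "gate"
        keep = set(map(tuple, passed[["lake_id", "sample_id"]].to_numpy()))
        final = stages["final"]
        final = final[[tuple(k) in keep for k in
                       final[["lake_id", "sample_id"]].to_numpy()]].reset_index(drop=True)
        write_taxon_table(final, out / "taxon_table.tsv")

        stage = "diversity"
        diversity = dv.sample_diversity_table(final, ages,
                                              n_replicates=config.n_replicates)
        write_table(diversity, out / "diversity.tsv")
        accum = pd.concat(
            [dv.accumulated_richness(sub, ages)
             for _, sub in final.groupby("lake_id")],
            ignore_index=True,
        )
        write_table(accum, out / "lake_accumulation.tsv")

        stage = "regional pool"
        regional = rp.accumulate_regional(final, ages)
        write_table(regional, out / "regional_accumulation.tsv")
        bins = rp.binned_pools(final, diversity,
                               width=config.bin_width,
                               size=config.subsample_size,
                               n_resamples=config.n_resamples,
                               seed=config.seed)
        write_table(bins, out / "binned_pools.tsv")
        try:
            pool_models = rp.fit_pool_models(bins)
        except ValueError as exc:
            log.warning("pool models skipped: %s", exc)
            pool_models = None

        stage = "drivers"
        driver = dr.build_driver_table(diversity, lakes, proxy,
                                       exclude_d18o_below=config.exclude_d18o_below)
        write_table(driver, out / "driver_table.tsv")
        lme = dr.fit_driver_lme(driver)
        write_table(lme.slopes, out / "lme_slopes.tsv")
        gamm = dr.fit_regional_gamm(diversity, use_ar1=True)
        write_table(pd.DataFrame({
            "age": gamm.pred_age, "fit": gamm.fit,
            "lower": gamm.lower, "upper": gamm.upper,
        }), out / "regional_trend.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    summary = {
        "config_hash": cfg_hash,
        "n_samples_retained": int(len(passed)),
        "n_taxa_final": int(final["taxon"].nunique()),
        "negative_controls_failed": int(
            (~qc[qc["sample_type"] == "neg_control"]["passed"]).sum()),
        "negative_controls_total": int((qc["sample_type"] == "neg_control").sum()),
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {
        "qc": qc, "final": final, "diversity": diversity,
        "lake_accumulation": accum, "regional_accumulation": regional,
        "binned_pools": bins, "pool_models": pool_models,
        "driver_table": driver, "lme": lme, "gamm": gamm, "summary": summary,
    }
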