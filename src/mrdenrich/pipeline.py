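"""End-to-end pipeline: simulate -> QC -> selectivity -> errors -> LoD/VAF -> MRD.

Desk-scale orchestration over the library modules, writing every stage's
output as TSV/JSON under one output directory together with a manifest of
the effective configuration and seed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, enrichment, error_model, mrd, qc
from .io import PipelineConfig, write_counts, write_json, write_table
from .synthetic_data import SimConfig, simulate_counts, simulate_panel

__all__ = ["run_pipeline"]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic-assay analysis pipeline; returns a results dict."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = SimConfig(
        n_probes=config.n_probes,
        vaf_levels=tuple(config.vaf_levels),
        replicates_per_level=config.replicates_per_level,
        input_mass_pg=config.input_mass_pg,
        pg_per_haploid_genome=config.pg_per_haploid_genome,
        library_efficiency=config.library_efficiency,
        duplex_probability=config.duplex_probability,
        sample_sd=config.sample_sd,
        dropout_probability=config.dropout_probability,
        seed=config.seed,
    )
    panel, truth = simulate_panel(sim)
    counts, controls, truth = simulate_counts(panel, truth, sim)
    write_table(panel, out / "panel.tsv")
    write_counts(counts, out / "counts.tsv")
    write_table(controls, out / "control_counts.tsv")
    write_table(truth.samples, out / "sample_truth.tsv")

    blanks = set(truth.samples.loc[truth.samples["vaf"] == 0.0, "sample_id"])
    reports = qc.qc_cohort(counts, controls, blank_sample_ids=blanks)
    write_json(
        [
            {
                "sample_id": r.sample_id, "failed": r.failed,
                "failing_control_probes": list(r.failing_control_probes),
                "contamination_ratio": None if math.isnan(r.contamination_ratio) else r.contamination_ratio,
                "contaminated": r.contaminated, "status": r.status, "notes": r.notes,
            }
            for r in reports
        ],
        out / "qc.json",
    )
    passing = {r.sample_id for r in reports if r.status == "pass"}
    counts_ok = counts[counts["sample_id"].isin(passing)]

    per_probe = enrichment.probe_selectivity(counts_ok, config.min_vaf_for_selectivity)
    s_g = enrichment.global_selectivity(counts_ok, config.min_vaf_for_selectivity)
    write_table(per_probe, out / "probe_selectivity.tsv")

    blank_ok = counts_ok[counts_ok["vaf"] == 0.0]
    priors_dup = error_model.fit_site_priors(blank_ok, "duplex")
    priors_ss = error_model.fit_site_priors(blank_ok, "single_strand")
    type_dup = error_model.fit_type_priors(blank_ok, panel, "duplex")
    write_table(pd.concat([priors_dup, priors_ss]), out / "site_priors.tsv")
    if not type_dup.empty:
        write_table(type_dup, out / "type_priors.tsv")

    fpr = detection.fpr_budget(config.fpr_n_samples, config.fpr_n_variants)
    copies = sim.haploid_copies
    scaling = dict(zip(truth.samples["sample_id"], truth.samples["scaling"]))

    # LoD95 per probe, calibrated on the highest-VAF passing samples
    f_cal = max(config.vaf_levels)
    cal = counts_ok[counts_ok["vaf"] == f_cal]
    lod_rows = []
    dup_prior_map = {r.probe_id: error_model.BackgroundPrior(r.alpha, r.beta, "site-specific")
                     for r in priors_dup.itertuples(index=False)}
    for probe, grp in cal.groupby("probe_id", sort=True):
        s_vec = np.array([scaling[s] for s in grp["sample_id"]])
        perf = detection.calibrate_probe_performance(
            grp["total_alt"].to_numpy(float), s_vec, copies, f_cal,
            probe_id=str(probe), background=dup_prior_map.get(probe),
        )
        val = detection.lod95(perf, fpr, copies)
        lod_rows.append({"probe_id": probe, "rate": perf.rate,
                         "lod95": val if np.isfinite(val) else float("nan")})
    lod = pd.DataFrame(lod_rows)
    write_table(lod, out / "lod95.tsv")

    spec = mrd.build_model_spec(
        panel, priors_dup, priors_ss, copies,
        library_efficiency=config.library_efficiency,
        duplex_fraction=config.duplex_probability,
    )
    mrd_rows = []
    status = {r.sample_id: r.status for r in reports}
    for sid, grp in counts.groupby("sample_id", sort=True):
        res = mrd.mrd_posterior(
            grp, spec, sample_id=str(sid), scaling=scaling.get(str(sid), 1.0),
            qc_status=status.get(str(sid), "pass"),
        )
        mrd_rows.append(
            {"sample_id": sid, "probability_mrd": res.probability_mrd,
             "level_estimate": res.level_estimate,
             "level_lo": res.level_interval[0], "level_hi": res.level_interval[1],
             "called": mrd.call_mrd(res, config.posterior_threshold),
             "n_probes_used": res.n_probes_used, "qc_status": res.qc_status,
             "total_duplex_alt": res.total_duplex_alt}
        )
    mrd_table = pd.DataFrame(mrd_rows)
    write_table(mrd_table, out / "mrd.tsv")

    manifest = {
        "config": config.model_dump(),
        "seed": config.seed,
        "global_selectivity": None if math.isnan(s_g) else s_g,
        "fpr": fpr,
        "median_lod95": float(lod["lod95"].median()) if len(lod) else None,
        "n_samples": int(truth.samples.shape[0]),
        "n_failed": int(sum(r.failed for r in reports)),
    }
    write_json(manifest, out / "manifest.json")
    return {
        "panel": panel, "counts": counts, "controls": controls,
        "qc": reports, "probe_selectivity": per_probe,
        "global_selectivity": s_g, "lod": lod, "mrd": mrd_table,
        "manifest": manifest,
    }
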