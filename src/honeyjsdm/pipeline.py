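"""End-to-end pipeline: simulate/load -> filter -> fit -> post-fit -> report.

Every stage writes its outputs under the configured directory together
with a run manifest (config hash, seeds, package version, per-stage wall
time and record counts); rerunning with the same config reproduces all
numeric outputs exactly.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import PipelineConfig, config_hash
from .model import convergence_report, fit_abundance, fit_occurrence
from .postfit import (
    evaluate_fit,
    group_variance_table,
    omega,
    predict_seasonal,
    variance_partition,
)
from .model import build_fixed_design
from .preprocess import run_filter_chain
from .simulate import DesignSpec, TruthConfig, simulate_dataset

__all__ = ["run_pipeline"]


def _stage(manifest, name, t0, **info):
    manifest["stages"].append(
        {"stage": name, "wall_time_s": round(time.perf_counter() - t0, 3), **info}
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis described by ``cfg``; returns the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "stages": [],
    }
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("simulate", "fit_occurrence", "fit_abundance")}
    manifest["stage_seeds"] = seeds

    # ---- inputs -------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        n_genera = sim_kwargs.pop("n_genera", 50)
        spec = DesignSpec(**sim_kwargs.pop("design", {}))
        tconf = TruthConfig(**sim_kwargs.pop("truth", {}))
        ds = simulate_dataset(n_genera=n_genera, spec=spec, config=tconf,
                              seed=seeds["simulate"])
        counts, samples, traits, blank = ds.counts, ds.samples, ds.traits, ds.blank
        io.write_count_table(counts, out / "counts.tsv")
        io.write_samples(samples, out / "samples.csv")
        io.write_traits(traits, out / "traits.csv")
        io.write_blank(blank, out / "blank.tsv")
        io.write_truth(ds.truth, out / "truth.json")
    else:
        counts = io.read_count_table(cfg.counts)
        samples = io.read_samples(cfg.samples)
        traits = io.read_traits(cfg.traits)
        blank = io.read_blank(cfg.blank) if cfg.blank else None
    _stage(manifest, "input", t0, genera=int(counts.shape[0]),
           samples=int(counts.shape[1]))

    # ---- filtering ----------------------------------------------------
    t0 = time.perf_counter()
    occ, ab, flog = run_filter_chain(
        counts, samples,
        blank=blank if cfg.simulate is None else (blank if blank is not None and blank.sum() else None),
        cell_threshold_pct=cfg.cell_threshold_pct,
        mean_threshold_pct=cfg.mean_threshold_pct,
        min_prevalence=cfg.min_prevalence_pct / 100.0,
        dominant_ids=cfg.dominant_ids,
    )
    io.write_filter_log(flog, out / "filter_log.json")
    occ.Y.to_csv(out / "occurrence_Y.tsv", sep="\t")
    ab.Z.to_csv(out / "abundance_Z.tsv", sep="\t")
    _stage(manifest, "preprocess", t0,
           occurrence_genera=int(occ.Y.shape[0]),
           abundance_genera=int(ab.Z.shape[0]))

    # ---- model fitting ------------------------------------------------
    spec = cfg.model_spec()
    schedule = cfg.schedule()
    t0 = time.perf_counter()
    d_occ = fit_occurrence(occ.Y, samples, traits, spec, schedule,
                           seed=seeds["fit_occurrence"])
    io.save_draws(d_occ, out / "draws_occurrence.npz")
    z_ok = np.isfinite(ab.Z).sum(axis=1) >= 2
    d_ab = fit_abundance(ab.Z.loc[z_ok], samples, traits, spec, schedule,
                         seed=seeds["fit_abundance"])
    io.save_draws(d_ab, out / "draws_abundance.npz")
    if schedule.n_chains >= 2:
        conv = pd.concat([convergence_report(d_occ).assign(model="occurrence"),
                          convergence_report(d_ab).assign(model="abundance")])
        conv.to_csv(out / "convergence.csv", index=False)
    _stage(manifest, "fit", t0, draws=int(d_occ.n_draws))

    # ---- post-fit -----------------------------------------------------
    t0 = time.perf_counter()
    X_occ, _ = build_fixed_design(samples.loc[occ.Y.columns], spec)
    vp_occ = variance_partition(d_occ, X_occ, traits)
    group_variance_table(vp_occ).to_csv(out / "variance_partition_occurrence.csv")
    vp_occ.fractions.to_csv(out / "variance_fractions_occurrence.csv")
    X_ab, _ = build_fixed_design(samples.loc[ab.Z.columns], spec)
    vp_ab = variance_partition(d_ab, X_ab, traits)
    group_variance_table(vp_ab).to_csv(out / "variance_partition_abundance.csv")

    fit_metrics = evaluate_fit(d_occ, d_ab, occ.Y, ab.Z.loc[z_ok], samples, spec)
    fit_metrics.to_csv(out / "explanatory_metrics.csv")

    trends = predict_seasonal(d_occ, timepoints=spec.timepoints)
    pd.concat([trends.occ_prob, trends.p_increase, trends.trend_call], axis=1)\
        .to_csv(out / "seasonal_trends.csv")

    om = omega(d_occ)
    om.omega_mean.to_csv(out / "omega_mean.tsv", sep="\t")
    om.sign_call.to_csv(out / "omega_sign_calls.tsv", sep="\t")
    om.edge_list().to_csv(out / "omega_edges.csv", index=False)
    _stage(manifest, "postfit", t0,
           trend_increase=int((trends.trend_call == "increase").sum()),
           trend_decrease=int((trends.trend_call == "decrease").sum()),
           omega_edges=int(len(om.edge_list())))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
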