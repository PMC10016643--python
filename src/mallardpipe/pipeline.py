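"""End-to-end orchestration: simulate -> filter -> ancestry -> classify -> assign -> stats.

A single :class:`RunConfig` drives every stage; the master seed is hashed with
each stage name so stages are independently reproducible, and an identical
config (seed included) yields a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, genodata, hybridsim, isoassign, originstats, synthio

logger = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    sim: synthio.SimConfig = field(default_factory=synthio.SimConfig)
    maf_min: float = 0.0023
    max_missing: float = 0.05
    ld_window: int = 2
    ld_step: int = 1
    ld_r2_max: float = 0.5
    admixture_k: int = 2
    admixture_replicates: int = 10
    admixture_tol: float = 1e-4
    admixture_max_iter: int = 500
    band_sims: int = 3
    band_reps: int = 5
    pure_cut: float = 0.05
    iso_sd: float = 12.8
    odds: float = 2.0
    local_interval: tuple[float, float] = isoassign.DEFAULT_LOCAL_INTERVAL
    northern_threshold: float = -140.0
    alpha: float = 0.05
    min_class_n: int = 10
    master_seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("sim", {})
        for key in ("grid_shape", "lat_range", "lon_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        if "local_interval" in raw:
            raw["local_interval"] = tuple(raw["local_interval"])
        return cls(sim=synthio.SimConfig(**sim_kwargs), **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return a machine-readable report."""
    sim_cfg = config.sim
    sim_cfg = synthio.SimConfig(
        **{**sim_cfg.to_dict(), "seed": stage_seed(config.master_seed, "simulate")}
    )

    # --- synthetic world ---------------------------------------------------
    wild_f, gfm_f, reference, ref_labels = synthio.gen_parental_pools(sim_cfg)
    isoscape_p = synthio.gen_isoscape(sim_cfg)
    cohort, truth, depth, samples = synthio.gen_cohort(
        sim_cfg, wild_f, gfm_f, isoscape_p
    )
    banding = synthio.gen_banding_data(sim_cfg)

    # --- genotype filtering ------------------------------------------------
    combined = genodata.concat_samples([reference, cohort])
    filtered = genodata.filter_snps(combined, config.maf_min, config.max_missing)
    pruned = genodata.ld_prune(
        filtered, config.ld_window, config.ld_step, config.ld_r2_max,
        seed=stage_seed(config.master_seed, "ld_prune"),
    ).autosomal()
    logger.info("loci: %d raw -> %d filtered -> %d pruned",
                combined.n_loci, filtered.n_loci, pruned.n_loci)

    # --- sex from depth ----------------------------------------------------
    sex_calls = genodata.assign_sex(depth)

    # --- admixture + consensus --------------------------------------------
    rng = np.random.default_rng(stage_seed(config.master_seed, "ancestry"))
    fits = [
        ancestry.fit_admixture(
            pruned, config.admixture_k, seed=int(rng.integers(2**31)),
            tol=config.admixture_tol, max_iter=config.admixture_max_iter,
        )
        for _ in range(config.admixture_replicates)
    ]
    consensus = ancestry.align_replicates(fits)
    wild_ref_idx = [pruned.sample_ids.index(s)
                    for s in ref_labels.index[ref_labels == "WILD"]]
    wild_col = int(np.argmax(consensus.Q_mean[wild_ref_idx].mean(axis=0)))
    wild_q_all = consensus.Q_mean[:, wild_col]

    # --- generation bands & classification ---------------------------------
    ref_only = pruned.take_samples(
        [pruned.sample_ids.index(s) for s in reference.sample_ids]
    )
    locus_pos = {lid: j for j, lid in enumerate(combined.locus_meta["id"])}
    keep_loci = [locus_pos[lid] for lid in pruned.locus_meta["id"]]
    bands, wild_ref_min = hybridsim.build_generation_bands(
        ref_only,
        wild_f[keep_loci],
        gfm_f[keep_loci],
        wild_ref_ids=list(ref_labels.index[ref_labels == "WILD"]),
        n_sims=config.band_sims,
        reps_per_sim=config.band_reps,
        seed=stage_seed(config.master_seed, "bands"),
        tol=config.admixture_tol,
        max_iter=config.admixture_max_iter,
    )
    cohort_idx = [pruned.sample_ids.index(s) for s in cohort.sample_ids]
    class_report, class_summary = hybridsim.classify_samples(
        wild_q_all[cohort_idx], cohort.sample_ids, bands, wild_ref_min,
        pure_cut=config.pure_cut,
    )

    # --- isotope assignment -------------------------------------------------
    iso_f = isoassign.rescale_isoscape(isoscape_p)
    weights, prior = isoassign.banding_weights(banding, iso_f)
    regions = []
    locals_ = []
    for y in samples["d2hf"]:
        post = isoassign.posterior_surface(float(y), iso_f, sd=config.iso_sd,
                                           prior=prior)
        regions.append(isoassign.odds_region(post, odds=config.odds))
        locals_.append(isoassign.classify_local(
            float(y), config.local_interval, sd=config.iso_sd))
    summed = isoassign.sum_surfaces(regions)
    samples = samples.copy()
    samples["origin"] = locals_
    samples["klass_inferred"] = class_report.set_index("sample_id").loc[
        samples["sample_id"], "klass"
    ].to_numpy()
    n = len(samples)
    n_local = int((samples["origin"] == "local").sum())
    northern = samples[samples["d2hf"] < config.northern_threshold]
    northern_split = (
        northern["klass_inferred"].value_counts(normalize=True) * 100
    ).round(2).to_dict()

    # --- statistics ---------------------------------------------------------
    stats_df = samples.rename(columns={"klass_inferred": "klass_model"})
    stats_df = stats_df.drop(columns=["klass"]).rename(
        columns={"klass_model": "klass"}
    )
    counts = stats_df["klass"].value_counts()
    modeled = [k for k in counts.index if counts[k] >= config.min_class_n]
    small = [k for k in counts.index if counts[k] < config.min_class_n]
    report_stats: dict = {}
    if "WILD" in modeled and len(modeled) >= 2:
        fit = originstats.fit_model(stats_df, tuple(modeled), alpha=config.alpha)
        tukey = originstats.tukey_contrasts(fit, alpha=config.alpha)
        report_stats = {
            "terms": fit.params.to_dict(orient="records"),
            "sex_included": fit.sex_included,
            "sex_pvalue": fit.sex_pvalue,
            "tukey": tukey.table.to_dict(orient="records"),
            "seasonal_change_permil": originstats.seasonal_change(fit),
            "group_means": originstats.group_summary(
                stats_df[stats_df["klass"].isin(modeled)]
            ).to_dict(orient="records"),
        }
    descriptive = originstats.descriptive_stats(stats_df, small).to_dict(
        orient="records"
    )

    report = {
        "config": {"master_seed": config.master_seed,
                   "sim": sim_cfg.to_dict()},
        "n_samples": n,
        "loci": {"raw": combined.n_loci, "filtered": filtered.n_loci,
                 "pruned": pruned.n_loci},
        "sex_calls": sex_calls.value_counts().to_dict(),
        "classification": class_summary,
        "wild_ref_min": wild_ref_min,
        "bands": hybridsim.bands_to_frame(bands).to_dict(orient="records"),
        "local_immigrant": {
            "local_n": n_local,
            "immigrant_n": n - n_local,
            "local_pct": 100.0 * n_local / n,
            "immigrant_pct": 100.0 * (n - n_local) / n,
        },
        "northern_origin": {
            "threshold_permil": config.northern_threshold,
            "n": int(len(northern)),
            "pct": 100.0 * len(northern) / n,
            "class_split_pct": northern_split,
        },
        "banding_weights": weights,
        "statistics": report_stats,
        "descriptive_small_classes": descriptive,
    }

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        class_report.to_csv(out / "classification.csv", index=False)
        hybridsim.bands_to_frame(bands).to_csv(out / "bands.csv", index=False)
        samples.to_csv(out / "samples.csv", index=False)
        isoassign.write_ascii_grid(
            summed.counts.astype(float), iso_f.lats, iso_f.lons,
            str(out / "origin_counts.asc"), mask=iso_f.mask,
        )
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        report["files"] = {
            "classification": str(out / "classification.csv"),
            "bands": str(out / "bands.csv"),
            "samples": str(out / "samples.csv"),
            "origin_counts": str(out / "origin_counts.asc"),
            "report": str(out / "report.json"),
        }
    return report
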