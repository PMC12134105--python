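"""End-to-end orchestration: simulate -> map sites -> statistics -> sets ->
modification frequencies -> thiols -> correlations.

A run is driven by a plain configuration mapping (typically loaded from
YAML), executes each stage into its own output file, and records a manifest
of every artifact and the parameters that produced it.  Given the same
configuration (including the seed) a rerun reproduces every file.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import (
    correlations,
    io_formats,
    localization_sets,
    ptm_mods,
    site_mapping,
    stats_core,
    synthetic_data,
    thiol_quant,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "n_pairs": 70,
    "n_proteins": 120,
    "redox_min_fraction": 0.30,
    "lfq_min_fraction": 0.60,
    "impute_width": 0.3,
    "impute_downshift": 1.8,
    "s0": 0.1,
    "fdr": 0.05,
    "alpha": 0.05,
    "n_perm": 250,
    "paired": False,
    "site_policy": "share",
    "min_psm": 10,
    "n_psms_per_sample": 2000,
}


def _merge_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    merged = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        merged.update(config)
    if merged["seed"] is None:
        raise ValueError("a seed is required: the pipeline has stochastic stages")
    return merged


def run_pipeline(config: Mapping[str, Any] | None = None, out_dir: str | Path = ".") -> dict:
    """Run the full synthetic-cohort pipeline and write all stage outputs.

    Returns the manifest (also written as ``manifest.json``): per stage the
    output files, the parameters used, and headline summary numbers.
    """
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": cfg, "stages": {}}
    seed = int(cfg["seed"])

    cohort = synthetic_data.CohortSpec(
        n_pairs=cfg["n_pairs"], n_proteins=cfg["n_proteins"], seed=seed
    )
    effects = synthetic_data.EffectSpec()
    noise = synthetic_data.NoiseSpec()

    # --- stage: simulate -------------------------------------------------
    redox = synthetic_data.generate_redox_experiment(cohort, effects, noise)
    lfq = synthetic_data.generate_lfq_experiment(cohort, effects, noise)
    psm = synthetic_data.generate_psm_table(
        cohort, effects, n_psms_per_sample=cfg["n_psms_per_sample"]
    )
    thiol = synthetic_data.generate_thiol_table(cohort, effects, noise)
    meta = redox["meta"]

    io_formats.write_fasta(redox["proteins"], out / "proteins.fasta")
    io_formats.write_sample_meta(meta, out / "samples.tsv")
    io_formats.write_peptide_table(redox["peptides"], out / "peptides.tsv")
    io_formats.write_matrix(lfq["matrix"], out / "lfq_matrix.tsv", index_label="protein")
    io_formats.write_psm_table(psm["psms"], out / "psms.tsv")
    io_formats.write_thiol_table(thiol["measurements"], out / "thiols.tsv")
    manifest["stages"]["simulate"] = {
        "outputs": [
            "proteins.fasta",
            "samples.tsv",
            "peptides.tsv",
            "lfq_matrix.tsv",
            "psms.tsv",
            "thiols.tsv",
        ],
        "n_samples": len(meta),
        "n_sites_true": int(len(redox["site_catalog"])),
    }

    # --- stage: map-sites -------------------------------------------------
    matrix = site_mapping.aggregate_site_ratios(
        redox["peptides"], redox["proteins"], meta, policy=cfg["site_policy"]
    )
    site_mapping.write_site_report(matrix, out / "site_matrix.tsv")
    manifest["stages"]["map_sites"] = {
        "outputs": ["site_matrix.tsv"],
        "policy": cfg["site_policy"],
        "n_sites_quantified": int(matrix.values.shape[0]),
        "n_skipped_observations": matrix.n_skipped,
    }

    # --- stage: redox statistics -----------------------------------------
    redox_filter = stats_core.FilterSpec(cfg["redox_min_fraction"], "each_group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = stats_core.filter_valid(matrix.values, meta, redox_filter)
    log_ratios = stats_core.log2_matrix(filtered)
    redox_results = stats_core.permutation_fdr(
        log_ratios,
        meta,
        s0=cfg["s0"],
        n_perm=cfg["n_perm"],
        seed=seed + 1,
        threshold_q=cfg["fdr"],
        paired=cfg["paired"],
    )
    redox_results.to_csv(out / "redox_results.tsv", sep="\t", index_label="site_id")
    manifest["stages"]["redox_stats"] = {
        "outputs": ["redox_results.tsv"],
        "filter": {"min_fraction": cfg["redox_min_fraction"], "mode": "each_group"},
        "s0": cfg["s0"],
        "n_perm": cfg["n_perm"],
        "n_sites_tested": int(len(redox_results)),
        "n_sites_significant_fdr": int(redox_results["significant"].sum()),
        "n_sites_significant_p": int((redox_results["p_value"] < cfg["alpha"]).sum()),
    }

    # --- stage: signed protein sets ---------------------------------------
    site_accession = matrix.site_index["accession"]
    sets = localization_sets.build_signed_sets(
        redox_results, site_accession, alpha=cfg["alpha"]
    )
    sizes = sets.sizes()
    with open(out / "signed_sets.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "sizes": sizes,
                "more_ox_tumor_only": sorted(sets.more_ox_tumor_only),
                "more_ox_healthy_only": sorted(sets.more_ox_healthy_only),
                "both": sorted(sets.both),
            },
            fh,
            indent=2,
        )
    manifest["stages"]["signed_sets"] = {
        "outputs": ["signed_sets.json"],
        "alpha": cfg["alpha"],
        **sizes,
    }

    # --- stage: LFQ statistics --------------------------------------------
    lfq_filter = stats_core.FilterSpec(cfg["lfq_min_fraction"], "any_group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lfq_kept = stats_core.filter_valid(lfq["matrix"], meta, lfq_filter)
        centered = stats_core.median_center(lfq_kept)
        imputed = stats_core.impute_downshift(
            centered,
            stats_core.ImputeSpec(
                width=cfg["impute_width"],
                downshift=cfg["impute_downshift"],
                seed=seed + 2,
            ),
        )
    lfq_results = stats_core.permutation_fdr(
        imputed,
        meta,
        s0=cfg["s0"],
        n_perm=cfg["n_perm"],
        seed=seed + 3,
        threshold_q=cfg["fdr"],
        paired=cfg["paired"],
    )
    lfq_results.to_csv(out / "lfq_results.tsv", sep="\t", index_label="protein")
    manifest["stages"]["lfq_stats"] = {
        "outputs": ["lfq_results.tsv"],
        "filter": {"min_fraction": cfg["lfq_min_fraction"], "mode": "any_group"},
        "n_proteins_tested": int(len(lfq_results)),
        "n_proteins_significant_fdr": int(lfq_results["significant"].sum()),
    }

    # --- stage: MG-H1 frequency -------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        freq = ptm_mods.mgh1_frequency(psm["psms"], meta)
    freq.to_csv(out / "mgh1_frequency.tsv", sep="\t")
    delta_summary = ptm_mods.summarize_delta_masses(
        psm["psms"]["delta_mass"],
        ptm_mods.DeltaMassSpec(min_psm=cfg["min_psm"]),
    )
    delta_summary.to_csv(out / "delta_mass_summary.tsv", sep="\t", index=False)
    mean_t = float(freq.loc[freq["group"] == "tumor", "frequency_pct"].mean())
    mean_h = float(freq.loc[freq["group"] == "healthy", "frequency_pct"].mean())
    manifest["stages"]["ptm_mods"] = {
        "outputs": ["mgh1_frequency.tsv", "delta_mass_summary.tsv"],
        "mean_frequency_tumor_pct": mean_t,
        "mean_frequency_healthy_pct": mean_h,
        "n_delta_bins": int(len(delta_summary)),
    }

    # --- stage: thiols -----------------------------------------------------
    norm = thiol_quant.normalize_table(thiol["measurements"])
    panel = thiol_quant.biological_sums(norm)
    ratios = thiol_quant.tumor_healthy_ratio(panel, meta)
    panel.to_csv(out / "thiol_panel.tsv", sep="\t")
    ratios.to_csv(out / "thiol_th_ratios.tsv", sep="\t")
    manifest["stages"]["thiols"] = {
        "outputs": ["thiol_panel.tsv", "thiol_th_ratios.tsv"],
        "median_th_ratio": {
            c: (None if np.isnan(v) else float(v))
            for c, v in ratios.median().items()
        },
    }

    # --- stage: correlations -----------------------------------------------
    tumor_samples = {m.pair_key: m.sample_id for m in meta if m.group == "tumor"}
    freq_tumor = pd.Series(
        {
            pair: freq.loc[sid, "frequency_pct"]
            for pair, sid in tumor_samples.items()
            if sid in freq.index
        }
    )
    first_protein = lfq["matrix"].index[0]
    lfq_tumor = pd.Series(
        {
            pair: lfq["matrix"].loc[first_protein, sid]
            for pair, sid in tumor_samples.items()
        }
    )
    data = {
        "mgh1_freq_tumor": freq_tumor,
        "lfq_first_protein_tumor": lfq_tumor,
        "slg_th_ratio": ratios["sLG"],
        "total_glutathione_th_ratio": ratios["total_glutathione"],
    }
    panel_spec = [
        ("mgh1_freq_tumor", "lfq_first_protein_tumor"),
        ("slg_th_ratio", "total_glutathione_th_ratio"),
    ]
    corr = correlations.correlation_panel(panel_spec, data)
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
    manifest["stages"]["correlations"] = {
        "outputs": ["correlations.tsv"],
        "n_pairs_tested": int(len(corr)),
    }

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
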