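"""End-to-end pipeline: simulate -> filter -> FNR -> spectra -> signatures ->
regions -> enrichment -> aging, with a single JSON report.

The pipeline operates on a simulated cohort (the package's self-contained
mode) and emits per-stage logs with counts in and out of every filter
criterion.  All stochastic stages derive their seeds from the single
configured seed, so a fixed configuration reproduces its report bit for
bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import aging, discovery, regions, signatures, simulate
from .io import write_catalog, write_table

__all__ = ["run_pipeline", "default_config"]


def default_config() -> dict:
    return {
        "seed": 0,
        "sim": {},                   # SimConfig overrides
        "nmf_rank": 3,
        "nmf_restarts": 10,
        "cluster_permutations": 200,
        "enrich_direction": "auto",
        "out": None,
    }


def _fnr_controls(truths, clones_by_id):
    """Germline-het control table pooled over all clones."""
    rows = []
    for truth in truths:
        germ = truth.of_kind("germline")
        by_clone = {c: set() for c in germ["clone"].unique()}
        obs_vaf = {}
        for clone_id in by_clone:
            for o in clones_by_id[clone_id].observations:
                obs_vaf[(clone_id,) + o.key] = (o.clone_alt, o.clone_depth)
        for _, g in germ.iterrows():
            key = (g["clone"], g["chrom"], g["pos"], g["ref"], g["alt"])
            alt, depth = obs_vaf.get(key, (0, 0))
            if not g["detected"]:
                alt, depth = 0, 30
            rows.append({"clone_alt": alt, "clone_depth": depth,
                         "detected": bool(g["detected"]) and depth > 0})
    return pd.DataFrame(rows)


def run_pipeline(config: dict | None = None) -> dict:
    """Run the full analysis on a simulated cohort; return the report dict.

    With ``config['out']`` set, writes the report JSON plus per-stage TSV
    outputs (catalog audit, spectra, signature contributions, region
    burdens, fits) under that directory.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    sim_cfg = simulate.SimConfig(**{"seed": seed, **cfg["sim"]})

    report: dict = {"stages": []}

    # --- simulate
    reference, clones, truths, metadata = simulate.simulate_cohort(sim_cfg)
    clones_by_id = {c.clone: c for c in clones}
    report["stages"].append({
        "stage": "simulate",
        "n_clones": len(clones),
        "n_donors": sim_cfg.n_donors,
        "genome_length": reference.callable_length,
    })

    # --- filter
    candidates = [o for c in clones for o in c.observations]
    params = discovery.FilterParams(blacklist=reference.region_sets["blacklist"])
    catalog = discovery.filter_somatic(candidates, params)
    per_clone = catalog.counts_per_clone()
    rejection = catalog.rejection_summary().to_dict()
    report["stages"].append({
        "stage": "filter",
        "n_candidates": len(candidates),
        "n_accepted": int(catalog.accepted.shape[0]),
        "rejections": {k: int(v) for k, v in rejection.items()},
    })

    # --- FNR
    controls = _fnr_controls(truths, clones_by_id)
    fnr = discovery.estimate_fnr(controls)
    observed_counts = per_clone.reindex(metadata["clone"], fill_value=0)
    corrected = {c: discovery.correct_for_fnr(int(n), fnr.fnr)
                 for c, n in observed_counts.items()}
    report["stages"].append({
        "stage": "fnr",
        "n_controls": fnr.n_control_sites,
        "fnr": round(fnr.fnr, 4),
        "observed_range": [int(observed_counts.min()), int(observed_counts.max())],
        "corrected_range": [min(corrected.values()), max(corrected.values())],
    })

    # --- spectra + signatures
    spectra = [signatures.build_spectrum(catalog, reference.sequences, clone=c)
               for c in metadata["clone"]]
    matrix = signatures.spectrum_matrix(spectra)
    sig_set = signatures.extract_signatures(
        matrix, rank=cfg["nmf_rank"], n_restarts=cfg["nmf_restarts"], seed=seed)
    panel = signatures.load_reference_signatures()
    refit = signatures.refit_catalog(matrix, panel)
    clust = signatures.cluster_clones(
        sig_set.contributions, n_perm=cfg["cluster_permutations"], seed=seed)
    report["stages"].append({
        "stage": "signatures",
        "n_snvs_in_spectra": int(matrix.to_numpy().sum()),
        "nmf_objective": round(sig_set.objective, 4),
        "cluster_sizes": np.bincount(clust["labels"].to_numpy()).tolist(),
    })

    # --- regions + enrichment
    expr = simulate.simulate_expression_table(sim_cfg, reference)
    fantom = regions.build_fantom_regions(
        expr, regions.FantomThresholds(), reference.gene_model)
    groups = dict(zip(metadata["clone"], metadata["group"]))
    load = regions.regional_mutation_load(
        catalog, {f"{ph}_{kind}": rs for (ph, kind), rs in fantom.items()}, groups)
    exon_rs = regions.RegionSet("exons", reference.gene_model.exons())
    enr = regions.enrichment_depletion(
        catalog.accepted[["chrom", "pos"]], exon_rs,
        reference.callable_length, direction=cfg["enrich_direction"])
    report["stages"].append({
        "stage": "regions",
        "surveyed": {f"{ph}_{kind}": int(rs.surveyed_length)
                     for (ph, kind), rs in fantom.items()},
        "exon_enrichment": {
            "observed": enr.observed, "expected": round(enr.expected, 3),
            "log2_ratio": round(enr.log2_ratio, 4) if np.isfinite(enr.log2_ratio) else None,
            "p": round(enr.p, 6), "direction": enr.direction,
        },
        "expressed_load_p": round(load["p_value"], 6),
    })

    # --- aging
    meta_fit = metadata.assign(mutation_count=observed_counts.to_numpy())
    rate = aging.fit_rate(meta_fit)
    threshold = aging.derive_threshold(meta_fit)
    report["stages"].append({
        "stage": "aging",
        "slope": round(rate.slope, 4),
        "slope_se": round(rate.slope_se, 4),
        "p_value": float(f"{rate.p_value:.3e}"),
        "method": rate.method,
        "divisions_per_year": aging.divisions_per_year(rate.slope),
        "threshold": round(threshold.threshold, 1) if threshold.threshold else None,
    })

    out = cfg.get("out")
    if out:
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        write_catalog(catalog, tsv_path=outdir / "catalog_audit.tsv")
        write_table(matrix, outdir / "spectra.tsv", index=True)
        write_table(sig_set.contributions, outdir / "signature_contributions.tsv", index=True)
        write_table(refit.contributions, outdir / "reference_refit.tsv", index=True)
        write_table(load["counts"], outdir / "regional_load.tsv", index=True)
        write_table(meta_fit, outdir / "metadata.tsv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
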