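"""End-to-end orchestration: simulate -> map -> classify -> correlate ->
OPLS -> integrate, in memory or against files with a run manifest."""

from __future__ import annotations

import json
import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .corr import correlate_features, cv_report, strain_aggregate
from .datatypes import RunConfig
from .integrate import integrate
from .kinship import ibs_kinship
from .lmm import ASSOC_COLUMNS, KinshipMixedModel
from .opls import fit_opls
from .qtl import classify_qtl, detect_hotspots, significant_snps
from .simulate import SimConfig, simulate_all

log = logging.getLogger(__name__)

__all__ = ["map_features", "run_all", "write_manifest"]


def map_features(values: pd.DataFrame, panel, kinship,
                 cfg: RunConfig | None = None,
                 min_strains: int | None = None):
    """Scan every column of a strain-level feature matrix.

    Features with fewer non-missing strains than the floor are skipped
    (logged).  Returns (association table, per-feature fit table).
    """
    cfg = cfg or RunConfig()
    floor = cfg.min_strains if min_strains is None else min_strains
    assoc_parts, fits = [], []
    for fid in values.columns:
        y = values[fid].dropna()
        if len(y) < floor:
            log.info("feature %s skipped: %d strains < %d", fid, len(y), floor)
            continue
        try:
            model = KinshipMixedModel(y, kinship, feature_id=fid)
        except ValueError as err:
            log.warning("feature %s skipped: %s", fid, err)
            continue
        fit = model.fit()
        assoc_parts.append(fit.scan(panel, maf_min=cfg.maf_min,
                                    qvalue_method=cfg.qvalue_method))
        fits.append(fit.summary())
    assoc = (pd.concat(assoc_parts, ignore_index=True) if assoc_parts
             else pd.DataFrame(columns=ASSOC_COLUMNS))
    fit_table = pd.DataFrame(fits).reset_index(drop=True)
    return assoc, fit_table


def run_all(sim_cfg: SimConfig, run_cfg: RunConfig | None = None,
            opls_traits: list[str] | None = None) -> dict:
    """Full synthetic-panel analysis; returns every artifact keyed by name."""
    run_cfg = run_cfg or RunConfig()
    sim = simulate_all(sim_cfg)
    panel, genes, truth = sim["panel"], sim["genes"], sim["truth"]
    kin = sim["kinship"]
    abundance, traits = sim["abundance"], sim["traits"]

    strain_matrix = strain_aggregate(abundance)
    cv = cv_report(abundance)

    # the coverage floor scales with panel size (50-of-75-strains analogue)
    prot_floor = min(run_cfg.min_strains,
                     int(np.ceil(sim_cfg.n_strains * 50 / 75)))
    prot_assoc, prot_fits = map_features(strain_matrix, panel, kin, run_cfg,
                                         min_strains=prot_floor)
    trait_floor = min(run_cfg.min_strains, sim_cfg.n_strains)
    trait_assoc, trait_fits = map_features(traits.values, panel, kin, run_cfg,
                                           min_strains=trait_floor)

    gene_of = {f"prot_{i + 1:04d}": genes[i]
               for i in range(sim_cfg.n_proteins)}
    calls = classify_qtl(prot_assoc, gene_of, panel.snp_meta, run_cfg)
    chrom_len = {str(c + 1): sim_cfg.chrom_length_bp
                 for c in range(sim_cfg.n_chromosomes)}
    hotspots = detect_hotspots(calls, chrom_len,
                               bin_bp=run_cfg.hotspot_bin_bp,
                               alpha=run_cfg.hotspot_alpha)

    corr = correlate_features(strain_matrix, traits,
                              r_low=run_cfg.corr_r_low,
                              r_high=run_cfg.corr_r_high,
                              p_cut=run_cfg.corr_p_cut)

    cis_sets = significant_snps(prot_assoc, gene_of, panel.snp_meta,
                                run_cfg, mode="cis")
    trait_sets = significant_snps(trait_assoc, {}, panel.snp_meta,
                                  run_cfg, mode="q")

    opls_results = {}
    for tid in (opls_traits or []):
        try:
            opls_results[tid] = fit_opls(strain_matrix, traits.values[tid],
                                         cross_validate=False)
        except ValueError as err:
            log.warning("OPLS skipped for %s: %s", tid, err)

    integrations = {}
    for tid in traits.trait_ids:
        integrations[tid] = integrate(
            list(strain_matrix.columns), tid,
            cis_sets=cis_sets, trait_sets=trait_sets,
            protein_assoc=prot_assoc, trait_assoc=trait_assoc,
            strain_matrix=strain_matrix, traits=traits,
            corr_results=corr, panel=panel, cfg=run_cfg,
        )

    return {
        **sim,
        "strain_matrix": strain_matrix, "cv": cv,
        "protein_assoc": prot_assoc, "protein_fits": prot_fits,
        "trait_assoc": trait_assoc, "trait_fits": trait_fits,
        "calls": calls, "hotspots": hotspots, "correlations": corr,
        "cis_sets": cis_sets, "trait_sets": trait_sets,
        "opls": opls_results, "integrations": integrations,
    }


def write_outputs(results: dict, out_dir) -> dict[str, str]:
    """Write the tabular artifacts of a run; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name, fn):
        p = out / name
        fn(p)
        paths[name] = str(p)

    _w("genotypes.tsv", lambda p: pio.write_genotypes(
        results["panel"], p, meta_path=out / "snp_meta.tsv"))
    paths["snp_meta.tsv"] = str(out / "snp_meta.tsv")
    _w("genes.tsv", lambda p: pio.write_genes(results["genes"], p))
    _w("abundance.tsv", lambda p: pio.write_abundance(results["abundance"], p))
    _w("traits.tsv", lambda p: pio.write_traits(results["traits"], p))
    _w("truth.json", lambda p: results["truth"].to_json(p))
    for key, fname in (("protein_assoc", "pqtl_assoc.tsv"),
                       ("trait_assoc", "pheqtl_assoc.tsv"),
                       ("protein_fits", "pqtl_fits.tsv"),
                       ("trait_fits", "pheqtl_fits.tsv"),
                       ("calls", "qtl_calls.tsv"),
                       ("hotspots", "hotspots.tsv"),
                       ("correlations", "correlations.tsv")):
        if key in results and isinstance(results[key], pd.DataFrame):
            _w(fname, lambda p, k=key: pio.write_table(results[k], p))
    for tid, tab in results.get("integrations", {}).items():
        _w(f"integration_{tid}.tsv", lambda p, t=tab: pio.write_table(t, p))
    return paths


def write_manifest(path, command: str, config: dict, seed: int,
                   inputs: dict[str, str] | None = None,
                   outputs: dict[str, str] | None = None,
                   started: float | None = None,
                   warnings: list[str] | None = None) -> None:
    """Atomically write the JSON run-metadata sidecar."""
    import platform

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": {k: (pio.sha256_file(v) if os.path.exists(v) else None)
                   for k, v in (inputs or {}).items()},
        "outputs": outputs or {},
        "elapsed_s": (time.time() - started) if started else None,
        "warnings": warnings or [],
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    os.replace(tmp, path)


def summary_counts(results: dict) -> dict:
    """Headline counts of a run (cis/trans proteins, hotspots, prioritized)."""
    calls = results.get("calls", pd.DataFrame())
    n_cis = int((calls["call"] == "cis").sum()) if len(calls) else 0
    n_trans = int((calls["call"] == "trans").sum()) if len(calls) else 0
    hs = results.get("hotspots", pd.DataFrame())
    n_hot = int(hs["hotspot"].sum()) if len(hs) else 0
    n_prior = sum(
        int((tab["verdict"] == "prioritized").sum())
        for tab in results.get("integrations", {}).values()
    )
    return {"n_cis_proteins": n_cis, "n_trans_proteins": n_trans,
            "n_hotspot_bins": n_hot, "n_prioritized": n_prior,
            "median_intra_strain_cv_pct": results.get("cv", {}).get(
                "median_intra"),
            "median_inter_strain_cv_pct": results.get("cv", {}).get(
                "median_inter")}
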