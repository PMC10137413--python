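"""End-to-end orchestration: simulate/load → align → profile → call → compare.

The pipeline consumes a config mapping (or YAML path) with blocks

* ``simulate``: keyword overrides for :class:`atlascmp.synthetic.AtlasConfig`,
  **or** ``inputs``: paths ``matrix_a``, ``metadata_a``, ``matrix_b``,
  ``metadata_b``, ``orthology``;
* ``thresholds``: keyword overrides for :class:`atlascmp.core.Thresholds`;
* ``output_dir``: where tables and ``summary.json`` are written;
* ``seed``: overrides the simulate block's seed.

Given a seed the run is fully deterministic: the summary JSON is written
with sorted keys and produced byte-identically by repeated runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import comparative, de, housekeeping as hk
from .core import (
    ExpressionMatrix,
    Thresholds,
    correlation_structure,
    count_expressed,
    median_profile,
    read_matrix,
)
from .orthology import align_one_to_one, category_accounting, read_orthology
from .synthetic import AtlasConfig, generate_atlas, write_atlas

__all__ = ["load_config", "run_pipeline"]

logger = logging.getLogger("atlascmp")


def load_config(config) -> dict:
    """Accept a dict, or a path to a YAML file, and return the config dict."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _jsonable(obj):
    """Recursively convert numpy scalars/containers for json.dump."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _safe_spearman(counts_a, counts_b) -> tuple[float, float]:
    """Spearman of per-tissue counts; NaN when a vector is constant
    (degenerate but possible on small synthetic runs)."""
    try:
        return comparative.spearman_counts(counts_a, counts_b)
    except ValueError:
        return float("nan"), float("nan")


def _load_inputs(inputs: Mapping) -> tuple[ExpressionMatrix, ExpressionMatrix, object]:
    em_a = read_matrix(inputs["matrix_a"], inputs["metadata_a"])
    em_b = read_matrix(inputs["matrix_b"], inputs["metadata_b"])
    omap = read_orthology(inputs["orthology"])
    return em_a, em_b, omap


def _write_de_tables(results: Mapping[str, de.DEResult], out_dir: Path, stem: str) -> None:
    frames = []
    for tissue, res in sorted(results.items()):
        tab = res.table.copy()
        tab.insert(0, "tissue", tissue)
        frames.append(tab)
    if frames:
        pd.concat(frames).to_csv(out_dir / f"{stem}.tsv", sep="\t")


def run_pipeline(config) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    cfg = load_config(config)
    thr = Thresholds(**cfg.get("thresholds", {}))
    out_dir = Path(cfg.get("output_dir", "atlascmp_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage: simulate or load ------------------------------------------------
    truth = None
    if "simulate" in cfg:
        sim_kwargs = dict(cfg.get("simulate") or {})
        if "seed" in cfg:
            sim_kwargs["seed"] = cfg["seed"]
        if "deg_tissues" in sim_kwargs:
            sim_kwargs["deg_tissues"] = tuple(sim_kwargs["deg_tissues"])
        atlas_cfg = AtlasConfig(**sim_kwargs)
        logger.info("simulating atlas: %d genes, %d tissues", atlas_cfg.n_genes, atlas_cfg.n_tissues)
        em_a, em_b, omap, truth = generate_atlas(atlas_cfg)
        write_atlas(out_dir, em_a, em_b, omap, truth)
    elif "inputs" in cfg:
        logger.info("loading input matrices")
        em_a, em_b, omap = _load_inputs(cfg["inputs"])
    else:
        raise ValueError("config needs a 'simulate' or an 'inputs' block")

    label_a = em_a.metadata["species"].iloc[0]
    label_b = em_b.metadata["species"].iloc[0]
    summary: dict = {
        "species": [label_a, label_b],
        "thresholds": dataclasses.asdict(thr),
    }
    if "seed" in cfg:
        summary["seed"] = cfg["seed"]

    # -- stage: profiles and expressed counts ----------------------------------
    logger.info("computing per-tissue median profiles")
    prof_a = median_profile(em_a)
    prof_b = median_profile(em_b)
    prof_a.to_csv(out_dir / "profile_a.tsv", sep="\t")
    prof_b.to_csv(out_dir / "profile_b.tsv", sep="\t")
    expr_a = count_expressed(prof_a, thr)
    expr_b = count_expressed(prof_b, thr)
    rho_expr, p_expr = _safe_spearman(expr_a, expr_b)
    summary["expressed"] = {
        "counts_a": expr_a.to_dict(),
        "counts_b": expr_b.to_dict(),
        "spearman_rho": rho_expr,
        "spearman_p": p_expr,
    }

    # -- stage: homology-category accounting ------------------------------------
    acc = {}
    for label, prof, sp in ((label_a, prof_a, "a"), (label_b, prof_b, "b")):
        counts_prop, mass_prop = category_accounting(prof, omap, sp, thr)
        acc[label] = {
            "expressed_proportion_mean": counts_prop.mean(axis=0).to_dict(),
            "expression_mass_proportion_mean": mass_prop.mean(axis=0).to_dict(),
        }
    summary["category_accounting"] = acc

    # -- stage: tissue-specific genes -------------------------------------------
    logger.info("calling tissue-specific genes")
    tsg_res_a = de.call_tsg(em_a, thr)
    tsg_res_b = de.call_tsg(em_b, thr)
    _write_de_tables(tsg_res_a, out_dir, "tsg_a")
    _write_de_tables(tsg_res_b, out_dir, "tsg_b")
    tsg_a = de.tsg_sets(tsg_res_a)
    tsg_b = de.tsg_sets(tsg_res_b)
    counts_tsg_a = {t: len(s) for t, s in tsg_a.items()}
    counts_tsg_b = {t: len(s) for t, s in tsg_b.items()}
    rho_tsg, p_tsg = _safe_spearman(counts_tsg_a, counts_tsg_b)

    pairs = omap.one_to_one_pairs()
    b_to_a = dict(zip(pairs["gene_b"], pairs["gene_a"]))
    universe = [g for g in pairs["gene_a"] if g in set(em_a.gene_ids)]
    tsg_a_11 = {t: {g for g in s if g in set(universe)} for t, s in tsg_a.items()}
    tsg_b_11 = {
        t: {b_to_a[g] for g in s if g in b_to_a} for t, s in tsg_b.items()
    }
    overlap_tab = comparative.tsg_overlap_tests(tsg_a_11, tsg_b_11, universe)
    overlap_tab.to_csv(out_dir / "tsg_overlap.tsv", sep="\t")
    summary["tsg"] = {
        "counts_a": counts_tsg_a,
        "counts_b": counts_tsg_b,
        "spearman_rho": rho_tsg,
        "spearman_p": p_tsg,
        "overlap": {
            t: {
                "overlap": int(row["overlap"]),
                "p": float(row["p"]),
                "fdr": float(row["fdr"]),
            }
            for t, row in overlap_tab.iterrows()
        },
    }

    # -- stage: housekeeping genes ----------------------------------------------
    logger.info("classifying housekeeping genes")
    phkg_a = hk.call_phkg(prof_a, thr)
    phkg_b = hk.call_phkg(prof_b, thr)
    shared_a = {g for g in phkg_a if g in set(pairs["gene_a"])}
    a_to_b = dict(zip(pairs["gene_a"], pairs["gene_b"]))
    shared = sorted(g for g in shared_a if a_to_b[g] in phkg_b)
    summary["hkg"] = {
        "n_phkg_a": len(phkg_a),
        "n_phkg_b": len(phkg_b),
        "n_shared": len(shared),
    }
    if len(shared) >= 4:
        rec_a = hk.hkg_records(prof_a, shared, thr)
        rec_b = hk.hkg_records(prof_b, [a_to_b[g] for g in shared], thr)
        rec_b.index = rec_a.index  # paired orthologs: report in species-A ids
        rec_a.to_csv(out_dir / "hkg_a.tsv", sep="\t")
        rec_b.to_csv(out_dir / "hkg_b.tsv", sep="\t")
        var_tab = hk.consistency_table(
            rec_a["variability_tier"], rec_b["variability_tier"]
        )
        summary["hkg"]["variability_counts"] = {
            a: var_tab.counts.loc[a].to_dict() for a in var_tab.counts.index
        }
        summary["hkg"]["variability_consistent_fraction"] = var_tab.consistent_fraction
        low_both = rec_a.index[
            (rec_a["variability_tier"] == "low") & (rec_b["variability_tier"] == "low")
        ]
        if len(low_both):
            lev_tab = hk.consistency_table(
                rec_a.loc[low_both, "level_tier"],
                rec_b.loc[low_both, "level_tier"],
                hk.LEVEL_TIERS,
            )
            summary["hkg"]["level_counts"] = {
                a: lev_tab.counts.loc[a].to_dict() for a in lev_tab.counts.index
            }
            summary["hkg"]["level_consistent_fraction"] = lev_tab.consistent_fraction

    # -- stage: cross-species DEGs ----------------------------------------------
    logger.info("calling cross-species DEGs")
    al_a, al_b = align_one_to_one(em_a, em_b, omap)
    deg_res = de.species_deg(al_a, al_b, thr)
    _write_de_tables(deg_res, out_dir, "deg")
    summary["deg"] = {
        t: {
            "n_up": int(res.table["up"].sum()),
            "n_down": int(res.table["down"].sum()),
        }
        for t, res in deg_res.items()
    }

    div = de.rank_divergence(deg_res, thr)
    divergent = {t: d for t, (d, _) in div.items()}
    conserved = {t: c for t, (_, c) in div.items()}
    overlap_div = comparative.tsg_divergence_overlap(tsg_a_11, divergent, conserved)
    overlap_div.to_csv(out_dir / "tsg_divergence_overlap.tsv", sep="\t")
    summary["tsg_divergence_overlap"] = {
        t: {
            "frac_divergent": row["frac_divergent"],
            "frac_conserved": row["frac_conserved"],
        }
        for t, row in overlap_div.iterrows()
    }

    # -- stage: profile-level conservation --------------------------------------
    prof_al_a = median_profile(al_a)
    prof_al_b = median_profile(al_b)
    shared_tissues = sorted(set(prof_al_a.columns) & set(prof_al_b.columns))
    windows = pd.DataFrame(
        {
            t: comparative.decile_shared(prof_al_a, prof_al_b, t)
            for t in shared_tissues
        }
    )
    windows.to_csv(out_dir / "decile_shared.tsv", sep="\t")
    summary["decile_shared_mean"] = windows.mean(axis=1).to_dict()

    corr = correlation_structure(prof_al_a, prof_al_b, thr, labels=(label_a, label_b))
    summary["correlation"] = {
        "same_tissue_cross_species": corr.same_tissue_cross_species,
        "cross_tissue_within_species": corr.cross_tissue_within_species,
    }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out_dir / "summary.json")
    return summary
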