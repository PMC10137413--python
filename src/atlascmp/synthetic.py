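"""Two-species synthetic expression atlas with planted ground truth.

The generator emulates the structure of a paired multi-tissue bulk RNA-seq
atlas of two closely related species: ~20 tissue classes sampled in both
species, a gene set partitioned into homology categories (one-to-one,
complex, no homology, non-protein), and three kinds of planted signal on
one-to-one orthologs only —

* **TSGs** (tissue-specific genes): a large positive log2 effect in one
  designated tissue, in both species;
* **HKGs** (housekeeping genes): high baseline and tissue effects rescaled
  so the across-tissue coefficient of variation of noise-free per-tissue
  medians stays below a target;
* **species DEGs**: a positive log2 effect in species A only, confined to
  designated tissues (emulating the skin-like divergence pattern).

Expression is simulated on the log2 scale as

    baseline + tissue effect + planted effects + N(0, noise_sd) per sample,

exponentiated, and each sample column renormalized to sum to 1e6 (TPM
semantics).  Renormalization slightly perturbs planted effect sizes; the
perturbation is small (the per-column scale factors differ by a few
percent across tissues) and is tolerated by the recovery analyses.

Everything is driven by a single seed through independently spawned RNG
streams per stage, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, write_matrix, write_metadata
from .orthology import CATEGORIES, OrthologyMap

__all__ = ["AtlasConfig", "SyntheticTruth", "generate_atlas", "write_atlas", "read_truth"]


@dataclasses.dataclass(frozen=True)
class AtlasConfig:
    """Study conditions for the synthetic atlas.

    Defaults are the conditions exercised throughout the test suite:
    20 tissues × 10 samples per tissue per species, planted effect sizes
    of 3 log2 units, per-sample log2 noise of 0.25, and a gene set of
    4000 genes split 80/10/5/5 across homology categories.

    ``tissue_effect_sd`` (log2 units) controls how strongly ordinary genes
    vary between tissues.  It is kept well below ``tsg_log2fc``/(its own
    tail) so that planted tissue-specific genes are the only genes whose
    one-vs-rest fold change systematically exceeds the calling threshold;
    see docs/methods.md for the calibration argument.
    """

    n_genes: int = 4000
    n_tissues: int = 20
    samples_per_tissue: int = 10
    frac_one_to_one: float = 0.80
    frac_complex: float = 0.10
    frac_no_homology: float = 0.05
    frac_non_protein: float = 0.05
    n_tsg_per_tissue: int = 10
    tsg_log2fc: float = 3.0
    n_hkg: int = 300
    hkg_cv_max: float = 0.10
    deg_tissues: tuple[int, ...] = (0,)
    n_deg_per_tissue: int = 100
    deg_log2fc: float = 3.0
    noise_sd: float = 0.25
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.5
    tissue_effect_sd: float = 0.35
    seed: int = 0
    species_labels: tuple[str, str] = ("species_a", "species_b")

    def __post_init__(self) -> None:
        fracs = (
            self.frac_one_to_one,
            self.frac_complex,
            self.frac_no_homology,
            self.frac_non_protein,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("homology fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("homology fractions must sum to 1")
        for name in ("n_genes", "n_tissues", "samples_per_tissue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tsg_log2fc", "deg_log2fc", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tissue_effect_sd < 0 or self.hkg_cv_max <= 0:
            raise ValueError("tissue_effect_sd must be >= 0 and hkg_cv_max > 0")
        if any(t < 0 or t >= self.n_tissues for t in self.deg_tissues):
            raise ValueError("deg_tissues indices out of range")
        object.__setattr__(self, "deg_tissues", tuple(self.deg_tissues))
        object.__setattr__(self, "species_labels", tuple(self.species_labels))

    @property
    def tissue_names(self) -> list[str]:
        return [f"tissue_{i:02d}" for i in range(self.n_tissues)]

    def category_counts(self) -> dict[str, int]:
        """Gene counts per homology category (per species); remainder after
        rounding is absorbed by the one-to-one class."""
        n = self.n_genes
        nc = round(self.frac_complex * n)
        nn = round(self.frac_no_homology * n)
        npr = round(self.frac_non_protein * n)
        n11 = n - nc - nn - npr
        if n11 <= 0:
            raise ValueError("config leaves no one-to-one genes")
        return {"one2one": n11, "complex": nc, "none": nn, "nonprotein": npr}


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Ledger of planted signal, keyed by per-species gene ids.

    ``tsg`` / ``deg`` map tissue name → planted gene id set, separately
    for the two species (planted genes are one-to-one pairs, so the two
    species' sets correspond element-wise through the orthology map).
    """

    tsg_a: Mapping[str, frozenset]
    tsg_b: Mapping[str, frozenset]
    hkg_a: frozenset
    hkg_b: frozenset
    deg_a: Mapping[str, frozenset]
    deg_b: Mapping[str, frozenset]
    category_a: Mapping[str, str]
    category_b: Mapping[str, str]

    def to_json_dict(self) -> dict:
        return {
            "tsg_a": {t: sorted(s) for t, s in self.tsg_a.items()},
            "tsg_b": {t: sorted(s) for t, s in self.tsg_b.items()},
            "hkg_a": sorted(self.hkg_a),
            "hkg_b": sorted(self.hkg_b),
            "deg_a": {t: sorted(s) for t, s in self.deg_a.items()},
            "deg_b": {t: sorted(s) for t, s in self.deg_b.items()},
            "category_a": dict(sorted(self.category_a.items())),
            "category_b": dict(sorted(self.category_b.items())),
        }


def _gene_ids(prefix: str, counts: dict[str, int]) -> dict[str, list[str]]:
    tag = {"one2one": "o", "complex": "x", "none": "n", "nonprotein": "p"}
    return {
        cat: [f"{prefix}_{tag[cat]}{i:05d}" for i in range(counts[cat])]
        for cat in CATEGORIES
    }


def _scale_effects_to_cv(effects: np.ndarray, target_cv: float) -> np.ndarray:
    """Rescale a centered log2 tissue-effect vector so that the empirical
    CV (sd/mean, n−1 denominator) of ``2**effects`` equals ``target_cv``.

    The CV is strictly increasing in the scale factor, so a bisection on
    the scale converges; degenerate all-equal inputs map to zero effects.
    """
    e = effects - effects.mean()
    if target_cv <= 0 or np.allclose(e, 0):
        return np.zeros_like(e)

    def cv(scale: float) -> float:
        v = 2.0 ** (scale * e)
        return v.std(ddof=1) / v.mean()

    lo, hi = 0.0, 1.0
    while cv(hi) < target_cv and hi < 1e6:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if cv(mid) < target_cv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) * e


def generate_atlas(
    config: AtlasConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologyMap, SyntheticTruth]:
    """Simulate the two-species atlas.

    Returns the two species' TPM matrices (columns renormalized to 1e6),
    the orthology map, and the truth ledger of planted gene sets.
    """
    counts = config.category_counts()
    n11 = counts["one2one"]
    T = config.n_tissues
    tissues = config.tissue_names

    ss = np.random.SeedSequence(config.seed)
    (
        s_base,
        s_tis,
        s_plant,
        s_hkg,
        s_other,
        s_noise_a,
        s_noise_b,
    ) = ss.spawn(7)
    r_base = np.random.default_rng(s_base)
    r_tis = np.random.default_rng(s_tis)
    r_plant = np.random.default_rng(s_plant)
    r_hkg = np.random.default_rng(s_hkg)
    r_other = np.random.default_rng(s_other)

    ids_a = _gene_ids("ga", counts)
    ids_b = _gene_ids("gb", counts)

    # one-to-one orthologs share baseline and tissue effects across species;
    # this is what makes same-tissue cross-species profiles correlate more
    # strongly than different tissues within a species.
    base11 = r_base.normal(config.baseline_log2_mean, config.baseline_log2_sd, n11)
    eff11 = r_tis.normal(0.0, config.tissue_effect_sd, (n11, T))

    # -- planting (one-to-one genes only, mutually disjoint sets) -------------
    need = T * config.n_tsg_per_tissue + config.n_hkg + len(config.deg_tissues) * config.n_deg_per_tissue
    if need > n11:
        raise ValueError(
            f"planted sets need {need} one-to-one genes but only {n11} are available"
        )
    picked = r_plant.choice(n11, size=need, replace=False)
    pos = 0
    tsg_idx: dict[int, np.ndarray] = {}
    for t in range(T):
        tsg_idx[t] = picked[pos : pos + config.n_tsg_per_tissue]
        pos += config.n_tsg_per_tissue
    hkg_idx = picked[pos : pos + config.n_hkg]
    pos += config.n_hkg
    deg_idx: dict[int, np.ndarray] = {}
    for t in config.deg_tissues:
        deg_idx[t] = picked[pos : pos + config.n_deg_per_tissue]
        pos += config.n_deg_per_tissue

    for t, idx in tsg_idx.items():
        eff11[idx, t] += config.tsg_log2fc

    # housekeeping genes: floor the baseline so the renormalized per-tissue
    # median sits ~5 log2 units above 1 TPM (the floor anticipates the
    # column scale 1e6 / expected-mass of the lognormal baseline mix), and
    # rescale tissue effects to half the CV bound, leaving headroom for the
    # column-scale jitter renormalization introduces.
    expected_mass = (
        config.n_genes
        * 2.0**config.baseline_log2_mean
        * math.exp((config.baseline_log2_sd * math.log(2)) ** 2 / 2)
    )
    hkg_floor = math.log2(expected_mass / 1e6) + 5.0
    base11[hkg_idx] = np.maximum(base11[hkg_idx], hkg_floor)
    for g in hkg_idx:
        raw = r_hkg.normal(0.0, 1.0, T)
        eff11[g] = _scale_effects_to_cv(raw, 0.5 * config.hkg_cv_max)

    # species effect: planted DEGs are up-regulated in species A only
    species_delta = np.zeros((n11, T))
    for t, idx in deg_idx.items():
        species_delta[idx, t] += config.deg_log2fc

    # -- non-one-to-one genes: independent per species -------------------------
    n_other = counts["complex"] + counts["none"] + counts["nonprotein"]
    base_other_a = r_other.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_other)
    eff_other_a = r_other.normal(0.0, config.tissue_effect_sd, (n_other, T))
    base_other_b = r_other.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_other)
    eff_other_b = r_other.normal(0.0, config.tissue_effect_sd, (n_other, T))

    level_a = np.vstack(
        [base11[:, None] + eff11 + species_delta, base_other_a[:, None] + eff_other_a]
    )
    level_b = np.vstack([base11[:, None] + eff11, base_other_b[:, None] + eff_other_b])

    # column renormalization divides each tissue by its total mass, which
    # would re-inject across-tissue variation into the planted HKG rows;
    # cancel it there by pre-adding each tissue's (centered) log2 mass.
    for level in (level_a, level_b):
        colsum_log2 = np.log2((2.0**level).sum(axis=0))
        level[hkg_idx] += colsum_log2 - colsum_log2.mean()

    gene_order_a = ids_a["one2one"] + ids_a["complex"] + ids_a["none"] + ids_a["nonprotein"]
    gene_order_b = ids_b["one2one"] + ids_b["complex"] + ids_b["none"] + ids_b["nonprotein"]

    # -- samples ----------------------------------------------------------------
    tissue_of_sample = np.repeat(np.arange(T), config.samples_per_tissue)

    def build_matrix(level, gene_order, species, noise_seed):
        rng = np.random.default_rng(noise_seed)
        log2_vals = level[:, tissue_of_sample] + rng.normal(
            0.0, config.noise_sd, (level.shape[0], tissue_of_sample.size)
        )
        tpm = np.exp2(log2_vals)
        tpm *= 1e6 / tpm.sum(axis=0)
        sample_ids = [
            f"{species}_{tissues[t]}_s{k:02d}"
            for t in range(T)
            for k in range(config.samples_per_tissue)
        ]
        values = pd.DataFrame(tpm, index=gene_order, columns=sample_ids)
        meta = pd.DataFrame(
            {
                "species": species,
                "tissue": [tissues[t] for t in tissue_of_sample],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return ExpressionMatrix(values, meta)

    em_a = build_matrix(level_a, gene_order_a, config.species_labels[0], s_noise_a)
    em_b = build_matrix(level_b, gene_order_b, config.species_labels[1], s_noise_b)

    # -- orthology map ----------------------------------------------------------
    rows = []
    for ga, gb in zip(ids_a["one2one"], ids_b["one2one"]):
        rows.append((ga, gb, "one2one"))
    ncx = counts["complex"]
    for i in range(ncx):
        # many-to-many flavour: each complex gene pairs with two partners
        rows.append((ids_a["complex"][i], ids_b["complex"][i], "complex"))
        if ncx > 1:
            rows.append((ids_a["complex"][i], ids_b["complex"][(i + 1) % ncx], "complex"))
    for ga in ids_a["none"]:
        rows.append((ga, "", "none"))
    for gb in ids_b["none"]:
        rows.append(("", gb, "none"))
    for ga in ids_a["nonprotein"]:
        rows.append((ga, "", "nonprotein"))
    for gb in ids_b["nonprotein"]:
        rows.append(("", gb, "nonprotein"))
    omap = OrthologyMap(pd.DataFrame(rows, columns=["gene_a", "gene_b", "category"]))

    # -- truth ledger -----------------------------------------------------------
    a11 = np.asarray(ids_a["one2one"])
    b11 = np.asarray(ids_b["one2one"])
    truth = SyntheticTruth(
        tsg_a={tissues[t]: frozenset(a11[idx]) for t, idx in tsg_idx.items()},
        tsg_b={tissues[t]: frozenset(b11[idx]) for t, idx in tsg_idx.items()},
        hkg_a=frozenset(a11[hkg_idx]),
        hkg_b=frozenset(b11[hkg_idx]),
        deg_a={tissues[t]: frozenset(a11[idx]) for t, idx in deg_idx.items()},
        deg_b={tissues[t]: frozenset(b11[idx]) for t, idx in deg_idx.items()},
        category_a={g: cat for cat in CATEGORIES for g in ids_a[cat]},
        category_b={g: cat for cat in CATEGORIES for g in ids_b[cat]},
    )
    return em_a, em_b, omap, truth


def write_atlas(
    out_dir,
    em_a: ExpressionMatrix,
    em_b: ExpressionMatrix,
    omap: OrthologyMap,
    truth: SyntheticTruth | None = None,
    compress: bool = True,
) -> dict[str, Path]:
    """Write matrices, metadata, orthology table and truth ledger to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".tsv.gz" if compress else ".tsv"
    paths = {}
    for tag, em in (("a", em_a), ("b", em_b)):
        paths[f"matrix_{tag}"] = out / f"matrix_{tag}{suffix}"
        write_matrix(em, paths[f"matrix_{tag}"])
        paths[f"metadata_{tag}"] = out / f"metadata_{tag}.tsv"
        write_metadata(em, paths[f"metadata_{tag}"])
    paths["orthology"] = out / "orthology.tsv"
    omap.records.to_csv(paths["orthology"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
    return paths


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(
        tsg_a={t: frozenset(s) for t, s in d["tsg_a"].items()},
        tsg_b={t: frozenset(s) for t, s in d["tsg_b"].items()},
        hkg_a=frozenset(d["hkg_a"]),
        hkg_b=frozenset(d["hkg_b"]),
        deg_a={t: frozenset(s) for t, s in d["deg_a"].items()},
        deg_b={t: frozenset(s) for t, s in d["deg_b"].items()},
        category_a=d["category_a"],
        category_b=d["category_b"],
    )
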