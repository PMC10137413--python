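# atlascmp

Comparative analysis of two species' multi-tissue gene expression
atlases. Given one TPM matrix per species (genes × samples, with tissue
and species labels) and an orthology table, `atlascmp`:

* builds per-tissue **median expression profiles** and counts expressed
  genes (median TPM > 0.1),
* calls **tissue-specific genes** (TSGs) by one-vs-rest empirical-Bayes
  moderated t-tests (log2FC > 1.5, BH FDR < 0.05),
* classifies **housekeeping genes**: preliminary HKGs (median TPM > 1 in
  every tissue), variability tiers by CV quartiles, expression-level
  tiers (1–10 / 10–50 / >50 TPM), and cross-species consistency tables,
* calls per-tissue **cross-species DEGs** on quantile-normalized
  one-to-one orthologs (|log2FC| > 1.2, FDR < 0.05) and ranks the most
  divergent / most conserved 10% of orthologs by −log₁₀(p),
* quantifies conservation: hypergeometric TSG overlap between species,
  Spearman correlation of per-tissue counts, decile shared-expression
  windows, and homology-category accounting of expressed genes and
  expression mass.

It is aimed at comparative transcriptomics of closely related species
(the motivating setting is a bovid pair — water buffalo against cattle —
with ~20 shared tissue classes), where the question is how conserved
tissue expression programs, tissue-specific genes, and housekeeping
genes are across the two genomes.

The statistical core is the moderated t-statistic: per-gene pooled
variances s²_g (df residual degrees of freedom) are shrunk toward an
empirical prior (d₀, s₀²) estimated by trigamma moment inversion on
log s²,

    s̃²_g = (d₀·s₀² + df·s²_g)/(d₀ + df),
    t_g = Δ_g / √(s̃²_g(1/n₁ + 1/n₂)),  t_g ~ t(df + d₀) under H₀,

with Benjamini–Hochberg step-up FDR control within each contrast. See
`docs/methods.md` for the full model and every convention.

Because the full two-species data sets behind the motivating study are
hundreds of samples of public downloads, the package ships a
**synthetic atlas generator** (`atlascmp.synthetic`) that plants TSGs,
HKGs and species-DEGs with known identities into a two-species TPM pair,
so the entire pipeline is testable offline against ground truth.

## Worked example

```python
from atlascmp import (AtlasConfig, generate_atlas, call_tsg, tsg_sets,
                      align_one_to_one, species_deg, median_profile,
                      correlation_structure)
from atlascmp.housekeeping import call_phkg

cfg = AtlasConfig(n_genes=2000, n_tissues=10, samples_per_tissue=6, seed=42)
em_a, em_b, omap, truth = generate_atlas(cfg)

tsg = tsg_sets(call_tsg(em_a))
print("TSGs per tissue (species A):", {t: len(s) for t, s in sorted(tsg.items())[:4]}, "...")

al_a, al_b = align_one_to_one(em_a, em_b, omap)
deg = species_deg(al_a, al_b)
print("DEGs per tissue:", {t: int(r.table["deg"].sum()) for t, r in sorted(deg.items())[:4]}, "...")

phkg = call_phkg(median_profile(em_a))
print("preliminary housekeeping genes (species A):", len(phkg))

cs = correlation_structure(median_profile(al_a), median_profile(al_b))
print(f"same-tissue cross-species r = {cs.same_tissue_cross_species:.3f}; "
      f"cross-tissue within-species r = {cs.cross_tissue_within_species:.3f}")
```

prints

```
TSGs per tissue (species A): {'tissue_00': 110, 'tissue_01': 10, 'tissue_02': 10, 'tissue_03': 10} ...
DEGs per tissue: {'tissue_00': 101, 'tissue_01': 0, 'tissue_02': 0, 'tissue_03': 0} ...
preliminary housekeeping genes (species A): 1991
same-tissue cross-species r = 0.993; cross-tissue within-species r = 0.966
```

Reading the output: each tissue recovers its 10 planted TSGs;
`tissue_00` additionally carries the 100 planted species-DEG genes,
which are genuinely tissue-specific in species A (their +3 log2 species
effect lives only in that tissue) and are likewise detected as the
dominant DEG signal (101 calls, ~1 false). With the generator's mild
tissue effects nearly all genes clear the housekeeping pre-filter, and
the same tissue in the *other species* correlates more strongly
(r ≈ 0.99) than different tissues within a species (r ≈ 0.97) — the
hallmark of conserved tissue expression programs.

The same stages are scriptable from the shell:

```sh
atlascmp simulate --config cfg.yaml --out data/
atlascmp run --config cfg.yaml            # full pipeline + summary.json
atlascmp tsg --matrix data/matrix_a.tsv.gz --metadata data/metadata_a.tsv --out tsg_a.tsv
```

where `cfg.yaml` holds `simulate:` (or `inputs:`) / `thresholds:` /
`output_dir:` / `seed:` blocks.

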