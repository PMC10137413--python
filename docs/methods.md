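# Methods

`atlascmp` implements a comparative analysis of two species' multi-tissue
bulk RNA-seq expression atlases: tissue-specific gene (TSG) detection,
housekeeping gene (HKG) classification, cross-species differential
expression on one-to-one orthologs, conservation/divergence ranking, and
set-overlap statistics — validated end to end on a synthetic two-species
atlas with planted ground truth.

## Data model

The unit of input is a genes × samples matrix of TPM values (columns sum
to 10⁶) with per-sample species and tissue labels, one matrix per
species, plus an orthology table assigning every gene to a homology
category: `one2one` (unique ortholog pair), `complex` (one-to-many /
many-to-one / many-to-many), `none`, or `nonprotein`. All cross-species
quantitative comparisons are restricted to one-to-one pairs; the other
categories enter only the per-tissue accounting of expressed-gene counts
and expression mass.

A tissue's expression state is summarized by its **median profile**: the
per-tissue median TPM of every gene (even sample counts use the midpoint
of the two central order statistics). "Expressed" always means per-tissue
median TPM strictly greater than 0.1 — the boundary value is excluded.
Log expression is `log2(TPM + 0.25)` throughout.

## Tissue-specific genes

For each tissue, a one-vs-rest two-group comparison on log expression
within one species. The test statistic is the empirical-Bayes moderated
t: per-gene pooled variances s²_g with df = n₁ + n₂ − 2 are shrunk toward
a prior via

  s̃²_g = (d₀·s₀² + df·s²_g) / (d₀ + df),

and t_g = Δ_g / √(s̃²_g(1/n₁ + 1/n₂)) is referred to Student-t with
df + d₀ degrees of freedom. The prior is estimated by the method of
moments on z = log s²: under the scaled-inverse-χ² hierarchy
Var(z) = ψ′(df/2) + ψ′(d₀/2), so ψ′(d₀/2) = Var(z) − ψ′(df/2) is inverted
by Newton iteration on the trigamma function (relative tolerance 1e-8,
initialised at 0.5 + 1/target as in the standard trigamma-inverse
recipe), with d₀ = ∞ whenever the observed dispersion of z does not
exceed what sampling alone implies; s₀² follows from E(z) with the
digamma bias corrections of both χ² factors. Two-sided p-values are
Benjamini–Hochberg adjusted within each contrast (step-up:
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, capped at 1).

A gene is a TSG iff log2FC > 1.5 **and** FDR < 0.05, where log2FC is the
difference of group means of log expression and only over-expression in
the focal tissue qualifies. Degenerate cases: a single gene (or all-zero
residual variances) falls back to the ordinary pooled t; a zero-variance
gene gets p = 0 when its fold change is non-zero and p = 1 otherwise.

## Cross-species differential expression

The two matrices are restricted to one-to-one pairs, log-transformed, and
**quantile-normalized jointly across all samples of both species** (the
reference distribution is the across-column mean of sorted values; tied
ranks interpolate linearly). This is a deliberate, deterministic
substitute for anchor-based dataset integration: it removes global
distributional shifts between the two data sets while preserving
within-column ranks. Per tissue, species A is tested against species B
with the same moderated-t engine; a DEG requires |log2FC| > 1.2 and
FDR < 0.05, with positive fold changes reported as up-regulated in
species A. (1.2 is the default; the cutoff is configurable because both
1.2 and 1.3 circulate for this analysis.)

Genes are then ranked per tissue by −log₁₀(p) (ties: larger |log2FC|
first, then lexicographic gene id); the top ⌈0.10·m⌉ are the most
divergent genes and the bottom ⌈0.10·m⌉ the most conserved.

## Housekeeping genes

Preliminary HKGs (pHKGs) are genes whose per-tissue median TPM exceeds 1
in **every** tissue (strict; a mean-based variant is available behind
`rule="mean"` because both phrasings circulate). Expression stability is
the coefficient of variation CV = sd/mean (sample sd, n − 1) of the
per-tissue medians — computed on tissue-level medians, not raw samples,
and therefore scale-invariant. On the cross-species **shared** pHKG set,
each species' CV distribution is split at its quartiles
(linear-interpolation convention): low (CV ≤ Q1), medium (Q1 < CV < Q3),
high (CV ≥ Q3); if Q1 = Q3 the low tier wins (deterministic precedence,
with a warning). Low-variability pHKGs are the HKGs proper and are
sub-tiered by mean expression: low (1 < TPM ≤ 10), medium
(10 < TPM ≤ 50), high (TPM > 50) — boundaries inclusive on the upper
side. Cross-species conservation is reported as 3 × 3 tier contingency
tables and their diagonal fractions.

## Overlap and conservation statistics

* **TSG overlap**: per tissue, the exact upper-tail hypergeometric
  probability P(X ≥ k) of the two species' TSG sets within the universe
  of one-to-one orthologs entering the analysis (all of them, not only
  expressed ones — the most conservative well-defined universe), BH
  adjusted across tissues.
* **Spearman correlations** of per-tissue counts use average ranks; for
  n ≤ 10 the two-sided p-value is the exact permutation tail, enumerated
  in chunks; larger n uses the t-approximation.
* **Decile windows**: per tissue and species, genes ranked by median
  expression descending (ties by gene id), split into ten contiguous
  windows with any remainder assigned to the highest-expression windows;
  the shared fraction per window is the cross-species window
  intersection over the window size.
* **Over-representation**: a generic hypergeometric test of a query set
  against user-supplied annotation sets, BH across terms. No annotation
  database ships with the package.

## Synthetic atlas and planted truth

The generator emulates the *structure* of a paired two-species atlas so
that every stage can be validated against known truth. Expression is
built per gene on the log2 scale:

  baseline + tissue effect + planted effects + N(0, noise_sd) per sample,

exponentiated and column-renormalized to 10⁶. One-to-one orthologs share
baseline and tissue effects across species — this single assumption
produces the characteristic ordering in which the same tissue in the
other species correlates more strongly than a different tissue in the
same species. Non-one-to-one genes receive independent per-species
effects and never carry planted signal.

Default study conditions (all configurable): 20 tissues × 10 samples per
tissue per species; 4000 genes split 80/10/5/5 across the homology
categories; baseline log2 level ~ N(3, 2.5²); tissue effects
~ N(0, 0.35²) log2 units; per-sample noise sd 0.25 log2 units; 10 planted
TSGs per tissue and 100 planted species-DEGs in one designated tissue,
both with effects of 3 log2 units; 300 planted HKGs with an across-tissue
CV bound of 0.10.

The tissue-effect sd of 0.35 is a calibration, not an afterthought: with
sd σ the one-vs-rest fold change of an ordinary gene is approximately
N(0, σ²(1 + 1/(T−1))), so σ = 0.35 keeps the probability of an unplanted
gene crossing the 1.5 log2FC calling threshold near 2·10⁻⁵ per
gene×tissue while still giving every gene genuine tissue structure. A
substantially larger σ would make "natural" tissue-specific genes common,
which is realistic but makes recovery of *planted* TSGs unmeasurable —
the false-discovery proportion against the planted ledger would be
dominated by genuine but unplanted signal.

Planted HKGs get a baseline floor placed ~5 log2 units above the level
at which the renormalized median would fall to 1 TPM (computed from the
expected lognormal column mass), and their tissue-effect vector is
bisection-rescaled so the noise-free CV of 2^effects equals half the
configured bound. Because column renormalization divides each tissue by
its own total mass — which would re-inject across-tissue variation into
these flat rows — the generator pre-adds each tissue's centered log2
column mass to the planted HKG rows, cancelling the renormalization
exactly in the noise-free limit. The remaining noise-driven CV is well
below the bound at the default settings.

One scoring convention follows from the construction: a planted
species-DEG gene carries its +3 effect in one tissue of species A and is
therefore *genuinely* tissue-specific there by the TSG definition. TSG
recovery scoring treats such calls as planted signal of another kind —
exempt from the false-positive count, never counted toward recall.

Randomness flows from a single seed through per-stage spawned RNG
streams, so identical configs give bit-identical matrices, maps and
truth ledgers.

### What the generator does not emulate

Read-level sampling (counts, library-size variation, length bias),
batch/library-prep artifacts, correlated gene programs, isoform
structure, unbalanced tissue panels between species, and the large
silent-gene fraction of real transcriptomes (with the default lognormal
baseline nearly every gene clears both the expression and the pHKG
cutoffs, so pHKG counts are proportionally much higher than in real
atlases). Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated generative model, not
robustness to these real-data complications.

## Validation problem sizes

The test suite validates the combinatorial statistics exactly
(hypergeometric tail vs full enumeration over universes up to 12;
BH vs an independent step-up reference on vectors up to length 12;
the unshrunk moderated t vs the closed-form pooled t to 1e-9), the
moderated test's calibration under the global null (5000 genes × 200
replicates of 10-vs-10; empirical type-I error required to fall in
[0.04, 0.06] at p < 0.05), prior recovery from 2000 simulated variances
at (d₀, s₀²) = (4, 1) (required within [2.5, 6.5] × [0.8, 1.25]), and
planted-signal recovery at the default study conditions (TSG/DEG recall
≥ 0.90 with false-discovery proportion ≤ 0.10; ≥ 95% of planted HKGs in
the low-variability tier). Pipeline determinism is asserted as
byte-identical summary JSON across repeated runs. These sizes keep the
whole suite under a minute of compute while leaving the statistical
assertions with comfortable Monte-Carlo margins.

## Known limitations

* The moderated test assumes independent genes and equal within-group
  variances; no voom-style mean–variance weighting and no covariates
  beyond the two-group design.
* Quantile normalization assumes the two species share an expression
  distribution shape; a genuine global shift in distributional form
  would be normalized away.
* The hypergeometric overlap universe and the divergent/conserved sets
  are per-tissue conventions; other universes (expressed-only) are
  supported but not the default.
* CV quartiles are computed per species on the shared pHKG set; a pooled
  alternative would shift tier boundaries.
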