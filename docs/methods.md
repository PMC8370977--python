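# Methods

## Data model

The analysis unit is the protein subgroup as exported by the search engine:
one row per protein with gene symbol, number of distinct peptides,
search-engine protein score, and one nonnegative value per TMT 11-plex
channel. Channel values may be raw reporter-ion intensities or mean ratios
to a base channel; every downstream statistic is a ratio of two channels,
so the two conventions are interchangeable (`compute_ratios` divides the
two columns either way, and a dedicated test asserts the equivalence).
Missing values are NaN throughout — never zero — and a missing or zero
denominator yields a missing ratio.

Gene symbols are uppercased and whitespace-stripped before any set
operation; all annotation matching is by symbol, not accession, because
curated TP/FP/annotation lists are symbol-keyed. Under strict parsing two
symbols that collide after normalization are an error; otherwise the row
with the higher protein score is kept.

The detection filter retains proteins with at least 2 distinct peptides
and a protein score of at least 20 (both inclusive); these defaults are
the conventional confidence filter for this kind of export and are
configurable per design.

## Pairwise ROC filtering

For one comparison (an experimental channel over a control or reference
channel) the proteins are ranked by ratio in descending order. Tied ratios
form a single threshold: a protein can never be separated from another
protein carrying the same ratio, and any per-gene ordering of ties would
be arbitrary and irreproducible. At each distinct value t,

    TPR(t) = |{g in TP : ratio(g) >= t}| / |TP among ranked|
    FPR(t) = |{g in FP : ratio(g) >= t}| / |FP among ranked|

with denominators counting only curated genes actually present in the
ranked list. The cutoff maximizes J(t) = TPR(t) − FPR(t) (the Youden
index of the empirical curve); among equal-J thresholds the highest —
most stringent — wins, minimizing false positives at equal J. The cutoff
is applied inclusively (ratio ≥ t\*), so the cutoff-defining protein is
itself retained, and it is applied to *all* ranked proteins, curated or
not. Because ranking and the argmax are order statistics, any strictly
increasing transform of the ratios (log, linear rescale, …) leaves the
selected gene set unchanged; this invariance is property-tested, and a
brute-force threshold sweep from the set definitions serves as the
oracle for the curve construction.

Degenerate inputs: no TP among the ranked proteins is an error (the curve
would be uninformative); no FP gives a valid curve with FPR ≡ 0 and a
warning; a gene on both curated lists is rejected at load time rather
than resolved by guessing.

Per replicate, each configured comparison gets its own independent ROC
cutoff. Designs with a spatial reference make two comparisons per
replicate — experimental vs background control with the compartment TP /
contamination FP lists, and experimental vs reference with
reference-specific TP/FP lists — and the replicate's enriched set is the
intersection of its post-cutoff sets. A protein missing a ratio in any
comparison of a replicate fails that replicate (conservative; no
imputation, no partial credit). Within-replicate intersection happens
before cross-replicate intersection; a protein enters the final proteome
if it survives in at least k replicates (k = 2 of 3 for the nucleus-style
design, all replicates for the nucleolus-style design, 2 of 2 for the
membrane designs). Last, annotated glycoprotein / secretory-pathway
contaminants are removed; this stage comes after intersection so the
stage counts expose how many contaminants survive ratiometric filtering —
phase separation enriches glycan-bearing proteins regardless of RNA
binding, so enrichment ratios cannot remove them. Omit-crosslink control
channels never participate in filtering; they feed only the crosslink-
dependence metric.

The pipeline records per-gene provenance (every ratio, every pass flag,
replicate support) and a run manifest (design hash, every selected
cutoff), and is deterministic: identical inputs give identical outputs.

An optional per-channel median-centering switch (default off) divides each
channel column by its median before ratios are formed, for exports whose
normalization status is unknown.

## Statistical filter

The alternative filter tests each protein on the log2 scale. With
moderation off, an ordinary Welch t-test of experimental vs pooled control
channels (zero-variance ties resolved as t = 0, p = 1). With moderation on
(default), per-protein pooled variances are shrunk toward a prior fitted
across proteins by empirical Bayes: the prior scale s₀² and degrees of
freedom d₀ are estimated by method of moments on the log residual
variances (trigamma inversion by Newton iteration), the posterior variance
is (d₀s₀² + d·s²)/(d₀ + d), and the moderated t carries d + d₀ degrees of
freedom — infinite d₀ (no detectable between-protein variance spread)
collapses to a z-test on the common variance. Exact numeric parity with
any external moderated-t implementation is not promised; correctness is
established through closed-form Welch agreement, null calibration, and
planted-effect recovery.

The reference-contrast variant estimates, per protein,
(target − target controls) − (reference − reference controls) with a
single pooled residual variance over the four groups; a protein equally
enriched by target and reference constructs has effect ≈ 0.

p-values are two-sided; directionality is imposed by the fold-change
threshold. Fold change is the ratio of linear-scale group means, and the
enrichment call is adj. p < α (default 0.05) and fold change strictly
greater than the threshold (default 1). Benjamini–Hochberg adjustment is
the standard step-up (q(i) = p(i)·m/i on the ascending sort, monotonicity
enforced from the top, capped at 1); proteins with fewer than two
observations in a group are flagged untestable and excluded from m.

## Evaluation metrics

Specificity of a called proteome against an annotation set is
|called ∩ annotation| / |called|; sensitivity (coverage) against a
curated gold standard is |called ∩ gold| / |gold|. Orphans are called
proteins carrying neither prior RNA-binding nor compartment annotation —
the candidate novel findings. Overlaps between proteomes are reported as
exact-membership region counts, which are inclusion–exclusion consistent
by construction. Percentages are reported to one decimal place, computed
on unrounded fractions.

Group comparisons (protein abundance of shared vs method-exclusive calls;
+FA/−FA crosslink dependence of RRM-domain vs unknown-domain proteins)
use the one-sided Wilcoxon rank-sum test with mid-rank tie handling:
exact by enumeration of all rank assignments for combined n ≤ 16
(p = P(W ≤ w) for the "less" alternative), normal approximation with
tie-corrected variance and continuity correction above. The exact branch
is verified against an independent enumeration oracle and against scipy's
exact test on tie-free data.

The per-protein crosslink-dependence ratio is the mean of the
experimental channel values over the mean of the omit-crosslink control
channel values; low values flag tight binders that survive phase
separation without chemical crosslinking.

RNA-binding-domain subclassification counts proteins with ≥1 classical
domain, with only nonclassical domains, and with no annotated domain;
a protein carrying both kinds counts as classical, and the three bins
partition the proteome.

## Synthetic data

The generator emulates one TMT 11-plex proximity-labeling experiment with
planted classes: tight (crosslink-independent) compartment RBPs,
crosslink-dependent compartment RBPs, off-compartment RBPs, compartment
non-RBPs, glycoprotein contaminants, and background. The log2 reporter
value of protein g in channel c is

    base_g + effect(class(g), role(c)) + N(0, noise_sd)

with base_g ~ N(17, 1.5²) on the log2 scale (a realistic reporter-ion
dynamic range) and noise_sd = 0.5 by default. Background-control channels
carry baseline for every class; experimental channels add the class
effect (default 2.0 log2, i.e. 4-fold, for compartment RBPs and
glycoproteins; baseline for off-compartment proteins, which are not
biotinylated by the targeted construct); spatial-reference channels carry
the reference effect (2.0 for off-compartment RBPs, 0.5 residual for
compartment RBPs and glycoproteins); omit-crosslink channels carry the
full effect only for tight binders and glycoproteins. In the +PUR
membrane preset the crosslink-dependent class drops to 1.0 log2,
modeling loss of polysome-mediated RNA engagement under translation
arrest, which makes the +PUR proteome smaller and largely a subset of
the basal one. Peptide counts and protein scores are sampled so that a
configurable fraction (8% by default) fails the detection filter.

Emitted annotation lists are consistent with the truth labels: the
curated TP list samples 40% of the compartment RBPs, the FP list 50% of
the off-compartment class, the gold standard 30% of the compartment RBPs,
and the RBP compendium contains all planted RBP classes plus 5% of the
background class (annotation noise). Glycoproteins are planted as
compartment-enriched, crosslink-independent contaminants: they pass every
ratiometric stage by construction and must be removed by the glycoprotein
list, which is exactly their intended failure mode.

The default universe adds 600 background proteins to the
150/100/100/50 planted classes, giving ~1000 proteins (~920 detected) — a
realistically sized detected proteome relative to published experiments
of this type. Recovery is measured among planted proteins that pass the
detection filter, since the ratiometric stages cannot recover proteins
the detection filter removed.

What the generator does **not** model: ratio compression from co-isolation
interference, TMT isotopic impurity spillover, peptide-level missingness
structure, correlated protein baselines (complex stoichiometry), or
between-replicate batch effects. Passing recovery tests therefore
demonstrates correctness of the filtering logic under the stated noise
model, not performance on real spectra.

## Numerical choices

- Youden-tie resolution toward the most stringent threshold uses a 1e-9
  tolerance; true J values live on the rational grid of TP/FP counts, far
  coarser than the tolerance, so the guard only absorbs float jitter.
- Trigamma inversion: Newton iteration with the standard asymptotic
  endpoints (y > 1e7 → 1/√y, y < 1e-6 → 1/y), tolerance 1e-10.
- BH input validation requires p ∈ (0, 1]; p-values are clipped away from
  exact zero (from infinite t statistics) before adjustment.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seed and configuration give byte-identical outputs.

## Problem sizes

Simulated experiments use ~1000 proteins across 5–9 channels; oracle
sweeps use ≤200-gene instances (500 draws) and exact rank-sum enumeration
uses group sizes ≤ 8. These sizes fully exercise every code path — the
statistics are count-based, so larger instances change precision, not
behavior.

## Known limitations

- The ROC cutoff depends on the curated TP/FP lists; small or biased lists
  shift the cutoff (visible in the simulations as seed-to-seed cutoff
  variance). The package treats list curation as an input, not a task.
- The moderated t assumes a common variance model per protein across
  groups; array-weight, trend and robust variants are out of scope.
- The statistical filter's reference contrast assumes shared negative
  controls are appropriate for both constructs.
- Published-count reproduction requires the original study's protein
  tables, which must be supplied by the user (see README).
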