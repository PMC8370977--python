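# rbpmap

Inference of compartment-specific RNA-binding proteomes (RBPomes) from
multiplexed proximity-labeling proteomics.

## The problem

Proximity labeling with an engineered peroxidase (APEX2) biotinylates
proteins within ~10 nm of a genetically targeted construct in live cells;
combining it with RNA–protein crosslinking and organic–aqueous phase
separation enriches the RNA-binding proteins (RBPs) of a chosen
subcellular compartment — including compartments that cannot be purified
biochemically, such as the nucleolus or the cytosolic face of the outer
mitochondrial membrane. The enriched samples are quantified in a TMT
11-plex together with negative controls (omit-enzyme, omit-H₂O₂, omit
crosslinker) and, for sub-compartments, a spatial-reference construct.

The statistical task is to turn the per-protein TMT reporter ratios into a
defensible gene list. This package implements the **pairwise ROC
strategy**:

1. rank proteins by the TMT ratio of each experimental/control comparison
   in descending order;
2. using curated true-positive (TP) and false-positive (FP) gene lists,
   accumulate TPR(t) = |{TP with ratio ≥ t}| / |TP ranked| and the analogous
   FPR(t) at every distinct ratio value t, giving an empirical ROC curve;
3. place the enrichment cutoff at the Youden optimum,
   t\* = argmax_t [TPR(t) − FPR(t)], ties resolved toward the most
   stringent threshold;
4. intersect the post-cutoff lists of a replicate's dual comparisons
   (background control and spatial reference), then intersect replicates
   (k-of-n support);
5. remove annotated glycoprotein / secretory-pathway contaminants, which
   phase separation co-enriches independent of RNA binding.

An alternative **statistical filter** is provided: per-protein moderated
t-tests (empirical-Bayes variance shrinkage in the style of limma) of
experimental versus pooled control channels on the log2 scale, a
reference-contrast variant estimating
(target − target controls) − (reference − reference controls),
Benjamini–Hochberg correction, and an enrichment call at
adj. p < 0.05 and fold change > 1.

Dataset-level metrics — annotation specificity, gold-standard sensitivity
(coverage), orphan detection, set overlaps, abundance-stratified Wilcoxon
rank-sum comparisons, RNA-binding-domain subclassification, and crosslink
(+FA/−FA) dependence — evaluate the called proteomes. A synthetic TMT
generator with planted ground-truth classes makes every stage testable
without any external data.

## Worked example

```python
from rbpmap import build_roc, select_cutoff, apply_cutoff

ratios = {"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0}
roc = build_roc(ratios, tp_set={"g1", "g2", "g4"}, fp_set={"g3", "g5"})
cutoff = select_cutoff(roc)
print(cutoff, roc.j_stat[roc.cutoff_index], sorted(apply_cutoff(ratios, cutoff)))
```

prints

```
4.0 0.6666666666666667 ['g1', 'g2']
```

At threshold 4 two of the three TPs are above the cutoff (TPR = 2/3) and no
FP is (FPR = 0), so TPR − FPR = 2/3 — the maximum over all five
thresholds — and the post-cutoff proteome is {g1, g2}.

The full chain on a simulated experiment:

```python
from rbpmap import preset, generate, run_pipeline

cfg = preset("nucleus", seed=1)
table, annotations, truth = generate(cfg)
result = run_pipeline(table, cfg.design, annotations)
print(result.stage_counts)
```

prints

```
{'detected': 920, 'post_roc': {1: 203, 2: 251, 3: 174}, 'post_intersection': 190, 'post_glyco': 146}
```

— of 1000 simulated proteins, 920 pass the detection filter (≥2 distinct
peptides, protein score ≥ 20), the three replicate ROC cutoffs keep
203/251/174, 190 are supported by at least two replicates, and 146 remain
after glycoprotein removal; 97% of the planted, detected compartment RBPs
are recovered.

## Analysis drivers

Numbered scripts under `analysis/` run the whole study on simulated data
and write their tables under `results/`:

```
python analysis/01_simulate.py --seed 1   # datasets for all four presets
python analysis/02_filter_roc.py          # pairwise-ROC pipeline + stage counts
python analysis/03_filter_stat.py         # moderated-t filter + ROC comparison
python analysis/04_metrics.py             # specificity / sensitivity / orphans / overlaps
```

Presets: `nucleus` (three replicates, single background comparison each),
`nucleolus` (dual comparison against a whole-nucleus spatial reference,
all-replicate intersection), `omm_basal` and `omm_pur` (two replicates,
dual comparison against a cytosolic reference, ± translation stress).

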