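"""Annotation resources and dataset-level evaluation metrics.

Specificity is the fraction of a called proteome carrying a prior annotation
(RNA binding, compartment membership); sensitivity is the fraction of a
curated gold-standard list recovered.  Orphans are called proteins with
neither annotation — the candidate novel findings.  Group comparisons
(protein abundance, crosslink dependence) use one-sided Wilcoxon rank-sum
tests with mid-rank tie handling, exact by enumeration for small samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .quant_io import ValidationError, normalize_symbol


# ---------------------------------------------------------------------------
# annotation resource
# ---------------------------------------------------------------------------

@dataclass
class AnnotationResource:
    """Curated gene sets and maps driving filtering and evaluation.

    ``tp_background``/``fp_background`` are the curated true/false positive
    lists for comparisons against enrichment (omit-enzyme / omit-H2O2)
    controls; ``tp_reference``/``fp_reference`` are the lists for comparisons
    against a spatial-reference construct.  The TP and FP list of a pair must
    be disjoint (validated).
    """

    tp_background: set = field(default_factory=set)
    fp_background: set = field(default_factory=set)
    tp_reference: set | None = None
    fp_reference: set | None = None
    glyco_set: set = field(default_factory=set)
    rbp_compendium: set = field(default_factory=set)
    compartment_set: set = field(default_factory=set)
    gold_standard: set = field(default_factory=set)
    rbd_map: dict[str, set] = field(default_factory=dict)
    domain_classes: dict[str, str] = field(default_factory=dict)
    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        def norm(s):
            return {normalize_symbol(g) for g in s} if s is not None else None
        self.tp_background = norm(self.tp_background)
        self.fp_background = norm(self.fp_background)
        self.tp_reference = norm(self.tp_reference)
        self.fp_reference = norm(self.fp_reference)
        self.glyco_set = norm(self.glyco_set)
        self.rbp_compendium = norm(self.rbp_compendium)
        self.compartment_set = norm(self.compartment_set)
        self.gold_standard = norm(self.gold_standard)
        if self.tp_background & self.fp_background:
            raise ValidationError("background TP and FP lists overlap")
        if self.tp_reference is not None and self.fp_reference is not None:
            if self.tp_reference & self.fp_reference:
                raise ValidationError("reference TP and FP lists overlap")

    def tp_fp_for(self, comparison_type: str) -> tuple[set, set]:
        """TP/FP pair configured for a comparison type."""
        if comparison_type == "background":
            return self.tp_background, self.fp_background
        if comparison_type == "reference":
            if self.tp_reference is None or self.fp_reference is None:
                raise ValidationError("reference comparison lacks a TP/FP assignment")
            return self.tp_reference, self.fp_reference
        raise ValidationError(f"no TP/FP assignment for comparison type {comparison_type!r}")


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def specificity(dataset: set, annotation: set) -> float:
    """|dataset ∩ annotation| / |dataset|."""
    if not dataset:
        raise ValueError("empty dataset")
    return len(dataset & annotation) / len(dataset)


def sensitivity(dataset: set, gold_standard: set) -> float:
    """|dataset ∩ gold standard| / |gold standard| (coverage)."""
    if not gold_standard:
        raise ValueError("empty gold standard")
    return len(dataset & gold_standard) / len(gold_standard)


def find_orphans(dataset: set, rbp_compendium: set, compartment_set: set) -> set:
    """Called proteins with neither prior RNA-binding nor compartment annotation."""
    return {g for g in dataset if g not in rbp_compendium and g not in compartment_set}


# ---------------------------------------------------------------------------
# set overlaps
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    names: list[str]
    regions: dict[frozenset, int]       # exact-membership region -> count
    pairwise: dict[tuple, int]          # (a, b) -> |A ∩ B|
    exclusive: dict[str, int]           # name -> count found only in that set

    def total(self) -> int:
        return sum(self.regions.values())


def overlap(sets: Mapping[str, set]) -> OverlapResult:
    """Region decomposition of two or more gene sets.

    Returns counts for every exact-membership region (so the counts are
    inclusion-exclusion consistent by construction), plus the pairwise
    intersection sizes and per-set exclusive counts.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    universe = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for g in universe:
        key = frozenset(n for n in names if g in sets[n])
        regions[key] = regions.get(key, 0) + 1
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for a, b in itertools.combinations(names, 2)
    }
    exclusive = {n: regions.get(frozenset([n]), 0) for n in names}
    return OverlapResult(names, regions, pairwise, exclusive)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  alternative: str = "less",
                  exact_max_n: int = 16) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test of x against y with mid-rank ties.

    Returns ``(W, p)`` where W is the rank sum of the first group.
    ``alternative='less'`` tests whether the first group tends to be lower.
    For combined sample size <= ``exact_max_n`` the p-value is exact, by
    enumeration of all rank assignments (P(W <= w) for 'less'); above that a
    normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)           # mid-ranks for ties
    w = float(ranks[:n1].sum())
    n = n1 + n2
    eps = 1e-9

    if n <= exact_max_n:
        count = 0
        total = comb(n, n1)
        for idx in itertools.combinations(range(n), n1):
            s = ranks[list(idx)].sum()
            if (alternative == "less" and s <= w + eps) or \
               (alternative == "greater" and s >= w - eps):
                count += 1
        return w, count / total

    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0                      # every observation tied
    if alternative == "less":
        z = (w - mu + 0.5) / np.sqrt(var)
        return w, float(sps.norm.cdf(z))
    z = (w - mu - 0.5) / np.sqrt(var)
    return w, float(sps.norm.sf(z))


def abundance_compare(shared: set, exclusive: set,
                      abundance: Mapping[str, float],
                      alternative: str = "less") -> dict:
    """Compare protein abundance between two gene groups by rank sum.

    ``alternative='less'`` tests whether the first group (e.g. proteins found
    only by the in-situ method) tends to have lower abundance than the second
    (e.g. proteins shared with a global profiling dataset).  Genes without an
    abundance value are dropped and counted.
    """
    a = [abundance[g] for g in shared if g in abundance]
    b = [abundance[g] for g in exclusive if g in abundance]
    dropped = (len(shared) - len(a)) + (len(exclusive) - len(b))
    if not a or not b:
        raise ValueError("a group is empty after dropping genes without abundance")
    w, p = rank_sum_test(a, b, alternative=alternative)
    return {"statistic": w, "p_value": p, "n_first": len(a), "n_second": len(b),
            "n_dropped": dropped,
            "median_first": float(np.median(a)), "median_second": float(np.median(b))}


# ---------------------------------------------------------------------------
# RNA-binding domains and crosslink dependence
# ---------------------------------------------------------------------------

def rbd_classify(dataset: set, rbd_map: Mapping[str, set],
                 domain_classes: Mapping[str, str]) -> dict[str, int]:
    """Count proteins with >=1 classical RBD, nonclassical-only, or none.

    A protein carrying both a classical and a nonclassical domain counts in
    the classical bin only; the three bins partition the dataset.  Domains
    absent from ``domain_classes`` are treated as unknown and do not promote
    a protein out of the "none" bin.
    """
    counts = {"classical": 0, "nonclassical_only": 0, "none": 0}
    for g in dataset:
        domains = rbd_map.get(g, set())
        classes = {domain_classes.get(d) for d in domains}
        if "classical" in classes:
            counts["classical"] += 1
        elif "nonclassical" in classes:
            counts["nonclassical_only"] += 1
        else:
            counts["none"] += 1
    return counts


def fa_dependence_compare(ratios: Mapping[str, float],
                          group_rrm: set, group_unknown: set) -> dict:
    """Compare +crosslink/-crosslink enrichment of RRM proteins vs unknown-RBD.

    Tight (high-affinity) binders survive phase separation without chemical
    crosslinking, so RRM-domain proteins are expected to show lower ratios.
    One-sided rank-sum test of the RRM group being lower; medians reported.
    """
    a = [ratios[g] for g in group_rrm if g in ratios]
    b = [ratios[g] for g in group_unknown if g in ratios]
    if not a or not b:
        raise ValueError("a group is empty among ratio-bearing genes")
    w, p = rank_sum_test(a, b, alternative="less")
    return {"statistic": w, "p_value": p,
            "median_rrm": float(np.median(a)), "median_unknown": float(np.median(b)),
            "n_rrm": len(a), "n_unknown": len(b)}
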