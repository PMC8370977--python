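import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rbpmap import (
    AnnotationResource,
    ValidationError,
    abundance_compare,
    fa_dependence_compare,
    find_orphans,
    overlap,
    rank_sum_test,
    rbd_classify,
    sensitivity,
    specificity,
)

from .conftest import midranks


# ---------------------------------------------------------------------------
# specificity / sensitivity / orphans
# ---------------------------------------------------------------------------

def test_specificity_examples():
    dataset = {f"G{i}" for i in range(10)}
    annotation = dataset - {"G0"}
    assert specificity(dataset, annotation) == pytest.approx(0.9)
    assert specificity(dataset, {"ZZZ"}) == 0.0
    with pytest.raises(ValueError):
        specificity(set(), annotation)


def test_sensitivity_examples():
    gold = {"A", "B", "C", "D"}
    assert sensitivity(gold | {"X"}, gold) == 1.0
    assert sensitivity({"A", "C"}, gold) == 0.5
    assert sensitivity({"X"}, gold) == 0.0
    with pytest.raises(ValueError):
        sensitivity({"A"}, set())


def test_metrics_invariant_to_irrelevant_annotation_growth():
    dataset = {"A", "B", "C"}
    annotation = {"A", "B"}
    grown = annotation | {"NOT_IN_DATASET"}
    assert specificity(dataset, annotation) == specificity(dataset, grown)
    gold = {"A", "Z"}
    assert sensitivity(dataset, gold) == sensitivity(dataset | set(), gold)


def test_find_orphans():
    compendium, compartment = {"A"}, {"C"}
    assert find_orphans({"A", "B", "C"}, compendium, compartment) == {"B"}
    assert find_orphans({"A", "C"}, compendium, compartment) == set()


# ---------------------------------------------------------------------------
# overlaps
# ---------------------------------------------------------------------------

def test_overlap_two_sets():
    res = overlap({"x": {"A", "B", "C"}, "y": {"B", "C", "D"}})
    assert res.pairwise[("x", "y")] == 2
    assert res.exclusive == {"x": 1, "y": 1}
    assert res.regions[frozenset({"x", "y"})] == 2
    assert res.total() == 4


def test_overlap_identical_and_disjoint():
    same = overlap({"a": {"P", "Q"}, "b": {"P", "Q"}})
    assert same.exclusive == {"a": 0, "b": 0}
    disjoint = overlap({"a": {"P"}, "b": {"Q"}, "c": {"R"}})
    assert all(v == 0 for v in disjoint.pairwise.values())


def test_overlap_requires_two_sets():
    with pytest.raises(ValueError):
        overlap({"only": {"A"}})


@given(st.lists(st.sets(st.integers(min_value=0, max_value=30)), min_size=2, max_size=4))
@settings(max_examples=50, deadline=None)
def test_overlap_inclusion_exclusion_consistency(raw_sets):
    sets = {f"s{i}": {str(x) for x in s} for i, s in enumerate(raw_sets)}
    res = overlap(sets)
    # region counts reconstruct every set size and pairwise intersection
    for name, s in sets.items():
        assert sum(c for key, c in res.regions.items() if name in key) == len(s)
    for (a, b), n in res.pairwise.items():
        assert sum(c for key, c in res.regions.items() if a in key and b in key) == n
    assert res.total() == len(set().union(*sets.values()))


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _enumeration_oracle(x, y, alternative):
    """Exact null distribution of the first-group rank sum, built with an
    independent mid-rank routine."""
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if alternative == "less" and s <= w_obs + 1e-9:
            hits += 1
        if alternative == "greater" and s >= w_obs - 1e-9:
            hits += 1
    return hits / total


def test_rank_sum_exact_worked_example():
    # minimal possible rank sum: one of C(6,3)=20 assignments
    w, p = rank_sum_test([1, 2, 3], [10, 11, 12], alternative="less")
    assert w == 6.0
    assert p == pytest.approx(1 / 20)


def test_rank_sum_single_elements():
    _, p = rank_sum_test([1], [2], alternative="less")
    assert p == pytest.approx(0.5)
    _, p = rank_sum_test([2], [1], alternative="less")
    assert p == pytest.approx(1.0)


def test_rank_sum_matches_enumeration_oracle_small_groups():
    rng = np.random.default_rng(77)
    for _ in range(40):
        n1, n2 = rng.integers(1, 9, size=2)
        # coarse grid forces ties
        x = rng.integers(0, 6, n1).astype(float)
        y = rng.integers(0, 6, n2).astype(float)
        for alt in ("less", "greater"):
            _, p = rank_sum_test(x, y, alternative=alt)
            assert p == pytest.approx(_enumeration_oracle(x, y, alt))


def test_rank_sum_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(123)
    for _ in range(20):
        n1, n2 = rng.integers(2, 8, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        _, p = rank_sum_test(x, y, alternative="less")
        ref = sps.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
        assert p == pytest.approx(ref)


def test_rank_sum_normal_approximation_reasonable():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 30)
    y = rng.normal(1, 1, 30)
    _, p = rank_sum_test(x, y, alternative="less")
    ref = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
    assert p == pytest.approx(ref, rel=0.05)
    assert p < 0.01


def test_rank_sum_rejects_bad_input():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])
    with pytest.raises(ValueError):
        rank_sum_test([1.0], [2.0], alternative="two-sided")


# ---------------------------------------------------------------------------
# abundance comparison
# ---------------------------------------------------------------------------

def test_abundance_compare_drops_missing_and_reports():
    abundance = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 10.0, "E": 11.0, "F": 12.0}
    res = abundance_compare({"A", "B", "C"}, {"D", "E", "F", "NOVALUE"}, abundance,
                            alternative="less")
    assert res["p_value"] == pytest.approx(1 / 20)
    assert res["n_dropped"] == 1
    assert res["median_first"] == 2.0 and res["median_second"] == 11.0


def test_abundance_compare_empty_group_errors():
    with pytest.raises(ValueError):
        abundance_compare({"A"}, {"B"}, {"A": 1.0})


# ---------------------------------------------------------------------------
# RBD classification and crosslink dependence
# ---------------------------------------------------------------------------

def test_rbd_classical_takes_precedence():
    rbd_map = {"A": {"RRM", "NTF2"}, "B": {"NTF2"}, "C": set()}
    classes = {"RRM": "classical", "NTF2": "nonclassical"}
    counts = rbd_classify({"A", "B", "C", "D"}, rbd_map, classes)
    assert counts == {"classical": 1, "nonclassical_only": 1, "none": 2}
    assert sum(counts.values()) == 4


def test_rbd_empty_map_all_none():
    assert rbd_classify({"A", "B"}, {}, {}) == {"classical": 0,
                                               "nonclassical_only": 0, "none": 2}


def test_fa_dependence_separated_groups_significant():
    rng = np.random.default_rng(6)
    ratios = {f"R{i}": float(v) for i, v in enumerate(rng.uniform(0.8, 1.4, 12))}
    ratios.update({f"U{i}": float(v) for i, v in enumerate(rng.uniform(2.0, 3.5, 12))})
    res = fa_dependence_compare(ratios, {f"R{i}" for i in range(12)},
                                {f"U{i}" for i in range(12)})
    assert res["p_value"] < 0.05
    assert res["median_rrm"] < res["median_unknown"]


def test_fa_dependence_identical_distributions():
    ratios = {"R0": 2.0, "U0": 2.0}
    res = fa_dependence_compare(ratios, {"R0"}, {"U0"})
    assert res["median_rrm"] == res["median_unknown"]


def test_fa_dependence_single_gene_groups():
    res = fa_dependence_compare({"R0": 1.0, "U0": 2.0}, {"R0"}, {"U0"})
    assert res["p_value"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# annotation resource validation
# ---------------------------------------------------------------------------

def test_annotation_resource_rejects_overlapping_lists():
    with pytest.raises(ValidationError, match="overlap"):
        AnnotationResource(tp_background={"A"}, fp_background={"A", "B"})


def test_annotation_resource_normalizes_symbols():
    ann = AnnotationResource(tp_background={" srsf1 "}, fp_background={"tomm20"})
    assert ann.tp_background == {"SRSF1"}
    assert ann.fp_background == {"TOMM20"}
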