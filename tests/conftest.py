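import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

from rbpmap import ExperimentDesign, QuantTable, RatioPair, TMT11_CHANNELS

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def micro_ratios():
    """Five-gene worked example: ratios 5..1, TP={g1,g2,g4}, FP={g3,g5}."""
    ratios = {"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0}
    return ratios, {"g1", "g2", "g4"}, {"g3", "g5"}


@pytest.fixture
def small_table():
    """Three proteins quantified across all 11 TMT channels."""
    rng = np.random.default_rng(42)
    data = {
        "protein_id": ["P1", "P2", "P3"],
        "gene_symbol": ["SRSF1", "HNRNPC", "TOMM20"],
        "n_distinct_peptides": [5, 3, 2],
        "protein_score": [120.0, 55.0, 21.0],
    }
    for ch in TMT11_CHANNELS:
        data[ch] = rng.uniform(50, 500, size=3).round(3)
    return QuantTable(pd.DataFrame(data))


@pytest.fixture
def simple_design():
    return ExperimentDesign(
        channels=[("126C", "background_control"), ("127N", "background_control"),
                  ("128N", "experimental"), ("128C", "experimental")],
        comparisons=[RatioPair("128N", "126C", 1), RatioPair("128C", "127N", 2)],
        min_replicates_k=1,
    )


def brute_force_roc_cutoff(ratios, tp_set, fp_set):
    """Independent oracle: evaluate TPR-FPR at every observed ratio value
    directly from the set definitions; ties to the highest threshold."""
    finite = {g: r for g, r in ratios.items() if np.isfinite(r)}
    n_tp = sum(1 for g in finite if g in tp_set)
    n_fp = sum(1 for g in finite if g in fp_set)
    best = None
    for t in sorted(set(finite.values()), reverse=True):
        tpr = sum(1 for g, v in finite.items() if g in tp_set and v >= t) / n_tp
        fpr = (sum(1 for g, v in finite.items() if g in fp_set and v >= t) / n_fp) if n_fp else 0.0
        j = tpr - fpr
        if best is None or j > best[0] + 1e-12:
            best = (j, t)
    return best[1], best[0]


def midranks(values):
    """Independent mid-rank assignment (average rank of tied values)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
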