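"""Ratio-ranked ROC curves and Youden-style cutoff selection.

The ranking variable is the per-protein TMT enrichment ratio.  Proteins are
ranked in descending order; at each distinct ratio value the cumulative
true-positive and false-positive counts (from curated TP/FP gene lists) give
one point of a receiver operating characteristic curve.  The enrichment
cutoff is placed where TPR - FPR is maximal, i.e. at the Youden optimum of
the empirical curve.  Proteins outside both curated lists do not move the
curve but are subject to the selected cutoff downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np


@dataclass
class ROCResult:
    """ROC curve over distinct descending ratio thresholds plus its cutoff.

    TPR and FPR denominators are the numbers of TP/FP genes actually present
    in the ranked list, not the sizes of the curated lists.
    """

    thresholds: np.ndarray      # distinct ratio values, descending
    tp_cum: np.ndarray          # cumulative TP count at ratio >= threshold
    fp_cum: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    j_stat: np.ndarray          # tpr - fpr
    n_tp_total: int
    n_fp_total: int
    cutoff_index: int | None = None
    cutoff_value: float | None = None


def build_roc(ratios: Mapping[str, float], tp_set: set, fp_set: set) -> ROCResult:
    """Build the descending-rank ROC curve for one comparison.

    Tied ratios are grouped at a single threshold: a protein can never be
    separated from another protein carrying the same ratio.  Raises if the
    curated lists overlap, or if no TP gene is present among the ratios.  An
    absent FP list gives a valid curve with FPR identically zero (warned).
    """
    overlap = tp_set & fp_set
    if overlap:
        raise ValueError("TP and FP lists overlap: " + ", ".join(sorted(overlap)))
    items = [(g, float(r)) for g, r in ratios.items() if np.isfinite(r)]
    if not items:
        raise ValueError("no finite ratios supplied")
    genes = np.array([g for g, _ in items], dtype=object)
    vals = np.array([r for _, r in items], dtype=float)

    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    genes = genes[order]
    is_tp = np.fromiter((g in tp_set for g in genes), dtype=bool, count=len(genes))
    is_fp = np.fromiter((g in fp_set for g in genes), dtype=bool, count=len(genes))

    n_tp = int(is_tp.sum())
    n_fp = int(is_fp.sum())
    if n_tp == 0:
        raise ValueError("no true positives ranked")
    if n_fp == 0:
        warnings.warn("no false positives ranked; FPR is identically zero")

    # group ties: last index of each run of equal values carries the counts
    # for the whole tie group
    distinct_mask = np.empty(len(vals), dtype=bool)
    distinct_mask[:-1] = vals[:-1] != vals[1:]
    distinct_mask[-1] = True
    tp_cum = np.cumsum(is_tp)[distinct_mask]
    fp_cum = np.cumsum(is_fp)[distinct_mask]
    thresholds = vals[distinct_mask]

    tpr = tp_cum / n_tp
    fpr = fp_cum / n_fp if n_fp else np.zeros_like(fp_cum, dtype=float)
    return ROCResult(
        thresholds=thresholds,
        tp_cum=tp_cum.astype(int),
        fp_cum=fp_cum.astype(int),
        tpr=tpr,
        fpr=fpr,
        j_stat=tpr - fpr,
        n_tp_total=n_tp,
        n_fp_total=n_fp,
    )


def select_cutoff(roc: ROCResult) -> float:
    """Threshold with maximal TPR - FPR; ties go to the most stringent one.

    Thresholds are stored in descending order, so the first maximum is the
    highest (most stringent) ratio among equally optimal thresholds,
    minimizing false positives at equal J.  The choice is recorded on the
    ROCResult and returned.
    """
    # tolerance guards against spurious float tie-breaks: true J values are
    # rationals on the TP/FP count grid, far coarser than 1e-9
    jmax = float(np.max(roc.j_stat))
    idx = int(np.argmax(roc.j_stat >= jmax - 1e-9))
    roc.cutoff_index = idx
    roc.cutoff_value = float(roc.thresholds[idx])
    return roc.cutoff_value


def apply_cutoff(ratios: Mapping[str, float], cutoff_value: float) -> set:
    """Genes with ratio >= cutoff (inclusive), curated or not."""
    if not np.isfinite(cutoff_value):
        raise ValueError("cutoff must be finite")
    return {g for g, r in ratios.items() if np.isfinite(r) and r >= cutoff_value}
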