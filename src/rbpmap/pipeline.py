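"""The pairwise-ROC filtering pipeline.

Stage order, per compartment experiment:

1. detection filter (distinct peptides, protein score),
2. per-comparison enrichment ratios,
3. an independent ROC cutoff for every comparison of every replicate,
4. within-replicate intersection of the dual comparisons (background control
   and spatial reference, where the design has both),
5. cross-replicate k-of-n intersection,
6. removal of annotated glycoprotein / secretory-pathway contaminants.

Glycoprotein removal comes last so the stage counts expose how many
contaminants survived ratiometric filtering; phase separation enriches
glycosylated proteins regardless of RNA binding, so they cannot be removed
by enrichment ratios alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import AnnotationResource
from .quant_io import (ExperimentDesign, QuantTable, RatioTable,
                       apply_detection_filter, compute_ratios)
from .roc import ROCResult, apply_cutoff, build_roc, select_cutoff

logger = logging.getLogger(__name__)


@dataclass
class ReplicateCall:
    """Per-replicate ROC results, post-cutoff sets, and their intersection."""

    replicate_id: int
    rocs: dict[str, ROCResult]          # comparison column -> curve with cutoff
    post_cutoff_sets: dict[str, set]
    enriched_set: set                   # intersection across the replicate's comparisons


@dataclass
class FilteredProteome:
    """Final called gene set with per-stage counts and per-gene provenance."""

    final_set: set
    removed_glycoproteins: set
    replicate_calls: list[ReplicateCall]
    stage_counts: dict
    provenance: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def call_replicate(ratio_table: RatioTable, design: ExperimentDesign,
                   annotations: AnnotationResource, replicate_id: int) -> ReplicateCall:
    """ROC-filter every comparison of one replicate and intersect the results.

    Each comparison gets its own ROC cutoff using the TP/FP pair configured
    for its comparison type.  A protein missing a ratio in any comparison of
    the replicate fails that replicate (no partial credit).  Omit-crosslink
    comparisons never participate in filtering.
    """
    pairs = [p for p in design.comparisons_for(replicate_id)
             if p.comparison_type != "crosslink"]
    if not pairs:
        raise ValueError(f"replicate {replicate_id} has no filtering comparisons")
    rocs, sets = {}, {}
    for pair in pairs:
        tp, fp = annotations.tp_fp_for(pair.comparison_type)
        ratios = ratio_table.ratios_for(pair)
        roc = build_roc(ratios, tp, fp)
        cutoff = select_cutoff(roc)
        rocs[pair.column] = roc
        sets[pair.column] = apply_cutoff(ratios, cutoff)
    enriched = set.intersection(*sets.values())
    return ReplicateCall(replicate_id, rocs, sets, enriched)


def intersect_replicates(replicate_sets: list[set], k: int) -> set:
    """Genes supported by at least k of the given replicate sets."""
    if not (1 <= k <= len(replicate_sets)):
        raise ValueError(f"k={k} outside 1..{len(replicate_sets)}")
    support: dict[str, int] = {}
    for s in replicate_sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    return {g for g, n in support.items() if n >= k}


def remove_glycoproteins(genes: set, glyco_set: set) -> tuple[set, set]:
    """Split a gene set into (kept, removed-as-glycoprotein)."""
    removed = genes & glyco_set
    return genes - removed, removed


def filter_from_ratios(ratio_table: RatioTable, design: ExperimentDesign,
                       annotations: AnnotationResource,
                       detected: int | None = None) -> FilteredProteome:
    """Run stages 3-6 of the pipeline on an already-computed ratio table."""
    calls = [call_replicate(ratio_table, design, annotations, rid)
             for rid in design.replicate_ids()]
    rep_sets = [c.enriched_set for c in calls]
    intersected = intersect_replicates(rep_sets, design.min_replicates_k)
    final, removed = remove_glycoproteins(intersected, annotations.glyco_set)

    stage_counts = {
        "detected": detected if detected is not None else len(ratio_table.values),
        "post_roc": {c.replicate_id: len(c.enriched_set) for c in calls},
        "post_intersection": len(intersected),
        "post_glyco": len(final),
    }

    # per-gene provenance over the ranked universe
    genes = sorted(ratio_table.values.index)
    rows = {"gene_symbol": genes}
    support = {g: 0 for g in genes}
    for call in calls:
        ok = pd.Series(True, index=genes)
        for col, s in call.post_cutoff_sets.items():
            rows[f"ratio_{col}"] = ratio_table.values[col].reindex(genes).to_numpy()
            passed = pd.Series([g in s for g in genes], index=genes)
            rows[f"pass_{col}"] = passed.to_numpy()
            ok &= passed
        for g in genes:
            if ok[g]:
                support[g] += 1
    rows["n_supporting_replicates"] = [support[g] for g in genes]
    rows["in_final"] = [g in final for g in genes]
    rows["removed_glycoprotein"] = [g in removed for g in genes]
    provenance = pd.DataFrame(rows).set_index("gene_symbol")

    manifest = {
        "config_hash": design.config_hash(),
        "min_replicates_k": design.min_replicates_k,
        "cutoffs": {c.replicate_id: {col: roc.cutoff_value for col, roc in c.rocs.items()}
                    for c in calls},
    }
    return FilteredProteome(final, removed, calls, stage_counts, provenance, manifest)


def run_pipeline(table: QuantTable, design: ExperimentDesign,
                 annotations: AnnotationResource,
                 *, median_center: bool = False) -> FilteredProteome:
    """Detection filter -> ratios -> per-replicate ROC calls -> k-of-n
    intersection -> glycoprotein removal.  Deterministic given inputs."""
    try:
        detected = apply_detection_filter(table, design.detection_min_peptides,
                                          design.detection_min_score)
    except Exception as exc:                                  # pragma: no cover
        raise RuntimeError(f"detection stage failed: {exc}") from exc
    ratio_table = compute_ratios(detected, design, median_center=median_center)
    return filter_from_ratios(ratio_table, design, annotations,
                              detected=len(detected))
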