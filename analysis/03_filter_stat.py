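#!/usr/bin/env python
"""Run the statistical (moderated-t) filter and compare it with the ROC filter.

For the nucleus simulation: moderated t-test of the three experimental
replicates against the pooled omit-enzyme / omit-H2O2 controls, BH
correction, enrichment call at adj. p < 0.05 and fold change > 1,
glycoprotein removal, and overlap with the pairwise-ROC proteome.  For the
nucleolus simulation: the reference contrast (target - target controls) -
(reference - reference controls) using the whole-nucleus channels as the
spatial reference.
"""

import argparse
import json
import warnings
from pathlib import Path

from rbpmap import (
    read_gene_list,
    read_quant_table,
    apply_detection_filter,
    reference_contrast,
    test_enrichment,
    write_gene_list,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--roc", type=Path, default=ROOT / "results" / "roc_filter")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "stat_filter")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    summary = {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # nucleus: experimental replicates vs pooled negative controls
        nuc = args.sim / "nucleus"
        table = apply_detection_filter(read_quant_table(nuc / "quant.tsv"))
        glyco = read_gene_list(nuc / "glycoproteins.txt")
        res = test_enrichment(table, ["128N", "128C", "129N"], ["126C", "127N"],
                              moderation=True)
        res.table.to_csv(args.out / "nucleus_stats.tsv", sep="\t")
        final = res.enriched_set() - glyco
        write_gene_list(final, args.out / "nucleus_final_proteome.txt")
        roc_final = read_gene_list(args.roc / "nucleus" / "final_proteome.txt")
        summary["nucleus"] = {
            "n_tested": int(res.table["tested"].sum()),
            "n_enriched": len(res.enriched_set()),
            "final_after_glyco": len(final),
            "overlap_with_roc_proteome": len(final & roc_final),
            "roc_proteome_size": len(roc_final),
            "prior_df": res.d0 if res.d0 is None else float(res.d0),
        }
        print(f"nucleus stat filter: {summary['nucleus']['n_enriched']} enriched "
              f"-> {len(final)} after glycoprotein removal; "
              f"{summary['nucleus']['overlap_with_roc_proteome']} shared with the "
              f"ROC proteome of {len(roc_final)}")

        # nucleolus: contrast against the whole-nucleus spatial reference
        nol = args.sim / "nucleolus"
        table = apply_detection_filter(read_quant_table(nol / "quant.tsv"))
        glyco = read_gene_list(nol / "glycoproteins.txt")
        res = reference_contrast(
            table,
            target_channels=["130C", "131N", "131C"],
            target_ctrl_channels=["126C", "129C"],
            ref_channels=["128N", "128C", "129N"],
            ref_ctrl_channels=["126C", "129C"],
        )
        res.table.to_csv(args.out / "nucleolus_stats.tsv", sep="\t")
        final = res.enriched_set() - glyco
        write_gene_list(final, args.out / "nucleolus_final_proteome.txt")
        roc_final = read_gene_list(args.roc / "nucleolus" / "final_proteome.txt")
        summary["nucleolus"] = {
            "n_tested": int(res.table["tested"].sum()),
            "n_enriched": len(res.enriched_set()),
            "final_after_glyco": len(final),
            "overlap_with_roc_proteome": len(final & roc_final),
            "roc_proteome_size": len(roc_final),
        }
        print(f"nucleolus reference contrast: {summary['nucleolus']['n_enriched']} "
              f"enriched -> {len(final)} after glycoprotein removal; "
              f"{summary['nucleolus']['overlap_with_roc_proteome']} shared with the "
              f"ROC proteome of {len(roc_final)}")

    (args.out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
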