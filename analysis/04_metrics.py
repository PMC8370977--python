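#!/usr/bin/env python
"""Evaluate the called proteomes: specificity, sensitivity, orphans, overlap,
abundance comparison, RBD classes and crosslink dependence.

Reads the simulated annotation resources and the final proteomes from the
earlier steps and writes one JSON report per preset plus a cross-preset
overlap table.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from rbpmap import (
    abundance_compare,
    crosslink_dependence_ratios,
    fa_dependence_compare,
    find_orphans,
    overlap,
    rbd_classify,
    read_gene_list,
    read_quant_table,
    ExperimentDesign,
    sensitivity,
    specificity,
)

ROOT = Path(__file__).resolve().parents[1]


def evaluate(sim_dir: Path, final: set) -> dict:
    compendium = read_gene_list(sim_dir / "rbp_compendium.txt")
    compartment = read_gene_list(sim_dir / "compartment.txt")
    gold = read_gene_list(sim_dir / "gold_standard.txt")
    truth = pd.read_csv(sim_dir / "truth.tsv", sep="\t", index_col="gene_symbol")
    abundance = {}   # baseline intensity as an abundance proxy
    table = read_quant_table(sim_dir / "quant.tsv")
    first_channel = table.channels[0]
    abundance = dict(zip(table.gene_symbols, table.data[first_channel]))

    report = {
        "final_size": len(final),
        "rbp_specificity_pct": round(100 * specificity(final, compendium), 1),
        "compartment_specificity_pct": round(100 * specificity(final, compartment), 1),
        "gold_standard_sensitivity_pct": round(100 * sensitivity(final, gold), 1),
        "orphans": sorted(find_orphans(final, compendium, compartment)),
    }

    # abundance of proteins shared with the annotation compendium vs the
    # final-proteome-only ("novel") calls
    shared = final & compendium
    novel = final - compendium
    if shared and novel:
        cmp = abundance_compare(novel, shared, abundance, alternative="less")
        report["novel_vs_shared_abundance_p"] = round(cmp["p_value"], 4)
    return report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--roc", type=Path, default=ROOT / "results" / "roc_filter")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "metrics")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    finals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sim_dir in sorted(p for p in args.sim.iterdir() if p.is_dir()):
            name = sim_dir.name
            final = read_gene_list(args.roc / name / "final_proteome.txt")
            finals[name] = final
            report = evaluate(sim_dir, final)

            # RBD subclassification and crosslink dependence (nucleus-style
            # designs carry an omit-crosslink channel and an RBD annotation)
            truth = pd.read_csv(sim_dir / "truth.tsv", sep="\t", index_col="gene_symbol")
            if name == "nucleus":
                table = read_quant_table(sim_dir / "quant.tsv")
                design = ExperimentDesign.read_json(sim_dir / "design.json")
                rbd_df = pd.read_csv(sim_dir / "rbd_map.tsv", sep="\t")
                rbd_map = {r.gene_symbol: set(r.domains.split(","))
                           for r in rbd_df.itertuples()}
                domain_classes = json.loads((sim_dir / "domain_classes.json").read_text())
                report["rbd_counts"] = rbd_classify(final, rbd_map, domain_classes)
                ratios = crosslink_dependence_ratios(table, design)
                rrm = {g for g, doms in rbd_map.items() if "RRM" in doms} & final
                unknown = {g for g in final if g not in rbd_map}
                if rrm and unknown:
                    fa = fa_dependence_compare(ratios, rrm, unknown)
                    report["fa_dependence"] = {
                        "median_rrm": round(fa["median_rrm"], 3),
                        "median_unknown": round(fa["median_unknown"], 3),
                        "p_value": round(fa["p_value"], 5),
                    }
            (args.out / f"{name}.json").write_text(json.dumps(report, indent=2) + "\n")
            print(f"{name}: |final|={report['final_size']} "
                  f"RBP spec {report['rbp_specificity_pct']}%, compartment spec "
                  f"{report['compartment_specificity_pct']}%, gold sensitivity "
                  f"{report['gold_standard_sensitivity_pct']}%, "
                  f"{len(report['orphans'])} orphans")

        # basal vs +PUR overlap, the translation-stress comparison
        if "omm_basal" in finals and "omm_pur" in finals:
            ov = overlap({"basal": finals["omm_basal"], "pur": finals["omm_pur"]})
            ov_report = {
                "shared": ov.pairwise[("basal", "pur")],
                "basal_only": ov.exclusive["basal"],
                "pur_only": ov.exclusive["pur"],
            }
            (args.out / "omm_overlap.json").write_text(json.dumps(ov_report, indent=2) + "\n")
            print(f"OMM basal vs +PUR: {ov_report['shared']} shared, "
                  f"{ov_report['basal_only']} basal-only, {ov_report['pur_only']} PUR-only")


if __name__ == "__main__":
    main()
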