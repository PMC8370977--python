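#!/usr/bin/env python
"""Generate the synthetic multiplex experiments used by the downstream steps.

Writes, for each preset (nucleus, nucleolus, omm_basal, omm_pur): the
protein quantification TSV, the experiment-design JSON, every curated gene
list, and the ground-truth class table, under results/sim/<preset>/.
"""

import argparse
from pathlib import Path

from rbpmap import generate, scenario_presets, write_gene_list, write_quant_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "sim")
    args = ap.parse_args()

    for name, cfg in scenario_presets(seed=args.seed).items():
        out = args.out / name
        out.mkdir(parents=True, exist_ok=True)
        table, ann, truth = generate(cfg)
        write_quant_table(table, out / "quant.tsv")
        cfg.design.write_json(out / "design.json")
        write_gene_list(ann.tp_background, out / "tp_background.txt")
        write_gene_list(ann.fp_background, out / "fp_background.txt")
        if ann.tp_reference is not None:
            write_gene_list(ann.tp_reference, out / "tp_reference.txt")
            write_gene_list(ann.fp_reference, out / "fp_reference.txt")
        write_gene_list(ann.glyco_set, out / "glycoproteins.txt")
        write_gene_list(ann.rbp_compendium, out / "rbp_compendium.txt")
        write_gene_list(ann.compartment_set, out / "compartment.txt")
        write_gene_list(ann.gold_standard, out / "gold_standard.txt")
        truth.table.to_csv(out / "truth.tsv", sep="\t")
        with open(out / "rbd_map.tsv", "w") as fh:
            fh.write("gene_symbol\tdomains\n")
            for g in sorted(ann.rbd_map):
                fh.write(f"{g}\t{','.join(sorted(ann.rbd_map[g]))}\n")
        (out / "domain_classes.json").write_text(
            __import__("json").dumps(ann.domain_classes, indent=2) + "\n")
        n_rbp = len(truth.compartment_rbps)
        print(f"{name}: {len(table)} proteins ({n_rbp} planted compartment RBPs, "
              f"{len(ann.glyco_set)} glycoproteins) -> {out}")


if __name__ == "__main__":
    main()
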