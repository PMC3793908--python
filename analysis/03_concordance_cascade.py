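"""Cross-species concordance: reciprocal orthology overlap of the two DE
screens, concordant gene calling, proliferation-set exclusion and the
two-fold filter, ending in the final concordant gene list. Writes the
cascade summary and gene list under results/concordance/."""

import json
from pathlib import Path

from dmbscreen import concordance, io
from dmbscreen._de_io import read_de_result

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    human_de = read_de_result(ROOT / "de" / "human_de_full.tsv", "human")
    mouse_de = read_de_result(ROOT / "de" / "mouse_de_full.tsv", "mouse")
    orthology = io.read_orthology(ROOT / "data" / "orthology.tsv")
    exclusion = io.read_gmt(ROOT / "data" / "exclusion_sets.gmt")

    report, pairs = concordance.reciprocal_overlap(
        human_de, mouse_de, orthology, cross_fdrs=(0.05, 0.01)
    )
    genes = concordance.concordant_genes(pairs)
    kept, removed, per_set = concordance.apply_exclusion(genes, exclusion)
    final, removed_fold = concordance.fold_filter(kept, threshold=2.0)
    cascade = concordance.summarize_cascade(
        human_de, mouse_de, report, genes, kept, removed, final, removed_fold
    )

    out = ROOT / "concordance"
    io.write_tsv(cascade, out / "cascade_summary.tsv")
    io.write_tsv(concordance.genes_to_table(final), out / "final_gene_list.tsv")

    truth = json.loads((ROOT / "data" / "truth.json").read_text())
    planted = set(truth["concordant_genes"])
    recoverable = planted - set(truth["proliferation_genes"])
    final_set = {g.gene_symbol for g in final}
    print(cascade.to_string(index=False))
    print(
        f"\nfinal list: {len(final)} genes "
        f"({sum(g.direction > 0 for g in final)} up, "
        f"{sum(g.direction < 0 for g in final)} down); "
        f"recall of recoverable planted genes "
        f"{len(final_set & recoverable)}/{len(recoverable)}, "
        f"false positives {len(final_set - planted)}"
    )


if __name__ == "__main__":
    main()
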