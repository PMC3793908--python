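"""Generate the synthetic study inputs: two-species tumor/normal expression
matrices with planted concordant genes, the orthology map, the exclusion
gene set, and the planted truth, all written under results/data/."""

import json
from pathlib import Path

from dmbscreen import io
from dmbscreen.concordance import GeneSet
from dmbscreen.simulate import SimConfig, simulate_two_species

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20230901


def main() -> None:
    cfg = SimConfig(seed=SEED)
    human, mouse, orthology, truth = simulate_two_species(cfg)

    io.write_expression(human, OUT / "human_expression.tsv", OUT / "human_samples.tsv")
    io.write_expression(mouse, OUT / "mouse_expression.tsv", OUT / "mouse_samples.tsv")
    io.write_orthology(orthology, OUT / "orthology.tsv")
    io.write_gmt(
        [GeneSet("proliferation", "activated/proliferating B-cell signature",
                 truth.proliferation_genes)],
        OUT / "exclusion_sets.gmt",
    )
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "concordant_genes": truth.concordant_genes,
                "survival_genes": truth.survival_genes,
                "proliferation_genes": sorted(truth.proliferation_genes),
                "hub_node": truth.hub_node,
            },
            indent=2,
        )
    )
    print(f"simulated {len(human.probeset_ids)} human and "
          f"{len(mouse.probeset_ids)} mouse probesets "
          f"({cfg.n_tumor} tumors vs {cfg.n_normal} normals per species)")
    print(f"planted {len(truth.concordant_genes)} concordant genes, "
          f"{len(truth.survival_genes)} survival-linked, hub={truth.hub_node}")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
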