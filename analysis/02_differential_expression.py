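"""Per-species two-group differential expression: ANOVA p, step-up FDR
within the p<0.01 list, signed fold changes. Reads the simulated matrices
from 01, writes full DE tables under results/de/."""

from pathlib import Path

from dmbscreen import io
from dmbscreen._de_io import write_de_result
from dmbscreen.diffexpr import run_de

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    orthology = io.read_orthology(ROOT / "data" / "orthology.tsv")
    ann = {
        "human": dict(zip(orthology.triples["human_probeset"],
                          orthology.triples["gene_symbol"])),
        "mouse": dict(zip(orthology.triples["mouse_probeset"],
                          orthology.triples["gene_symbol"])),
    }
    for species in ("human", "mouse"):
        matrix = io.read_expression(
            ROOT / "data" / f"{species}_expression.tsv",
            ROOT / "data" / f"{species}_samples.tsv",
        )
        res = run_de(matrix, ann[species], p_cut=0.01, q_cut=0.01)
        write_de_result(res, ROOT / "de" / f"{species}_de_full.tsv")
        n_p = int((res.full["p_value"] < 0.01).sum())
        print(
            f"{species}: {n_p}/{len(res.full)} probesets at ANOVA p<0.01 "
            f"({100 * n_p / len(res.full):.2f}%), "
            f"{len(res.significant)} surviving FDR<0.01 "
            f"({100 * len(res.significant) / max(n_p, 1):.1f}% of the p<0.01 list)"
        )


if __name__ == "__main__":
    main()
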