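"""Reciprocal cross-species overlap and the filtering cascade."""

import numpy as np
import pandas as pd
import pytest

from dmbscreen.concordance import (
    GeneSet,
    OrthologyMap,
    apply_exclusion,
    concordant_genes,
    fold_filter,
    reciprocal_overlap,
)
from dmbscreen.diffexpr import DEResult, run_de
from dmbscreen.simulate import SimConfig, simulate_two_species


def de_result(species, rows, p_cut=0.01, q_cut=0.01):
    """Hand-built DEResult from (probeset, gene, p, q, fold) tuples."""
    full = pd.DataFrame(
        rows, columns=["probeset_id", "gene_symbol", "p_value", "q_value", "fold_change"]
    )
    full["direction"] = np.where(full["fold_change"] >= 0, 1, -1)
    sig = full[(full["p_value"] < p_cut) & (full["q_value"] < q_cut)].reset_index(
        drop=True
    )
    return DEResult(species=species, full=full, significant=sig, p_cut=p_cut, q_cut=q_cut)


def one_to_one_map(genes):
    return OrthologyMap(
        pd.DataFrame(
            [(f"h_{g}", g, f"m_{g}") for g in genes],
            columns=["human_probeset", "gene_symbol", "mouse_probeset"],
        )
    )


@pytest.fixture
def toy_de():
    human = de_result(
        "human",
        [
            (f"h_{g}", g, 0.001, 0.001, fc)
            for g, fc in [("A", 3.0), ("B", 2.5), ("C", -4.0)]
        ]
        + [("h_D", "D", 0.5, 0.9, 1.1)],
    )
    mouse = de_result(
        "mouse",
        [
            (f"m_{g}", g, 0.001, 0.001, fc)
            for g, fc in [("B", 2.2), ("C", -2.8), ("D", 5.0)]
        ]
        + [("m_A", "A", 0.6, 0.95, 1.05)],
    )
    return human, mouse, one_to_one_map(["A", "B", "C", "D"])


class TestReciprocalOverlap:
    def test_hand_set_intersection(self, toy_de):
        human, mouse, omap = toy_de
        report, pairs = reciprocal_overlap(human, mouse, omap)
        # human sig {A,B,C}; mouse sig {B,C,D} -> human-in-mouse = {B,C}
        assert report.human_in_mouse[0.01] == (2, pytest.approx(100 * 2 / 3, abs=0.01))
        assert report.mouse_in_human[0.01][0] == 2
        assert set(pairs["gene_symbol"]) == {"B", "C"}

    def test_empty_map_gives_zero_overlaps(self, toy_de):
        human, mouse, _ = toy_de
        empty = OrthologyMap(
            pd.DataFrame(columns=["human_probeset", "gene_symbol", "mouse_probeset"])
        )
        report, pairs = reciprocal_overlap(human, mouse, empty)
        assert all(c == (0, 0.0) for c in report.human_in_mouse.values())
        assert len(pairs) == 0

    def test_overlap_monotone_in_cross_fdr(self, toy_de):
        human, mouse, omap = toy_de
        report, _ = reciprocal_overlap(human, mouse, omap, cross_fdrs=(0.05, 0.01))
        assert report.human_in_mouse[0.01][0] <= report.human_in_mouse[0.05][0]
        assert report.mouse_in_human[0.01][0] <= report.mouse_in_human[0.05][0]

    def test_reciprocal_symmetry_under_species_swap(self, toy_de):
        human, mouse, omap = toy_de
        fwd, _ = reciprocal_overlap(human, mouse, omap)
        swapped = OrthologyMap(
            omap.triples.rename(
                columns={
                    "human_probeset": "mouse_probeset",
                    "mouse_probeset": "human_probeset",
                }
            )
        )
        rev, _ = reciprocal_overlap(mouse, human, swapped)
        assert rev.human_in_mouse[0.01][0] == fwd.mouse_in_human[0.01][0]
        assert rev.mouse_in_human[0.01][0] == fwd.human_in_mouse[0.01][0]

    def test_planted_truth_contained_in_overlap(self, planted_sim):
        cfg, human, mouse, omap, truth = planted_sim
        ann_h = dict(
            zip(omap.triples["human_probeset"], omap.triples["gene_symbol"])
        )
        ann_m = dict(
            zip(omap.triples["mouse_probeset"], omap.triples["gene_symbol"])
        )
        hde = run_de(human, ann_h)
        mde = run_de(mouse, ann_m)
        _, pairs = reciprocal_overlap(hde, mde, omap)
        overlap_genes = set(pairs["gene_symbol"])
        planted_passing = set(truth.concordant_genes) & set(
            hde.significant["gene_symbol"]
        ) & set(mde.significant["gene_symbol"])
        assert planted_passing <= overlap_genes


def pair_row(gene, fch, fcm, ph=0.001, pm=0.001, hps=None, mps=None):
    return {
        "gene_key": gene.upper(),
        "gene_symbol": gene,
        "human_probeset_id": hps or f"h_{gene}",
        "p_value_human": ph,
        "q_value_human": 0.001,
        "fold_change_human": fch,
        "direction_human": 1 if fch >= 0 else -1,
        "mouse_probeset_id": mps or f"m_{gene}",
        "p_value_mouse": pm,
        "q_value_mouse": 0.001,
        "fold_change_mouse": fcm,
        "direction_mouse": 1 if fcm >= 0 else -1,
    }


class TestConcordantGenes:
    def test_matching_direction_is_concordant(self):
        genes = concordant_genes(pd.DataFrame([pair_row("A", 3.0, 2.5)]))
        assert len(genes) == 1
        assert genes[0].direction == 1

    def test_discordant_pair_excluded_by_default_kept_with_flag(self):
        pairs = pd.DataFrame([pair_row("DOCK11", -2.39, 2.34)])
        assert concordant_genes(pairs) == []
        kept = concordant_genes(pairs, keep_discordant=True)
        assert len(kept) == 1
        assert kept[0].direction == -1  # human side calls the direction

    def test_multiple_probesets_grouped_into_one_gene(self):
        pairs = pd.DataFrame(
            [
                pair_row("A", 3.0, 4.0, hps="h_A1"),
                pair_row("A", 2.0, 4.0, hps="h_A2"),
            ]
        )
        genes = concordant_genes(pairs)
        assert len(genes) == 1
        assert len(genes[0].human_records) == 2
        assert genes[0].max_abs_fold_human == pytest.approx(3.0)

    def test_direction_from_pair_with_largest_min_fold(self):
        # down pair has min(|FC|)=2.5; up pair min=2.0 -> gene called down
        pairs = pd.DataFrame(
            [
                pair_row("G", -2.5, -3.0, hps="h_G1", mps="m_G1"),
                pair_row("G", 2.0, 6.0, hps="h_G2", mps="m_G2"),
            ]
        )
        genes = concordant_genes(pairs)
        assert genes[0].direction == -1

    def test_case_insensitive_symbol_matching(self):
        rows = [pair_row("Foxm1", 3.0, 2.5)]
        rows[0]["gene_key"] = "FOXM1"
        genes = concordant_genes(pd.DataFrame(rows))
        assert len(genes) == 1


class TestFilters:
    def _gene(self, symbol, fh, fm, direction=None):
        pairs = pd.DataFrame([pair_row(symbol, fh, fm)])
        return concordant_genes(pairs, keep_discordant=True)[0]

    def test_exclusion_partitions_input(self):
        genes = [self._gene(s, 3.0, 3.0) for s in "ABC"]
        kept, removed, counts = apply_exclusion(
            genes, [GeneSet("prolif", "", {"B", "D"})]
        )
        assert [g.gene_symbol for g in kept] == ["A", "C"]
        assert [g.gene_symbol for g in removed] == ["B"]
        assert counts == {"prolif": 1}

    def test_empty_exclusion_keeps_everything(self):
        genes = [self._gene("A", 3.0, 3.0)]
        kept, removed, _ = apply_exclusion(genes, [])
        assert kept == genes and removed == []

    def test_fold_filter_requires_both_species(self):
        weak = self._gene("W", 1.9, 3.0)
        strong = self._gene("S", -2.14, -2.08)  # published boundary case
        kept, removed = fold_filter([weak, strong], threshold=2.0)
        assert [g.gene_symbol for g in kept] == ["S"]
        assert [g.gene_symbol for g in removed] == ["W"]

    def test_fold_filter_rejects_threshold_below_one(self):
        with pytest.raises(ValueError):
            fold_filter([], threshold=0.5)

    def test_exclusion_expected_removals_near_planted_fraction(self):
        """Binomial expectation: ~13% of concordant genes planted into the
        exclusion set should be removed."""
        removed_fracs = []
        for seed in range(10):
            cfg = SimConfig(seed=300 + seed)
            _, _, _, truth = simulate_two_species(cfg)
            conc = set(truth.concordant_genes)
            excl = truth.proliferation_genes
            removed_fracs.append(len(conc & excl) / len(conc))
        assert np.mean(removed_fracs) == pytest.approx(0.13, abs=0.02)
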