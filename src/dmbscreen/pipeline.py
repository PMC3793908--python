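"""End-to-end driver chaining every stage of the screen.

differential expression (both species) → reciprocal orthology overlap →
concordant gene calling → exclusion and fold filters → recurrence voting →
survival screen with exact proportion CI → network expansion to a hub
candidate. The driver either simulates its inputs (with planted truth, the
default) or loads them from the paths in the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import concordance, diffexpr, io, network, recurrence, simulate, survival
from .concordance import GeneSet
from .io import PipelineConfig
from .simulate import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the screen produces, stage by stage."""

    human_de: diffexpr.DEResult
    mouse_de: diffexpr.DEResult
    overlap: concordance.OverlapReport
    concordant: list
    kept_after_exclusion: list
    removed_by_exclusion: list
    final_genes: list
    removed_by_fold: list
    cascade: pd.DataFrame
    votes: pd.DataFrame
    survival_table: pd.DataFrame
    survival_significant: set
    proportion_ci: tuple
    expansion: network.ExpansionResult | None
    hub_ranking: pd.DataFrame | None
    truth: simulate.SimTruth | None = None

    @property
    def final_symbols(self) -> list[str]:
        return sorted(g.gene_symbol for g in self.final_genes)


def run_pipeline(
    config: PipelineConfig | None = None,
    sim_config: SimConfig | None = None,
) -> PipelineResult:
    """Run the whole screen on simulated inputs with planted truth.

    *config* holds every analysis threshold; *sim_config* the generator's
    study conditions. Stage errors propagate with the stage named.
    """
    config = config or PipelineConfig()
    sim_config = sim_config or SimConfig(seed=config.rng_seed)

    try:
        human, mouse, orthology, truth = simulate.simulate_two_species(sim_config)
    except Exception as exc:
        raise RuntimeError(f"simulation stage failed: {exc}") from exc

    annotations = dict(
        zip(orthology.triples["human_probeset"], orthology.triples["gene_symbol"])
    )
    annotations_mouse = dict(
        zip(orthology.triples["mouse_probeset"], orthology.triples["gene_symbol"])
    )
    try:
        human_de = diffexpr.run_de(
            human, annotations, p_cut=config.p_anova, q_cut=config.fdr_primary
        )
        mouse_de = diffexpr.run_de(
            mouse, annotations_mouse, p_cut=config.p_anova, q_cut=config.fdr_primary
        )
    except Exception as exc:
        raise RuntimeError(f"differential-expression stage failed: {exc}") from exc

    try:
        overlap, pairs = concordance.reciprocal_overlap(
            human_de,
            mouse_de,
            orthology,
            cross_fdrs=(config.cross_fdr_loose, config.cross_fdr_strict),
        )
        conc = concordance.concordant_genes(
            pairs, keep_discordant=config.keep_discordant
        )
        overlap.n_concordant_annotated_genes = len(conc)
        overlap.n_up = sum(1 for g in conc if g.direction > 0)
        overlap.n_down = sum(1 for g in conc if g.direction < 0)
    except Exception as exc:
        raise RuntimeError(f"concordance stage failed: {exc}") from exc

    exclusion = [
        GeneSet(
            "proliferation",
            "activated/proliferating normal B-cell signature",
            truth.proliferation_genes,
        )
    ]
    kept, removed, _ = concordance.apply_exclusion(conc, exclusion)
    final, removed_fold = concordance.fold_filter(kept, config.fold_threshold)
    cascade = concordance.summarize_cascade(
        human_de, mouse_de, overlap, conc, kept, removed, final, removed_fold
    )

    final_table = pd.DataFrame(
        {
            "gene_symbol": [g.gene_symbol for g in final],
            "direction": [g.direction for g in final],
        }
    )
    try:
        studies = simulate.simulate_study_summaries(
            truth, config.n_studies, config.detect_prob, sim_config
        )
        votes = (
            recurrence.recurrence_vote(
                final_table,
                studies,
                p_max=config.recurrence_p,
                fold_min=config.recurrence_fold,
            )
            if len(final_table)
            else pd.DataFrame(columns=["gene_symbol", "votes", "tier"])
        )
    except Exception as exc:
        raise RuntimeError(f"recurrence stage failed: {exc}") from exc

    try:
        surv_table = pd.DataFrame()
        surv_sig: set = set()
        ci = (0.0, 1.0, False)
        if len(final_table):
            cohort = simulate.simulate_survival(
                list(final_table["gene_symbol"]),
                truth,
                config.n_subjects,
                sim_config,
            )
            surv_table, surv_sig = survival.screen_genes(
                cohort, alpha=config.alpha_survival
            )
            ci = survival.proportion_ci_exact(
                len(surv_sig),
                len(final_table),
                level=config.ci_level,
                chance=config.chance_level,
            )
    except Exception as exc:
        raise RuntimeError(f"survival stage failed: {exc}") from exc

    expansion = None
    ranking = None
    try:
        if len(votes) and (votes["votes"] >= 2).any():
            seeds = sorted(
                votes.sort_values(["votes", "gene_symbol"], ascending=[False, True])
                .head(6)["gene_symbol"]
            )
            net = simulate.simulate_network(truth, seeds, sim_config)
            expansion = network.expand_network(
                net,
                seeds,
                target_n=config.network_target_n,
                min_confidence=config.network_min_confidence,
            )
            ranking = network.hub_candidates(expansion)
    except Exception as exc:
        raise RuntimeError(f"network stage failed: {exc}") from exc

    return PipelineResult(
        human_de=human_de,
        mouse_de=mouse_de,
        overlap=overlap,
        concordant=conc,
        kept_after_exclusion=kept,
        removed_by_exclusion=removed,
        final_genes=final,
        removed_by_fold=removed_fold,
        cascade=cascade,
        votes=votes,
        survival_table=surv_table,
        survival_significant=surv_sig,
        proportion_ci=ci,
        expansion=expansion,
        hub_ranking=ranking,
        truth=truth,
    )


def write_results(result: PipelineResult, outdir) -> None:
    """Dump every stage's tables as TSV under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(result.human_de.significant, outdir / "human_de_significant.tsv")
    io.write_tsv(result.mouse_de.significant, outdir / "mouse_de_significant.tsv")
    io.write_tsv(result.cascade, outdir / "cascade_summary.tsv")
    io.write_tsv(
        concordance.genes_to_table(result.final_genes), outdir / "final_genes.tsv"
    )
    if len(result.votes):
        io.write_tsv(result.votes, outdir / "recurrence_votes.tsv")
    if len(result.survival_table):
        io.write_tsv(result.survival_table, outdir / "survival_screen.tsv")
    if result.hub_ranking is not None:
        io.write_tsv(result.hub_ranking, outdir / "hub_ranking.tsv")
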