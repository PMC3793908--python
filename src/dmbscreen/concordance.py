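"""Cross-species concordance of differential expression and the filtering
cascade that narrows matched human/mouse DE hits to a final concordant gene
list.

The reciprocal-overlap step asks, for each significant probeset in one
species, whether ANY orthologous probeset in the other species is also
significant at a chosen FDR; matched pairs are then grouped by gene symbol,
genes whose every pair disagrees in direction are dropped (strict
concordance; a permissive flag retains them), genes found in exclusion sets
(e.g. normal B-cell proliferation signatures) are removed, and a final
fold-change filter keeps genes reaching the threshold magnitude in both
species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import DEResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologyMap:
    """Triples linking a human probeset and a mouse probeset via a shared
    gene symbol; many-to-many relations are permitted."""

    triples: pd.DataFrame  # columns: human_probeset, gene_symbol, mouse_probeset

    COLUMNS = ("human_probeset", "gene_symbol", "mouse_probeset")

    def __post_init__(self) -> None:
        df = self.triples
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"orthology map missing columns: {sorted(missing)}")
        if df.duplicated(list(self.COLUMNS)).any():
            raise ValueError("orthology map contains duplicate triples")
        if (df["gene_symbol"].astype(str).str.strip() == "").any():
            raise ValueError("orthology map contains empty gene symbols")

    def __len__(self) -> int:
        return len(self.triples)


@dataclass
class GeneSet:
    """Named flat gene-symbol set (GMT-style)."""

    name: str
    description: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        self.members = {str(m) for m in self.members}

    def members_upper(self) -> set[str]:
        return {m.upper() for m in self.members}


@dataclass
class OverlapReport:
    """Reciprocal overlap counts between the two species' significant sets.

    ``human_in_mouse[fdr]`` counts primary-significant human probesets with
    at least one orthologous mouse probeset at mouse q < fdr, as
    (count, percent of the human significant set); ``mouse_in_human`` is the
    symmetric count over mouse significant probesets whose gene has an
    annotated human counterpart.
    """

    n_human_sig: int
    n_mouse_sig: int
    n_mouse_sig_with_human_homolog: int
    human_in_mouse: dict[float, tuple[int, float]] = field(default_factory=dict)
    mouse_in_human: dict[float, tuple[int, float]] = field(default_factory=dict)
    n_concordant_annotated_genes: int = 0
    n_up: int = 0
    n_down: int = 0


@dataclass(eq=False)
class ConcordantGene:
    """A gene significant in both species with a shared direction."""

    gene_symbol: str
    human_records: pd.DataFrame
    mouse_records: pd.DataFrame
    direction: int
    max_abs_fold_human: float
    max_abs_fold_mouse: float


def _pct(count: int, denom: int) -> float:
    return 100.0 * count / denom if denom else 0.0


def _norm(sym: pd.Series) -> pd.Series:
    """Case-insensitive symbol key (mouse Foxm1 matches human FOXM1)."""
    return sym.astype(str).str.upper()


def reciprocal_overlap(
    human_de: DEResult,
    mouse_de: DEResult,
    orthology: OrthologyMap,
    cross_fdrs: tuple[float, ...] = (0.05, 0.01),
) -> tuple[OverlapReport, pd.DataFrame]:
    """Reciprocal human-in-mouse / mouse-in-human overlap of DE probesets.

    Returns the overlap report plus the matched probeset pairs at the
    strictest requested FDR: one row per (human probeset, mouse probeset)
    orthology pair with both members significant, carrying both records'
    p, q, fold change and direction.
    """
    if len(orthology) == 0:
        logger.warning("empty orthology map: all overlap counts are zero")
        report = OverlapReport(
            n_human_sig=len(human_de.significant),
            n_mouse_sig=len(mouse_de.significant),
            n_mouse_sig_with_human_homolog=0,
            human_in_mouse={f: (0, 0.0) for f in cross_fdrs},
            mouse_in_human={f: (0, 0.0) for f in cross_fdrs},
        )
        return report, pd.DataFrame()

    triples = orthology.triples.copy()
    triples["gene_key"] = _norm(triples["gene_symbol"])

    hsig = human_de.significant
    msig = mouse_de.significant
    hfull = human_de.full
    mfull = mouse_de.full

    report = OverlapReport(
        n_human_sig=len(hsig),
        n_mouse_sig=len(msig),
        n_mouse_sig_with_human_homolog=int(
            msig["probeset_id"].isin(triples["mouse_probeset"]).sum()
        ),
    )

    # human significant probesets joined to their orthologous mouse records;
    # the orthology map's symbol wins over per-species annotations
    h_pairs = hsig.drop(columns="gene_symbol", errors="ignore").merge(
        triples, left_on="probeset_id", right_on="human_probeset", how="inner"
    ).merge(
        mfull.drop(columns="gene_symbol", errors="ignore").add_suffix("_mouse"),
        left_on="mouse_probeset",
        right_on="probeset_id_mouse",
        how="inner",
    )
    m_pairs = msig.drop(columns="gene_symbol", errors="ignore").merge(
        triples, left_on="probeset_id", right_on="mouse_probeset", how="inner"
    ).merge(
        hfull.drop(columns="gene_symbol", errors="ignore").add_suffix("_human"),
        left_on="human_probeset",
        right_on="probeset_id_human",
        how="inner",
    )

    for fdr in cross_fdrs:
        h_hit = h_pairs.loc[h_pairs["q_value_mouse"] < fdr, "probeset_id"].nunique()
        m_hit = m_pairs.loc[m_pairs["q_value_human"] < fdr, "probeset_id"].nunique()
        report.human_in_mouse[fdr] = (h_hit, _pct(h_hit, report.n_human_sig))
        report.mouse_in_human[fdr] = (
            m_hit,
            _pct(m_hit, report.n_mouse_sig_with_human_homolog),
        )

    strict = min(cross_fdrs)
    pairs = h_pairs[h_pairs["q_value_mouse"] < strict].copy()
    pairs = pairs.rename(
        columns={
            "probeset_id": "human_probeset_id",
            "p_value": "p_value_human",
            "q_value": "q_value_human",
            "fold_change": "fold_change_human",
            "direction": "direction_human",
            "probeset_id_mouse": "mouse_probeset_id",
        }
    )
    keep = [
        "gene_key",
        "gene_symbol",
        "human_probeset_id",
        "p_value_human",
        "q_value_human",
        "fold_change_human",
        "direction_human",
        "mouse_probeset_id",
        "p_value_mouse",
        "q_value_mouse",
        "fold_change_mouse",
        "direction_mouse",
    ]
    pairs = pairs[keep].drop_duplicates(
        ["human_probeset_id", "mouse_probeset_id"]
    ).reset_index(drop=True)
    return report, pairs


def concordant_genes(
    pairs: pd.DataFrame, keep_discordant: bool = False
) -> list[ConcordantGene]:
    """Group matched probeset pairs by gene and call per-gene direction.

    A gene is concordant when at least one human–mouse pair agrees in
    direction; the gene direction comes from the pair maximizing
    min(|FC_human|, |FC_mouse|), ties broken toward the smaller human
    p-value, then lexicographic probeset id. Genes whose every pair is
    discordant are excluded and logged unless *keep_discordant* is set, in
    which case the human direction of the best pair is used.
    """
    out: list[ConcordantGene] = []
    if pairs is None or len(pairs) == 0:
        return out
    for _, grp in pairs.groupby("gene_key", sort=True):
        symbol = grp["gene_symbol"].iloc[0]
        agree = grp[grp["direction_human"] == grp["direction_mouse"]]
        chosen = agree if len(agree) else grp
        if not len(agree):
            if not keep_discordant:
                logger.info("gene %s: all pairs discordant; excluded", symbol)
                continue
            logger.info("gene %s: all pairs discordant; kept (permissive)", symbol)
        ranked = chosen.assign(
            _minfc=chosen[["fold_change_human", "fold_change_mouse"]]
            .abs()
            .min(axis=1)
        ).sort_values(
            ["_minfc", "p_value_human", "human_probeset_id"],
            ascending=[False, True, True],
        )
        best = ranked.iloc[0]
        direction = int(best["direction_human"])
        # retain records consistent with the called direction
        consistent = grp[grp["direction_human"] == direction] if len(agree) else grp
        hrec = (
            consistent[
                [
                    "human_probeset_id",
                    "p_value_human",
                    "q_value_human",
                    "fold_change_human",
                    "direction_human",
                ]
            ]
            .drop_duplicates("human_probeset_id")
            .reset_index(drop=True)
        )
        mrows = grp[grp["direction_mouse"] == direction] if len(agree) else grp
        mrec = (
            mrows[
                [
                    "mouse_probeset_id",
                    "p_value_mouse",
                    "q_value_mouse",
                    "fold_change_mouse",
                    "direction_mouse",
                ]
            ]
            .drop_duplicates("mouse_probeset_id")
            .reset_index(drop=True)
        )
        out.append(
            ConcordantGene(
                gene_symbol=symbol,
                human_records=hrec,
                mouse_records=mrec,
                direction=direction,
                max_abs_fold_human=float(hrec["fold_change_human"].abs().max()),
                max_abs_fold_mouse=float(mrec["fold_change_mouse"].abs().max()),
            )
        )
    return out


def apply_exclusion(
    genes: list[ConcordantGene], exclusion_sets: list[GeneSet]
) -> tuple[list[ConcordantGene], list[ConcordantGene], dict[str, int]]:
    """Remove genes appearing in the union of exclusion sets.

    Returns (kept, removed, per-set membership counts). kept ∪ removed
    partitions the input exactly.
    """
    union: set[str] = set()
    for gs in exclusion_sets:
        union |= gs.members_upper()
    kept, removed = [], []
    per_set = {gs.name: 0 for gs in exclusion_sets}
    for g in genes:
        key = g.gene_symbol.upper()
        if key in union:
            removed.append(g)
            for gs in exclusion_sets:
                if key in gs.members_upper():
                    per_set[gs.name] += 1
        else:
            kept.append(g)
    logger.info(
        "exclusion filter removed %d of %d genes", len(removed), len(genes)
    )
    return kept, removed, per_set


def fold_filter(
    genes: list[ConcordantGene], threshold: float = 2.0
) -> tuple[list[ConcordantGene], list[ConcordantGene]]:
    """Keep genes whose best fold magnitude reaches *threshold* in BOTH
    species; the removed list can be partitioned by direction downstream."""
    if threshold < 1:
        raise ValueError("fold threshold must be >= 1")
    kept, removed = [], []
    for g in genes:
        if g.max_abs_fold_human >= threshold and g.max_abs_fold_mouse >= threshold:
            kept.append(g)
        else:
            removed.append(g)
    return kept, removed


def genes_to_table(genes: list[ConcordantGene]) -> pd.DataFrame:
    """Flatten a concordant gene list to one row per human probeset,
    mirroring the packaged fixture layout."""
    rows = []
    for g in genes:
        mouse = g.mouse_records.iloc[0]
        for i, (_, h) in enumerate(g.human_records.iterrows()):
            rows.append(
                {
                    "gene_symbol": g.gene_symbol,
                    "human_probeset": h["human_probeset_id"],
                    "human_p": h["p_value_human"],
                    "human_fold": h["fold_change_human"],
                    "mouse_probeset": mouse["mouse_probeset_id"] if i == 0 else "",
                    "mouse_p": mouse["p_value_mouse"] if i == 0 else float("nan"),
                    "mouse_fold": mouse["fold_change_mouse"] if i == 0 else float("nan"),
                    "direction": g.direction,
                }
            )
    return pd.DataFrame(rows)


def summarize_cascade(
    human_de: DEResult,
    mouse_de: DEResult,
    report: OverlapReport,
    concordant: list[ConcordantGene],
    kept_after_exclusion: list[ConcordantGene],
    removed_by_exclusion: list[ConcordantGene],
    final: list[ConcordantGene],
    removed_by_fold: list[ConcordantGene],
) -> pd.DataFrame:
    """Counts and percentages at every arrow of the filtering cascade."""
    n_conc = len(concordant)
    up = sum(1 for g in concordant if g.direction > 0)
    down = n_conc - up
    rows = [
        ("human_probesets_tested", len(human_de.full), ""),
        ("human_probesets_significant", len(human_de.significant),
         f"{_pct(len(human_de.significant), len(human_de.full)):.2f}%"),
        ("mouse_probesets_tested", len(mouse_de.full), ""),
        ("mouse_probesets_significant", len(mouse_de.significant),
         f"{_pct(len(mouse_de.significant), len(mouse_de.full)):.2f}%"),
        ("mouse_sig_with_human_homolog", report.n_mouse_sig_with_human_homolog,
         f"{_pct(report.n_mouse_sig_with_human_homolog, report.n_mouse_sig):.1f}%"),
    ]
    for fdr, (cnt, pct) in sorted(report.human_in_mouse.items(), reverse=True):
        rows.append((f"human_in_mouse_fdr_{fdr:g}", cnt, f"{pct:.1f}%"))
    for fdr, (cnt, pct) in sorted(report.mouse_in_human.items(), reverse=True):
        rows.append((f"mouse_in_human_fdr_{fdr:g}", cnt, f"{pct:.1f}%"))
    rows += [
        ("concordant_genes", n_conc, ""),
        ("concordant_up", up, f"{_pct(up, n_conc):.1f}%"),
        ("concordant_down", down, f"{_pct(down, n_conc):.1f}%"),
        ("removed_by_exclusion", len(removed_by_exclusion),
         f"{_pct(len(removed_by_exclusion), n_conc):.0f}%"),
        ("kept_after_exclusion", len(kept_after_exclusion), ""),
        ("removed_by_fold_filter", len(removed_by_fold), ""),
        ("removed_by_fold_up",
         sum(1 for g in removed_by_fold if g.direction > 0), ""),
        ("removed_by_fold_down",
         sum(1 for g in removed_by_fold if g.direction < 0), ""),
        ("final_gene_list", len(final), ""),
        ("final_up", sum(1 for g in final if g.direction > 0), ""),
        ("final_down", sum(1 for g in final if g.direction < 0), ""),
    ]
    return pd.DataFrame(rows, columns=["stage", "count", "percent"])
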