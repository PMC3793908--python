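"""Recurrence of candidate genes across independent expression studies and
target-set enrichment within a GO-restricted universe.

Vote counting asks, for each candidate gene, in how many independent study
summaries it reappears with at least a two-fold change at p ≤ 0.01 (and,
by default, in the same direction); tiers at ≥2, ≥3 and ≥4 votes flag the
recurrently confirmed genes. Enrichment tests whether a target gene set
(e.g. transcription-factor targets) is overrepresented among the candidates
via Fisher's exact test on the 2×2 membership table, optionally after
restricting every set to one GO category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .concordance import GeneSet

logger = logging.getLogger(__name__)

VOTE_TIERS = (2, 3, 4)


@dataclass
class StudySummary:
    """Precomputed differential-expression summary of one external study."""

    study_id: str
    category: str
    records: pd.DataFrame  # columns: gene_symbol, fold_change, p_value

    def __post_init__(self) -> None:
        req = {"gene_symbol", "fold_change", "p_value"}
        if not req <= set(self.records.columns):
            raise ValueError(f"study {self.study_id}: missing columns {req - set(self.records.columns)}")
        p = self.records["p_value"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError(f"study {self.study_id}: p-values outside [0,1]")
        if self.records.duplicated("gene_symbol").any():
            # multiple probesets of one gene collapse to the smallest p
            self.records = (
                self.records.sort_values("p_value")
                .drop_duplicates("gene_symbol")
                .reset_index(drop=True)
            )


@dataclass
class EnrichmentResult:
    """2×2 Fisher/hypergeometric enrichment of targets among candidates."""

    a: int  # candidate ∩ target
    b: int  # candidate \ target
    c: int  # target \ candidate
    d: int  # neither
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float
    universe: str = ""

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def recurrence_vote(
    dmb_genes: pd.DataFrame,
    studies: list[StudySummary],
    p_max: float = 0.01,
    fold_min: float = 2.0,
    require_direction: bool = True,
) -> pd.DataFrame:
    """Count, per candidate gene, the studies confirming it.

    *dmb_genes* needs columns ``gene_symbol`` and ``direction`` (±1). A study
    confirms a gene when it contains a record with |fold| ≥ *fold_min*,
    p ≤ *p_max* and, if *require_direction*, a fold change of matching sign.
    Votes are counted across ALL studies; per-category counts are reported
    alongside. Returns one row per candidate with ``votes``, ``tier``
    (highest of ≥2/≥3/≥4 reached, 0 otherwise) and one ``votes_<category>``
    column per study category.
    """
    if not studies:
        raise ValueError("at least one study summary is required")
    categories = sorted({s.category for s in studies})
    rows = []
    for _, cand in dmb_genes.iterrows():
        sym = str(cand["gene_symbol"]).upper()
        direction = int(cand["direction"])
        votes = 0
        per_cat = {c: 0 for c in categories}
        for s in studies:
            rec = s.records[s.records["gene_symbol"].astype(str).str.upper() == sym]
            if rec.empty:
                continue
            r = rec.iloc[0]
            ok = abs(r["fold_change"]) >= fold_min and r["p_value"] <= p_max
            if require_direction:
                ok = ok and (r["fold_change"] > 0) == (direction > 0)
            if ok:
                votes += 1
                per_cat[s.category] += 1
        tier = max((t for t in VOTE_TIERS if votes >= t), default=0)
        row = {
            "gene_symbol": cand["gene_symbol"],
            "direction": direction,
            "votes": votes,
            "tier": tier,
        }
        row.update({f"votes_{c}": per_cat[c] for c in categories})
        rows.append(row)
    out = pd.DataFrame(rows)
    logger.info(
        "recurrence: %d/%d genes in >=2 studies",
        int((out["votes"] >= 2).sum()),
        len(out),
    )
    return out


def fisher_enrichment(
    candidates: GeneSet,
    targets: GeneSet,
    universe: GeneSet,
    restrict_to: GeneSet | None = None,
) -> EnrichmentResult:
    """Overrepresentation of *targets* among *candidates* over *universe*.

    All three sets are intersected with *restrict_to* first when given.
    Reports the one-sided (enrichment) hypergeometric p, the two-sided
    Fisher p (sum of tables no more probable than the observed one), and
    the odds ratio, Haldane-corrected (+0.5 per cell) when a zero cell
    would make it undefined.
    """
    uni = universe.members_upper()
    if restrict_to is not None:
        uni &= restrict_to.members_upper()
    if not uni:
        raise ValueError("restricted universe is empty")
    cand = candidates.members_upper() & uni
    targ = targets.members_upper() & uni
    a = len(cand & targ)
    b = len(cand - targ)
    c = len(targ - cand)
    d = len(uni) - a - b - c
    # P(X >= a) with X ~ Hypergeom(N=|uni|, K=|targ|, n=|cand|)
    p_one = float(stats.hypergeom.sf(a - 1, len(uni), a + c, a + b))
    _, p_two = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    restrict_name = restrict_to.name if restrict_to is not None else "none"
    return EnrichmentResult(
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(odds),
        p_one_sided=min(p_one, 1.0),
        p_two_sided=float(min(p_two, 1.0)),
        universe=f"{universe.name} restricted to {restrict_name} (N={len(uni)})",
    )
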