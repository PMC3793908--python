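"""Two-group differential expression on log2 expression matrices.

Each probeset is tested with a one-way two-group ANOVA (equivalent to the
pooled-variance t-test, F = t² with 1 and n−2 degrees of freedom), p-values
are adjusted with the Benjamini–Hochberg step-up procedure, and effect sizes
are reported as signed linear-scale fold changes (±2^|Δlog2|, so a value in
(−1, 1) is impossible by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Log2 probeset × sample intensities with group labels.

    Parameters
    ----------
    probeset_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_probesets, n_samples)
        Log2-scale intensities; must be finite.
    species : str
        ``"human"`` or ``"mouse"``.
    groups : dict
        Maps each sample id to ``"tumor"`` or ``"normal"``.
    """

    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    species: str
    groups: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probeset_ids)} probesets x {len(self.sample_ids)} samples"
            )
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise ValueError("duplicate probeset ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = {g for g in self.groups.values()} - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in (TUMOR, NORMAL):
            if len(self.group_columns(grp)) < 2:
                raise ValueError(f"group {grp!r} has fewer than 2 samples")

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of samples belonging to *group*."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group],
            dtype=int,
        )


def two_group_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-probeset one-way ANOVA of tumor versus normal samples.

    With two groups the F statistic equals the squared pooled-variance
    t statistic; the p-value is the upper tail of F(1, n−2). Probesets with
    zero within-group variance but unequal group means get p = 0 with a
    logged warning (an edge case only synthetic data can produce).

    Returns a DataFrame with columns ``probeset_id``, ``F``, ``p_value``,
    ``mean_tumor``, ``mean_normal``.
    """
    it = matrix.group_columns(TUMOR)
    inorm = matrix.group_columns(NORMAL)
    x_t = matrix.values[:, it]
    x_n = matrix.values[:, inorm]
    n1, n2 = x_t.shape[1], x_n.shape[1]
    n = n1 + n2

    m_t = x_t.mean(axis=1)
    m_n = x_n.mean(axis=1)
    grand = (n1 * m_t + n2 * m_n) / n
    ss_between = n1 * (m_t - grand) ** 2 + n2 * (m_n - grand) ** 2
    ss_within = ((x_t - m_t[:, None]) ** 2).sum(axis=1) + (
        (x_n - m_n[:, None]) ** 2
    ).sum(axis=1)
    ms_within = ss_within / (n - 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / ms_within
    # zero within-group variance: no difference -> F=0; difference -> p=0
    degenerate = ms_within == 0
    f[degenerate & (ss_between == 0)] = 0.0
    sep = degenerate & (ss_between > 0)
    if sep.any():
        logger.warning(
            "%d probesets have zero within-group variance with unequal means; "
            "reporting p=0",
            int(sep.sum()),
        )
        f[sep] = np.inf
    p = stats.f.sf(f, 1, n - 2)
    p[sep] = 0.0
    return pd.DataFrame(
        {
            "probeset_id": matrix.probeset_ids,
            "F": f,
            "p_value": p,
            "mean_tumor": m_t,
            "mean_normal": m_n,
        }
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j ≥ i} (p_(j) · m / j) over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def signed_fold_change(mean_tumor_log2: float, mean_normal_log2: float) -> float:
    """Signed linear fold change from log2 group means.

    Returns 2^Δ for Δ = tumor − normal ≥ 0 and −2^(−Δ) otherwise, so
    up-regulation is +r and down-regulation −r with r ≥ 1.
    """
    delta = np.asarray(mean_tumor_log2, dtype=float) - np.asarray(
        mean_normal_log2, dtype=float
    )
    if not np.all(np.isfinite(delta)):
        raise ValueError("group means must be finite")
    fc = np.where(delta >= 0, np.exp2(delta), -np.exp2(-delta))
    return float(fc) if fc.ndim == 0 else fc


@dataclass
class DEResult:
    """Full and significant per-probeset DE tables for one species."""

    species: str
    full: pd.DataFrame
    significant: pd.DataFrame
    p_cut: float
    q_cut: float
    fdr_scope: str = "within_p_cut"


DE_COLUMNS = [
    "probeset_id",
    "gene_symbol",
    "p_value",
    "q_value",
    "fold_change",
    "direction",
]


def run_de(
    matrix: ExpressionMatrix,
    annotations: dict[str, str] | None = None,
    p_cut: float = 0.01,
    q_cut: float = 0.01,
    fdr_scope: str = "within_p_cut",
) -> DEResult:
    """Differential-expression screen for one species.

    The screen is two-stage: probesets are first filtered at ANOVA
    p < *p_cut*, then the step-up FDR is applied and q < *q_cut* required.
    With the default ``fdr_scope="within_p_cut"`` the BH adjustment runs on
    the p-filtered subset (the workflow microarray suites apply when an FDR
    column is added to an ANOVA-filtered list; probesets outside the subset
    get q = 1). ``fdr_scope="global"`` adjusts over all probesets instead.
    The full table is retained so downstream cross-species lookups can use
    other FDR thresholds. *annotations* maps probeset ids to gene symbols
    (missing probesets get an empty symbol).
    """
    if fdr_scope not in ("within_p_cut", "global"):
        raise ValueError("fdr_scope must be 'within_p_cut' or 'global'")
    table = two_group_test(matrix)
    p = table["p_value"].to_numpy()
    if fdr_scope == "global":
        table["q_value"] = bh_fdr(p)
    else:
        q = np.ones_like(p)
        mask = p < p_cut
        if mask.any():
            q[mask] = bh_fdr(p[mask])
        table["q_value"] = q
    fc = np.asarray(
        signed_fold_change(
            table["mean_tumor"].to_numpy(), table["mean_normal"].to_numpy()
        )
    )
    table["fold_change"] = fc
    table["direction"] = np.where(fc >= 0, 1, -1).astype(int)
    ann = annotations or {}
    table["gene_symbol"] = [ann.get(p, "") for p in table["probeset_id"]]
    full = table[DE_COLUMNS + ["F", "mean_tumor", "mean_normal"]].copy()
    sig = full[(full["p_value"] < p_cut) & (full["q_value"] < q_cut)].reset_index(
        drop=True
    )
    logger.info(
        "%s: %d of %d probesets significant at p<%g and q<%g",
        matrix.species,
        len(sig),
        len(full),
        p_cut,
        q_cut,
    )
    return DEResult(
        species=matrix.species,
        full=full,
        significant=sig,
        p_cut=p_cut,
        q_cut=q_cut,
        fdr_scope=fdr_scope,
    )
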