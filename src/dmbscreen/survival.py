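"""Per-gene univariate proportional-hazards screening by treatment arm.

Each gene's expression level is fitted, one arm at a time, in a univariate
Cox proportional-hazards model: the log hazard ratio per one-unit increase
in expression maximizes the partial likelihood (Breslow handling of tied
event times by default, Efron optionally), solved by Newton–Raphson from
beta = 0. Significance is judged by the 95% Wald interval excluding a
hazard ratio of 1, which is exactly the two-sided Wald p < 0.05. The
fraction of screened genes reaching significance is then compared with the
5% expected by chance through an exact (Clopper–Pearson) binomial
confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ARMS = ("CHOP", "R-CHOP")


class NoEventsError(ValueError):
    """Raised when an arm contains fewer than two observed events."""


class DegenerateCovariateError(ValueError):
    """Raised when the covariate is constant across subjects."""


@dataclass
class SurvivalCohort:
    """Subjects with follow-up time, event indicator, treatment arm and
    per-gene expression levels.

    *data* holds columns ``subject_id``, ``time``, ``event``, ``arm`` plus
    one numeric column per gene.
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "time", "event", "arm")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort missing columns: {sorted(missing)}")
        if (self.data["time"] < 0).any():
            raise ValueError("negative follow-up times")
        if not set(self.data["event"].unique()) <= {0, 1}:
            raise ValueError("event must be 0 (censored) or 1 (death)")
        bad = set(self.data["arm"].unique()) - set(ARMS)
        if bad:
            raise ValueError(f"unknown treatment arms: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def arm_frame(self, arm: str) -> pd.DataFrame:
        return self.data[self.data["arm"] == arm]


@dataclass
class CoxFit:
    """Univariate proportional-hazards fit for one gene in one arm."""

    gene_symbol: str
    arm: str
    beta: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    converged: bool = True

    @property
    def significant(self) -> bool:
        """CI excludes 1 ⇔ Wald p < 0.05 (same z statistic)."""
        return self.converged and self.p_value < 0.05


def _cox_derivatives(
    beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray, ties: str
) -> tuple[float, float, float]:
    """Log partial likelihood, score and information for a single covariate.

    Arrays must be sorted by descending time so the risk set at each event
    time is a prefix.
    """
    eta = beta * x
    w = np.exp(eta)
    # running sums over the risk set (prefix in descending-time order)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x)
    cwx2 = np.cumsum(w * x * x)

    loglik = score = info = 0.0
    n = len(times)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] == times[i]:
            j += 1
        # risk set = indices 0..j (all with time >= times[i])
        d_idx = [k for k in range(i, j + 1) if events[k] == 1]
        d = len(d_idx)
        if d:
            s0 = cw[j]
            s1 = cwx[j]
            s2 = cwx2[j]
            sx = float(x[d_idx].sum())
            seta = float(eta[d_idx].sum())
            if ties == "breslow":
                loglik += seta - d * math.log(s0)
                score += sx - d * s1 / s0
                info += d * (s2 / s0 - (s1 / s0) ** 2)
            else:  # efron
                dw = w[d_idx].sum()
                dwx = (w[d_idx] * x[d_idx]).sum()
                dwx2 = (w[d_idx] * x[d_idx] * x[d_idx]).sum()
                loglik += seta
                for r in range(d):
                    f = r / d
                    z0 = s0 - f * dw
                    z1 = s1 - f * dwx
                    z2 = s2 - f * dwx2
                    loglik -= math.log(z0)
                    score -= z1 / z0
                    info += z2 / z0 - (z1 / z0) ** 2
                score += sx
        i = j + 1
    return loglik, score, info


def fit_cox_univariate(
    cohort: SurvivalCohort,
    gene: str,
    arm: str,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 25,
) -> CoxFit:
    """Fit one gene's expression against survival within one treatment arm.

    Newton–Raphson from beta = 0 until |score| < *tol*; the standard error
    comes from the observed information at the optimum and the CI is
    exp(beta ± 1.96·se). Monotone partial likelihoods (risk perfectly
    ordered by expression) do not converge; they return a flagged fit with
    infinite CI rather than raising, so a many-gene screen can proceed.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    frame = cohort.arm_frame(arm)
    if gene not in frame.columns:
        raise KeyError(f"gene {gene!r} not in cohort")
    times = frame["time"].to_numpy(dtype=float)
    events = frame["event"].to_numpy(dtype=int)
    x = frame[gene].to_numpy(dtype=float)
    n_events = int(events.sum())
    if n_events < 2:
        raise NoEventsError(f"{gene}/{arm}: fewer than 2 events")
    if np.ptp(x) == 0:
        raise DegenerateCovariateError(f"{gene}/{arm}: constant expression")

    order = np.argsort(-times, kind="mergesort")
    times, events, x = times[order], events[order], x[order]
    # center for numerical stability; beta is translation-invariant
    x = x - x.mean()

    beta = 0.0
    converged = False
    info = np.nan
    for _ in range(max_iter):
        _, score, info = _cox_derivatives(beta, times, events, x, ties)
        if info <= 0 or not np.isfinite(score):
            break
        step = score / info
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(score) < tol or abs(beta) > 50:
            converged = abs(score) < tol
            break
    # a monotone partial likelihood has score -> 0 as |beta| grows: a tiny
    # score at an absurd beta (HR beyond e^15 per covariate unit) or a
    # collapsing information is divergence, not convergence
    if abs(beta) > 15 or (np.isfinite(info) and info > 0 and 1 / math.sqrt(info) > 50):
        converged = False
    if not converged or not np.isfinite(info) or info <= 0:
        logger.warning("%s/%s: monotone likelihood or non-convergence", gene, arm)
        return CoxFit(
            gene_symbol=gene,
            arm=arm,
            beta=float(beta),
            se=math.inf,
            hazard_ratio=float(np.exp(np.clip(beta, -50, 50))),
            ci_low=0.0,
            ci_high=math.inf,
            p_value=1.0,
            n_events=n_events,
            converged=False,
        )
    se = 1.0 / math.sqrt(info)
    z975 = stats.norm.ppf(0.975)
    z = beta / se
    return CoxFit(
        gene_symbol=gene,
        arm=arm,
        beta=float(beta),
        se=float(se),
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z975 * se)),
        ci_high=float(np.exp(beta + z975 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_events=n_events,
        converged=True,
    )


def screen_genes(
    cohort: SurvivalCohort,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    ties: str = "breslow",
) -> tuple[pd.DataFrame, set[str]]:
    """Fit every gene separately in each arm and collect the significant set.

    The two arms are modeled independently (treatment regimens differ too
    much to pool). A gene is significant if any of its fits in any arm has
    Wald p < *alpha*; the arm-difference z-test
    z = (β₁−β₂)/√(se₁²+se₂²) is reported per gene. Failed or flagged fits
    are logged and excluded from the significance count.
    """
    genes = genes if genes is not None else cohort.genes
    if not genes:
        raise ValueError("no genes to screen")
    rows = []
    significant: set[str] = set()
    for gene in genes:
        fits: dict[str, CoxFit] = {}
        for arm in ARMS:
            try:
                fits[arm] = fit_cox_univariate(cohort, gene, arm, ties=ties)
            except (NoEventsError, DegenerateCovariateError) as exc:
                logger.warning("skipping %s/%s: %s", gene, arm, exc)
        if not fits:
            continue
        ok = {a: f for a, f in fits.items() if f.converged}
        if len(ok) == 2:
            f1, f2 = ok[ARMS[0]], ok[ARMS[1]]
            z = (f1.beta - f2.beta) / math.sqrt(f1.se**2 + f2.se**2)
            p_diff = float(2 * stats.norm.sf(abs(z)))
        else:
            p_diff = float("nan")
        sig_here = any(f.p_value < alpha for f in ok.values())
        if sig_here:
            significant.add(gene)
        for arm, f in fits.items():
            rows.append(
                {
                    "gene_symbol": gene,
                    "arm": arm,
                    "beta": f.beta,
                    "se": f.se,
                    "hazard_ratio": f.hazard_ratio,
                    "ci_low": f.ci_low,
                    "ci_high": f.ci_high,
                    "p_value": f.p_value,
                    "n_events": f.n_events,
                    "converged": f.converged,
                    "significant": f.converged and f.p_value < alpha,
                    "p_arm_diff": p_diff,
                }
            )
    table = pd.DataFrame(rows)
    logger.info("survival screen: %d/%d genes significant", len(significant), len(genes))
    return table, significant


def direction_consistency(hazard_ratio: float, de_direction: int) -> bool:
    """An up-regulated gene is consistent when higher expression raises the
    death rate (HR > 1); a down-regulated gene when HR < 1. HR = 1 exactly
    is inconsistent by convention (strict inequalities)."""
    if de_direction not in (1, -1):
        raise ValueError("de_direction must be +1 or -1")
    if hazard_ratio == 1.0:
        logger.info("HR exactly 1: boundary case, called inconsistent")
        return False
    return hazard_ratio > 1.0 if de_direction == 1 else hazard_ratio < 1.0


def proportion_ci_exact(
    k: int, n: int, level: float = 0.95, chance: float = 0.05
) -> tuple[float, float, bool]:
    """Clopper–Pearson exact CI for a binomial proportion k/n.

    Returns (lower, upper, excludes_chance). The bounds come from beta
    quantiles; lower = 0 when k = 0 and upper = 1 when k = n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = (1 - level) / 2
    lower = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    excludes = chance < lower or chance > upper
    return lower, upper, excludes
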