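"""Synthetic two-species expression data, survival cohorts, external-study
summaries and interaction networks with known planted truth.

The generator emulates the structure of a cross-species tumor/normal
microarray comparison: log2-scale expression (as produced by RMA
normalization) with per-gene baselines, Gaussian within-group noise,
differentially expressed genes whose tumor mean shifts by a fixed log2
effect, and a planted subset of genes that are shifted in the SAME
direction in both species (the concordant truth the downstream cascade
should recover). Survival follows an exponential model whose hazard scales
with expression of survival-linked genes; the interaction network plants a
single high-confidence hub wired to the seed genes above a low-confidence
background.

Each operation draws from its own RNG stream, seeded from ``config.seed``
plus a fixed per-operation offset, so the stages are independently
reproducible and byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import OrthologyMap
from .diffexpr import ExpressionMatrix
from .recurrence import StudySummary
from .survival import SurvivalCohort

# per-operation RNG stream offsets
_STREAM_EXPRESSION = 0
_STREAM_SURVIVAL = 1
_STREAM_NETWORK = 2
_STREAM_STUDIES = 3


class ConfigurationError(ValueError):
    """Invalid simulation configuration; names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic data generator.

    Defaults mirror the structure of the emulated study: small tumor and
    normal groups per species, a modest fraction of truly DE genes, 60
    planted cross-species concordant genes, and a log2 effect large enough
    for an adequately powered two-group comparison at these sample sizes.
    """

    n_genes_per_species: int = 2000
    n_tumor: int = 7
    n_normal: int = 3
    frac_de: float = 0.10
    n_concordant: int = 60
    effect_log2: float = 1.5
    sigma: float = 0.5
    frac_proliferation_overlap: float = 0.13
    survival_beta: float = 0.5
    baseline_hazard: float = 0.1
    censor_time: float = 10.0
    hub_seed_edges: int = 5
    background_edge_prob: float = 0.01
    extra_probesets_per_gene: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes_per_species", "n_tumor", "n_normal", "n_concordant"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("frac_de", "frac_proliferation_overlap", "background_edge_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.frac_de > 0 and self.n_concordant > self.frac_de * self.n_genes_per_species:
            raise ConfigurationError(
                "n_concordant exceeds frac_de * n_genes_per_species"
            )
        if self.hub_seed_edges < 0:
            raise ConfigurationError("hub_seed_edges must be >= 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censor_time < 0:
            raise ConfigurationError("censor_time must be >= 0")
        if self.extra_probesets_per_gene < 0:
            raise ConfigurationError("extra_probesets_per_gene must be >= 0")


@dataclass
class SimTruth:
    """Ground truth planted by the generator."""

    de_genes_human: set[str]
    de_genes_mouse: set[str]
    concordant_genes: dict[str, int]  # gene -> direction (+1/-1)
    proliferation_genes: set[str]
    survival_genes: dict[str, float]  # gene -> true log-hazard coefficient
    hub_node: str = "HUB1"

    def __post_init__(self) -> None:
        conc = set(self.concordant_genes)
        if not conc <= (self.de_genes_human & self.de_genes_mouse):
            raise ValueError("concordant genes must be DE in both species")
        if not set(self.concordant_genes.values()) <= {1, -1}:
            raise ValueError("directions must be +1 or -1")


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def _rng(config: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(config.seed * 10 + offset)


def simulate_two_species(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologyMap, SimTruth]:
    """Generate matched human and mouse tumor/normal expression matrices.

    Each gene gets one probeset per species (plus
    ``extra_probesets_per_gene`` additional human probesets when requested,
    exercising many-to-many orthology). Log2 values are
    Normal(baseline_g, sigma); DE genes shift the tumor-group mean by
    effect_log2 × direction; the planted concordant genes share their
    direction across species while the remaining DE genes are drawn
    independently per species.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPRESSION)
    n = config.n_genes_per_species
    genes = _gene_names(n)

    n_de = int(round(config.frac_de * n))
    n_de = max(n_de, config.n_concordant if config.frac_de > 0 else 0)
    if config.frac_de == 0:
        n_de = 0

    if n_de:
        de_pool = rng.choice(n, size=n_de, replace=False)
        concordant_idx = de_pool[: config.n_concordant]
        # species-specific DE genes: split the remainder
        rest = de_pool[config.n_concordant :]
        half = len(rest) // 2
        human_only = rest[:half]
        mouse_only = rest[half:]
    else:
        concordant_idx = np.array([], dtype=int)
        human_only = np.array([], dtype=int)
        mouse_only = np.array([], dtype=int)

    conc_dir = rng.choice([1, -1], size=len(concordant_idx))
    human_dir = {int(i): int(d) for i, d in zip(concordant_idx, conc_dir)}
    mouse_dir = dict(human_dir)
    for i in human_only:
        human_dir[int(i)] = int(rng.choice([1, -1]))
    for i in mouse_only:
        mouse_dir[int(i)] = int(rng.choice([1, -1]))

    baselines = rng.uniform(6.0, 10.0, size=n)

    def build(species: str, dir_map: dict[int, int], prefix: str) -> ExpressionMatrix:
        n_probesets_per_gene = 1 + (
            config.extra_probesets_per_gene if species == "human" else 0
        )
        probesets, rows = [], []
        n_s = config.n_tumor + config.n_normal
        samples = [f"{prefix}T{i}" for i in range(config.n_tumor)] + [
            f"{prefix}N{i}" for i in range(config.n_normal)
        ]
        groups = {s: ("tumor" if s.startswith(f"{prefix}T") else "normal") for s in samples}
        for gi in range(n):
            shift = config.effect_log2 * dir_map.get(gi, 0)
            for k in range(n_probesets_per_gene):
                probesets.append(f"{prefix}{gi:05d}_{k}_at")
                mu = np.full(n_s, baselines[gi])
                mu[: config.n_tumor] += shift
                rows.append(rng.normal(mu, config.sigma))
        return ExpressionMatrix(
            probeset_ids=probesets,
            sample_ids=samples,
            values=np.vstack(rows),
            species=species,
            groups=groups,
        )

    human = build("human", human_dir, "HS")
    mouse = build("mouse", mouse_dir, "MM")

    triples = []
    for gi, g in enumerate(genes):
        for k in range(1 + config.extra_probesets_per_gene):
            triples.append((f"HS{gi:05d}_{k}_at", g, f"MM{gi:05d}_0_at"))
    orthology = OrthologyMap(
        pd.DataFrame(triples, columns=list(OrthologyMap.COLUMNS))
    )

    concordant = {genes[int(i)]: int(d) for i, d in zip(concordant_idx, conc_dir)}
    n_prolif = int(round(config.frac_proliferation_overlap * len(concordant)))
    prolif = set(list(concordant)[:n_prolif])
    # pad the exclusion set with non-DE background genes so it looks like a
    # real proliferation signature rather than a subset of the truth
    de_all = {genes[i] for i in human_dir} | {genes[i] for i in mouse_dir}
    background = [g for g in genes if g not in de_all][:50]
    prolif |= set(background)

    # survival-linked genes drawn from the opposite end of the concordant
    # list so they stay disjoint from the proliferation-excluded subset
    n_surv = max(1, int(round(0.13 * len(concordant)))) if concordant else 0
    survival_genes = {
        g: config.survival_beta for g in list(concordant)[-n_surv:]
    } if n_surv else {}

    truth = SimTruth(
        de_genes_human={genes[i] for i in human_dir},
        de_genes_mouse={genes[i] for i in mouse_dir},
        concordant_genes=concordant,
        proliferation_genes=prolif,
        survival_genes=survival_genes,
    )
    return human, mouse, orthology, truth


def simulate_survival(
    genes: list[str], truth: SimTruth, n_subjects: int, config: SimConfig
) -> SurvivalCohort:
    """Exponential survival cohort with expression-linked hazards.

    Per-subject gene expression is standard normal; the event time is
    exponential with rate baseline_hazard × exp(Σ β_g x_g) over the
    survival-linked genes, administratively censored at ``censor_time``.
    Subjects split evenly between the CHOP and R-CHOP arms.
    """
    config.validate()
    if not genes:
        raise ValueError("gene list must be non-empty")
    if n_subjects < 20:
        raise ValueError("need at least 20 subjects")
    rng = _rng(config, _STREAM_SURVIVAL)
    x = rng.standard_normal((n_subjects, len(genes)))
    betas = np.array([truth.survival_genes.get(g, 0.0) for g in genes])
    rate = config.baseline_hazard * np.exp(x @ betas)
    t_event = rng.exponential(1.0 / rate)
    time = np.minimum(t_event, config.censor_time)
    event = (t_event <= config.censor_time).astype(int)
    arm = np.where(np.arange(n_subjects) % 2 == 0, "CHOP", "R-CHOP")
    data = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n_subjects)],
            "time": time,
            "event": event,
            "arm": arm,
        }
    )
    for j, g in enumerate(genes):
        data[g] = x[:, j]
    return SurvivalCohort(data)


def simulate_network(
    truth: SimTruth, seed_genes: list[str], config: SimConfig
):
    """Interaction network with a planted high-confidence hub.

    The hub connects to ``hub_seed_edges`` of the seed genes with
    confidence ≥ 0.9; background edges among all nodes appear independently
    with probability ``background_edge_prob`` at confidence ≤ 0.4.
    """
    from .network import WeightedNetwork

    config.validate()
    if not seed_genes:
        raise ValueError("seed_genes must be non-empty")
    rng = _rng(config, _STREAM_NETWORK)
    hub = truth.hub_node
    others = [g for g in sorted(truth.concordant_genes) if g not in seed_genes][:40]
    nodes = list(dict.fromkeys(list(seed_genes) + [hub] + others))
    edges: list[tuple[str, str, float]] = []
    n_hub = min(config.hub_seed_edges, len(seed_genes))
    for s in seed_genes[:n_hub]:
        edges.append((hub, s, float(rng.uniform(0.9, 0.99))))
    seen = {frozenset((u, v)) for u, v, _ in edges}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if frozenset((u, v)) in seen:
                continue
            if rng.random() < config.background_edge_prob:
                edges.append((u, v, float(rng.uniform(0.1, 0.4))))
    return WeightedNetwork.from_edges(edges, nodes=nodes)


def simulate_study_summaries(
    truth: SimTruth, n_studies: int, detect_prob: float, config: SimConfig
) -> list[StudySummary]:
    """External-study DE summaries in which each planted concordant gene is
    detected (|FC| ≥ 2, p ≤ 0.01, planted direction) independently with
    probability *detect_prob*; undetected and non-DE genes appear with
    sub-threshold statistics."""
    config.validate()
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    if not 0 <= detect_prob <= 1:
        raise ValueError("detect_prob must lie in [0, 1]")
    rng = _rng(config, _STREAM_STUDIES)
    categories = [
        "DLBCL vs normal",
        "DLBCL vs FL",
        "DLBCL vs BL",
        "FL transformation",
    ]
    non_de = sorted(truth.de_genes_human - set(truth.concordant_genes))[:50]
    studies = []
    for s in range(n_studies):
        rows = []
        for g, d in sorted(truth.concordant_genes.items()):
            if rng.random() < detect_prob:
                fc = d * (2.0 + rng.exponential(2.0))
                p = float(rng.uniform(1e-6, 0.01))
            else:
                fc = d * float(rng.uniform(1.0, 1.9))
                p = float(rng.uniform(0.05, 1.0))
            rows.append((g, fc, p))
        for g in non_de:
            sign = 1 if rng.random() < 0.5 else -1
            rows.append(
                (g, sign * float(rng.uniform(1.0, 1.9)), float(rng.uniform(0.05, 1.0)))
            )
        studies.append(
            StudySummary(
                study_id=f"study{s + 1}",
                category=categories[s % len(categories)],
                records=pd.DataFrame(
                    rows, columns=["gene_symbol", "fold_change", "p_value"]
                ),
            )
        )
    return studies
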