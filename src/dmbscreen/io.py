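"""Readers and writers for the pipeline's plain-text formats, the packaged
reference fixtures, and the pipeline configuration.

All tabular files are tab-separated with a mandatory header row; lines
starting with ``#`` are comments. Gene sets use the GMT convention
(name, description, then members, one set per line). The two packaged
fixtures transcribe the published 60-gene concordant ("DMB") list with
per-species probesets, p-values and signed fold changes, and the published
per-probeset survival results (hazard ratios with 95% CIs in the CHOP and
R-CHOP arms).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .concordance import GeneSet, OrthologyMap
from .diffexpr import ExpressionMatrix

_FIXTURES = resources.files("dmbscreen") / "fixtures"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (report percentages round 0.5 away from
    zero, unlike Python's banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# --- expression matrices ---------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path, sidecar_path) -> None:
    """Write probesets × samples TSV plus a sample→group/species sidecar."""
    df = pd.DataFrame(
        matrix.values, index=matrix.probeset_ids, columns=matrix.sample_ids
    )
    df.index.name = "probeset_id"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
    side = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group": [matrix.groups[s] for s in matrix.sample_ids],
            "species": matrix.species,
        }
    )
    write_tsv(side, sidecar_path)


def read_expression(path, sidecar_path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    side = read_tsv(sidecar_path)
    species = side["species"].iloc[0]
    groups = dict(zip(side["sample_id"], side["group"]))
    return ExpressionMatrix(
        probeset_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        species=str(species),
        groups=groups,
    )


# --- orthology, gene sets, networks ---------------------------------------

def read_orthology(path) -> OrthologyMap:
    df = read_tsv(path)
    return OrthologyMap(df[list(OrthologyMap.COLUMNS)])


def write_orthology(orthology: OrthologyMap, path) -> None:
    write_tsv(orthology.triples[list(OrthologyMap.COLUMNS)], path)


def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(parts[0], parts[1], set(p for p in parts[2:] if p)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_edge_list(path):
    from .network import WeightedNetwork

    df = read_tsv(path)
    return WeightedNetwork.from_frame(df)


def write_edge_list(net, path) -> None:
    rows = [
        (u, v, d["confidence"]) for u, v, d in net.graph.edges(data=True)
    ]
    write_tsv(
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]), path
    )


def read_survival(path):
    from .survival import SurvivalCohort

    return SurvivalCohort(read_tsv(path))


def write_survival(cohort, path) -> None:
    write_tsv(cohort.data, path)


# --- packaged fixtures -----------------------------------------------------

@dataclass
class Table1Fixture:
    """The published 60-gene concordant list in tidy long form.

    ``rows`` has one row per human probeset; mouse columns are filled on
    each gene's first row only (every gene has exactly one mouse probeset).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.genes()
        if len(genes) != 60:
            raise ValueError(f"expected 60 genes, found {len(genes)}")
        per_gene = self.rows.groupby("gene_symbol")
        if (per_gene["mouse_probeset"].count() != 1).any():
            raise ValueError("each gene must have exactly one mouse probeset")
        folds = pd.concat(
            [self.rows["human_fold"], self.rows["mouse_fold"].dropna()]
        )
        if (folds.abs() < 2).any():
            raise ValueError("all fold magnitudes must be >= 2")
        ps = pd.concat([self.rows["human_p"], self.rows["mouse_p"].dropna()])
        if (ps >= 0.01).any():
            raise ValueError("all p-values must be < 0.01")

    def genes(self) -> list[str]:
        return sorted(self.rows["gene_symbol"].unique())

    def gene_table(self) -> pd.DataFrame:
        """One row per gene with best (largest-magnitude) per-species fold
        and the mouse record."""
        rows = []
        for g, grp in self.rows.groupby("gene_symbol"):
            hbest = grp.loc[grp["human_fold"].abs().idxmax()]
            mrow = grp.dropna(subset=["mouse_fold"]).iloc[0]
            rows.append(
                {
                    "gene_symbol": g,
                    "human_fold": hbest["human_fold"],
                    "mouse_fold": mrow["mouse_fold"],
                    "direction_human": 1 if hbest["human_fold"] > 0 else -1,
                    "direction_mouse": 1 if mrow["mouse_fold"] > 0 else -1,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class Table2Fixture:
    """Published per-probeset survival fits (HR with 95% CI per arm)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        for arm in ("chop", "rchop"):
            hr = self.rows[f"hr_{arm}"]
            lo = self.rows[f"ci_low_{arm}"]
            hi = self.rows[f"ci_high_{arm}"]
            if (hr <= 0).any():
                raise ValueError("hazard ratios must be positive")
            if (lo >= hi).any():
                raise ValueError("CI bounds out of order")

    def significant_genes(self) -> set[str]:
        """Genes with a 95% CI excluding 1 in at least one arm."""
        sig = set()
        for _, r in self.rows.iterrows():
            for arm in ("chop", "rchop"):
                if r[f"ci_low_{arm}"] > 1 or r[f"ci_high_{arm}"] < 1:
                    sig.add(r["gene_symbol"])
        return sig


def load_fixture(name: str):
    """Load a packaged fixture: ``"table1"`` (concordant gene list) or
    ``"table2"`` (survival fits)."""
    if name == "table1":
        df = pd.read_csv(
            _FIXTURES / "table1_dmb_genes.tsv", sep="\t", comment="#"
        )
        return Table1Fixture(df)
    if name == "table2":
        df = pd.read_csv(
            _FIXTURES / "table2_survival.tsv", sep="\t", comment="#"
        )
        return Table2Fixture(df)
    raise KeyError(f"unknown fixture {name!r}")


# --- configuration ---------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every threshold the end-to-end screen applies, in one place."""

    p_anova: float = 0.01
    fdr_primary: float = 0.01
    cross_fdr_loose: float = 0.05
    cross_fdr_strict: float = 0.01
    fold_threshold: float = 2.0
    recurrence_p: float = 0.01
    recurrence_fold: float = 2.0
    alpha_survival: float = 0.05
    ci_level: float = 0.95
    chance_level: float = 0.05
    network_target_n: int = 50
    network_min_confidence: float = 0.9
    keep_discordant: bool = False
    n_studies: int = 7
    detect_prob: float = 0.5
    n_subjects: int = 200
    rng_seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "p_anova",
            "fdr_primary",
            "cross_fdr_loose",
            "cross_fdr_strict",
            "recurrence_p",
            "alpha_survival",
            "ci_level",
            "chance_level",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if self.network_target_n < 1:
            raise ValueError("network_target_n must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))
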