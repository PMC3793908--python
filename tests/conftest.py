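import numpy as np
import pytest

from dmbscreen.diffexpr import ExpressionMatrix
from dmbscreen.pipeline import run_pipeline
from dmbscreen.simulate import SimConfig, simulate_two_species


def make_matrix(tumor_rows, normal_rows, species="human", prefix="P"):
    """Build an ExpressionMatrix from per-probeset tumor/normal value lists."""
    tumor_rows = np.atleast_2d(np.asarray(tumor_rows, dtype=float))
    normal_rows = np.atleast_2d(np.asarray(normal_rows, dtype=float))
    n_t, n_n = tumor_rows.shape[1], normal_rows.shape[1]
    samples = [f"T{i}" for i in range(n_t)] + [f"N{i}" for i in range(n_n)]
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    return ExpressionMatrix(
        probeset_ids=[f"{prefix}{i}" for i in range(tumor_rows.shape[0])],
        sample_ids=samples,
        values=np.hstack([tumor_rows, normal_rows]),
        species=species,
        groups=groups,
    )


@pytest.fixture(scope="session")
def planted_sim():
    """One planted two-species simulation shared across tests."""
    cfg = SimConfig(seed=7)
    human, mouse, orthology, truth = simulate_two_species(cfg)
    return cfg, human, mouse, orthology, truth


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on planted data, shared across tests."""
    return run_pipeline(sim_config=SimConfig(seed=11))
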