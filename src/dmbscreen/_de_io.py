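"""Persistence helpers for differential-expression results (used by the
analysis drivers so each stage can re-read the previous stage's tables)."""

from __future__ import annotations

import pandas as pd

from .diffexpr import DEResult
from .io import read_tsv, write_tsv


def write_de_result(res: DEResult, path) -> None:
    write_tsv(
        res.full,
        path,
        comment=(
            f"species={res.species} p_cut={res.p_cut} q_cut={res.q_cut} "
            f"fdr_scope={res.fdr_scope}"
        ),
    )


def read_de_result(
    path, species: str, p_cut: float = 0.01, q_cut: float = 0.01
) -> DEResult:
    full = read_tsv(path)
    full["gene_symbol"] = full["gene_symbol"].fillna("")
    sig = full[(full["p_value"] < p_cut) & (full["q_value"] < q_cut)].reset_index(
        drop=True
    )
    return DEResult(species=species, full=full, significant=sig, p_cut=p_cut, q_cut=q_cut)
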