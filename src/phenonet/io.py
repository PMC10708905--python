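"""Reading and writing matrices, fits and event lists as plain text.

Incidence and copresence matrices travel as labeled dense TSV or as
Matrix Market (``.mtx``) sparse files; event lists as the dated edge-list
TSV consumed by :func:`phenonet.temporal_data.read_daily_events`; fits
and result bundles as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .exceptions import InputError
from .temporal_data import BipartiteNetwork, CopresenceMatrix, TemporalDataset

__all__ = [
    "write_incidence_tsv",
    "read_incidence_tsv",
    "write_matrix_mtx",
    "read_matrix_mtx",
    "write_copresence_tsv",
    "write_events_tsv",
    "write_json",
]


def write_incidence_tsv(network: BipartiteNetwork, path) -> None:
    """Dense labeled TSV: rows x columns with 0/1 entries."""
    df = pd.DataFrame(
        network.incidence, index=network.row_labels, columns=network.col_labels
    )
    df.to_csv(path, sep="\t", index_label="actor")


def read_incidence_tsv(path) -> BipartiteNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    inc = df.to_numpy()
    if not np.isin(inc, (0, 1)).all():
        raise InputError(f"{path}: incidence entries must be 0/1")
    return BipartiteNetwork(
        tuple(str(r) for r in df.index),
        tuple(str(c) for c in df.columns),
        inc.astype(np.int8),
    )


def write_matrix_mtx(matrix: np.ndarray, path) -> None:
    """Sparse Matrix Market (coordinate, integer or real) text file."""
    mmwrite(str(path), sparse.coo_matrix(np.asarray(matrix)))


def read_matrix_mtx(path) -> np.ndarray:
    m = mmread(str(path))
    return m.toarray() if sparse.issparse(m) else np.asarray(m)


def write_copresence_tsv(
    N: CopresenceMatrix, network: BipartiteNetwork, path
) -> None:
    df = pd.DataFrame(N.n, index=network.row_labels, columns=network.col_labels)
    df.to_csv(path, sep="\t", index_label="actor")


def write_events_tsv(data: TemporalDataset, path) -> None:
    """Dated edge-list TSV round-trippable through read_daily_events."""
    out = data.events.copy()
    out["day"] = out["day"].map(lambda d: d.isoformat())
    out.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
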