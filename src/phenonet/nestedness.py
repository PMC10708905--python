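"""Nestedness of bipartite networks via the normalized spectral radius.

The adjacency matrix of a bipartite graph is the (R+C) x (R+C) symmetric
matrix with the R x C incidence matrix B as its off-diagonal block; its
spectral radius equals the largest singular value of B, which is how it
is computed here.  For fixed size and fill, a larger spectral radius
means a more nested topology.  Raw values are normalized by the maximum
possible value for a graph with L edges and R + C vertices,

    rho = rho_raw / sqrt(2L - R - C + 1),

which maps the perfectly nested single link K_{1,1} to exactly 1.  The
radicand is positive whenever every node has degree >= 1.

Erdős–Rényi (ER) random graphs with matched (R, C, L) provide the
baseline: delta_rho = rho - rho_ER > 0 marks a nested network, and

    delta_rho_tilde = (rho - rho_ER) / (rho_emp - rho_ER)

rescales a model's nestedness between the ER baseline (0) and the
empirical level (1).  Values above 1 are legitimate (model more nested
than the data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateNetworkError, InputError
from .temporal_data import BipartiteNetwork

__all__ = [
    "NestednessResult",
    "ERBaseline",
    "spectral_radius_raw",
    "normalize_rho",
    "rho_normalized",
    "er_baseline_rho",
    "delta_rho",
    "delta_rho_tilde",
    "measure_nestedness",
]


@dataclass(frozen=True)
class ERBaseline:
    """Ensemble mean/sd of normalized spectral radius over ER graphs."""

    mean: float
    sd: float
    n_graphs: int
    n_empty: int = 0  # draws with no links at all (counted as rho = 0)


@dataclass(frozen=True)
class NestednessResult:
    rho_raw: float
    rho: float
    rho_er_mean: float
    rho_er_sd: float
    delta_rho: float
    rho_emp: float | None = None
    delta_rho_tilde: float | None = None

    def to_dict(self) -> dict:
        return {
            "rho_raw": self.rho_raw,
            "rho": self.rho,
            "rho_er_mean": self.rho_er_mean,
            "rho_er_sd": self.rho_er_sd,
            "delta_rho": self.delta_rho,
            "rho_emp": self.rho_emp,
            "delta_rho_tilde": self.delta_rho_tilde,
        }


def spectral_radius_raw(incidence: np.ndarray) -> float:
    """Dominant-eigenvalue magnitude of the bipartite adjacency matrix.

    Computed as the largest singular value of the incidence matrix, which
    is identical (the adjacency spectrum is {+/- sigma_k} plus zeros) but
    works at half the dimension.
    """
    mat = np.asarray(incidence, dtype=float)
    if mat.size == 0:
        raise InputError("empty incidence matrix")
    if not mat.any():
        warnings.warn("all-zero incidence matrix: spectral radius is 0", stacklevel=2)
        return 0.0
    return float(np.linalg.svd(mat, compute_uv=False)[0])


def normalize_rho(rho_raw: float, R: int, C: int, L: int) -> float:
    """Scale a raw spectral radius by its maximum possible value.

    The bound sqrt(2L - R - C + 1) holds for connected graphs with every
    node of degree >= 1; the radicand must therefore be positive.
    """
    radicand = 2 * L - R - C + 1
    if radicand < 1:
        raise DegenerateNetworkError(
            f"normalization undefined for R={R}, C={C}, L={L}: "
            "2L - R - C + 1 < 1 (some node has degree 0?)"
        )
    return float(rho_raw / np.sqrt(radicand))


def rho_normalized(matrix: np.ndarray, *, drop_empty: bool = True) -> float:
    """Normalized spectral radius of a binary matrix.

    With ``drop_empty`` (default), all-zero rows and columns are removed
    first — they do not change the singular values but do change the
    (R, C, L) entering the normalization — so the value is the one the
    network would get had only interacting actors been included.
    """
    mat = np.asarray(matrix, dtype=float)
    if drop_empty:
        mat = mat[mat.sum(axis=1) > 0][:, mat.sum(axis=0) > 0]
    if mat.size == 0:
        raise DegenerateNetworkError("matrix has no links")
    R, C = mat.shape
    return normalize_rho(spectral_radius_raw(mat), R, C, int(mat.sum()))


def er_baseline_rho(
    R: int,
    C: int,
    L: int,
    n_graphs: int = 10_000,
    seed: int | np.random.Generator = 0,
    *,
    batch: int = 1_000,
) -> ERBaseline:
    """Normalized spectral radius over an ensemble of ER bipartite graphs.

    Each graph draws every link independently with probability L/(R*C)
    (expected-L ensemble, matching the ER model definition).  Each draw is
    normalized after removing its all-zero rows/columns using its own
    realized link count, so the radicand stays positive for every
    nonempty draw; empty draws contribute rho = 0 and are counted in
    ``n_empty``.
    """
    if n_graphs < 1:
        raise InputError("n_graphs must be >= 1")
    p = L / (R * C)
    if not 0.0 <= p <= 1.0:
        raise InputError(f"L={L} incompatible with R*C={R * C}")
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_graphs)
    n_empty = 0
    done = 0
    while done < n_graphs:
        m = min(batch, n_graphs - done)
        graphs = (rng.random((m, R, C)) < p).astype(float)
        sigma = np.linalg.svd(graphs, compute_uv=False)[:, 0]
        links = graphs.sum(axis=(1, 2))
        rows = (graphs.sum(axis=2) > 0).sum(axis=1)
        cols = (graphs.sum(axis=1) > 0).sum(axis=1)
        radicand = 2 * links - rows - cols + 1
        empty = links == 0
        n_empty += int(empty.sum())
        radicand[empty] = 1.0  # sigma is 0 there; rho = 0 regardless
        rhos[done : done + m] = sigma / np.sqrt(radicand)
        done += m
    return ERBaseline(
        mean=float(rhos.mean()), sd=float(rhos.std(ddof=0)), n_graphs=n_graphs,
        n_empty=n_empty,
    )


def delta_rho(rho: float, rho_er_mean: float) -> float:
    """Excess nestedness over the ER baseline; > 0 means nested."""
    return rho - rho_er_mean


def delta_rho_tilde(rho_model: float, rho_er_mean: float, rho_emp: float) -> float:
    """Rescale between ER baseline (0) and empirical nestedness (1)."""
    span = rho_emp - rho_er_mean
    if span == 0.0:
        raise InputError(
            "delta_rho_tilde undefined: empirical rho equals the ER mean"
        )
    return (rho_model - rho_er_mean) / span


def measure_nestedness(
    network: BipartiteNetwork | np.ndarray,
    n_graphs: int = 10_000,
    seed: int | np.random.Generator = 0,
    *,
    rho_emp: float | None = None,
    baseline: ERBaseline | None = None,
) -> NestednessResult:
    """Raw, normalized and ER-referenced nestedness of one network.

    When ``rho_emp`` is supplied the result also carries delta_rho_tilde
    (the network's nestedness rescaled between ER and empirical levels).
    A precomputed ``baseline`` may be passed so that several networks of
    identical (R, C, L) share one ER ensemble.
    """
    inc = network.incidence if isinstance(network, BipartiteNetwork) else np.asarray(network)
    mat = inc[inc.sum(axis=1) > 0][:, inc.sum(axis=0) > 0]
    if mat.size == 0:
        raise DegenerateNetworkError("network has no links")
    R, C = mat.shape
    L = int(mat.sum())
    raw = spectral_radius_raw(mat)
    rho = normalize_rho(raw, R, C, L)
    if baseline is None:
        baseline = er_baseline_rho(R, C, L, n_graphs, seed)
    dr = delta_rho(rho, baseline.mean)
    drt = None
    if rho_emp is not None:
        drt = delta_rho_tilde(rho, baseline.mean, rho_emp)
    return NestednessResult(
        rho_raw=raw,
        rho=rho,
        rho_er_mean=baseline.mean,
        rho_er_sd=baseline.sd,
        delta_rho=dr,
        rho_emp=rho_emp,
        delta_rho_tilde=drt,
    )
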