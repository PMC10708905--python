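"""Probabilistic link models for binary bipartite networks.

Four models assign each potential link an independent Bernoulli
probability while conserving, on average, the empirical link count L:

* **ER** — every entry equals the fill L/(R*C) (Erdős–Rényi);
* **degree distribution (DD)** — p_ij = k_i/(2C) + k_j/(2R), with k_i and
  k_j the empirical row/column degrees;
* **phenology** — p_ij = 1 - q^{n_ij}, where n_ij is the number of days
  the pair was copresent and q is the probability of *no* interaction on
  a single copresent day;
* **presence** — same functional form, but n_ij is replaced by the
  rounded-up average number of days each actor of the pair was present.

The single parameter q of the phenology/presence models is set so the
expected link count matches L.  Writing x_k for the number of pairs with
copresence k (k = 0..f) and Z = R*C - L for the number of empty entries
in the empirical incidence matrix, q solves

    g(q) = sum_k x_k q^k = Z,   q in [0, 1].

g is nondecreasing on [0, 1] with g(0) = x_0 and g(1) = R*C, so the root
is unique and bracketed whenever x_0 <= Z, i.e. whenever no more links
are required than there are pairs with at least one copresence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import DimensionError, InputError, ModelInfeasibleError
from .temporal_data import BipartiteNetwork, CopresenceMatrix

__all__ = [
    "PhenologyFit",
    "LinkProbabilityMatrix",
    "er_probabilities",
    "degree_distribution_probabilities",
    "solve_q",
    "phenology_probabilities",
    "presence_probabilities",
    "sample_realizations",
]

#: canonical model names
MODEL_NAMES = ("ER", "DD", "phenology", "presence")


@dataclass(frozen=True)
class PhenologyFit:
    """Solved interaction probability for a copresence histogram.

    ``q`` is the probability of no interaction given one copresence and
    ``p = 1 - q``; ``coefficients[k]`` counts the pairs with copresence k;
    ``Z`` is the number of zeros in the empirical incidence matrix;
    ``residual`` is g(q) - Z at the returned root.
    """

    q: float
    p: float
    coefficients: np.ndarray
    Z: int
    residual: float

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "p": self.p,
            "coefficients": [int(x) for x in self.coefficients],
            "Z": self.Z,
            "residual": self.residual,
        }


@dataclass(frozen=True)
class LinkProbabilityMatrix:
    """Per-pair Bernoulli link probabilities under one model."""

    probs: np.ndarray
    model_name: str
    fit: PhenologyFit | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", arr)
        if arr.min(initial=0.0) < 0.0 or arr.max(initial=0.0) > 1.0 + 1e-12:
            raise InputError("probabilities must lie in [0, 1]")

    @property
    def expected_links(self) -> float:
        return float(self.probs.sum())


def er_probabilities(network: BipartiteNetwork) -> LinkProbabilityMatrix:
    """Uniform link probability equal to the network fill."""
    probs = np.full((network.R, network.C), network.fill)
    return LinkProbabilityMatrix(probs, "ER")


def degree_distribution_probabilities(
    network: BipartiteNetwork,
) -> LinkProbabilityMatrix:
    """p_ij = k_i/(2C) + k_j/(2R) from the empirical degree sequences.

    Conserves the total expected link count exactly; the expected degree
    of row node i is k_i/2 + L/(2R) (and symmetrically for columns), so
    individual degrees are conserved in the aggregate, pulling each node
    halfway toward the mean degree of its category.
    """
    ki = network.row_degrees[:, None].astype(float)
    kj = network.col_degrees[None, :].astype(float)
    probs = ki / (2 * network.C) + kj / (2 * network.R)
    return LinkProbabilityMatrix(probs, "DD")


def solve_q(coefficients, Z: int) -> PhenologyFit:
    """Solve sum_k x_k q^k = Z for the unique root q in [0, 1].

    Parameters
    ----------
    coefficients
        Histogram of copresence values: either an array-like ``x`` with
        ``x[k]`` the number of pairs having copresence k, or a mapping
        ``{k: count}`` (missing keys count as 0).
    Z
        Number of zero entries in the empirical incidence matrix,
        R*C - L.

    The boundary roots q = 0 (every copresent pair linked) and q = 1
    (no links at all) are returned exactly; interior roots come from
    bracketed Brent iteration at ~1e-15 tolerance.
    """
    if isinstance(coefficients, dict):
        f = max(coefficients) if coefficients else 0
        x = np.zeros(f + 1, dtype=np.int64)
        for k, v in coefficients.items():
            x[int(k)] = v
    else:
        x = np.asarray(coefficients, dtype=np.int64)
    if x.ndim != 1 or x.size == 0 or (x < 0).any():
        raise InputError("coefficients must be a 1-D nonnegative histogram")
    total = int(x.sum())
    Z = int(Z)
    if not 0 <= Z <= total:
        raise InputError(f"Z={Z} outside [0, {total}=R*C]")

    positive_pairs = total - int(x[0])
    L = total - Z
    if int(x[0]) > Z:
        raise ModelInfeasibleError(
            f"no root in [0, 1]: L={L} links requested but only "
            f"{positive_pairs} pairs have copresence >= 1"
        )

    powers = np.arange(x.size)

    def g(q: float) -> float:
        return float(np.dot(x, q**powers))

    if Z == int(x[0]):
        q = 0.0
    elif Z == total:
        q = 1.0
    else:
        q = float(brentq(lambda t: g(t) - Z, 0.0, 1.0, xtol=1e-14, rtol=8.9e-16))
    return PhenologyFit(q=q, p=1.0 - q, coefficients=x, Z=Z, residual=g(q) - Z)


def _copresence_model(
    N: CopresenceMatrix, network: BipartiteNetwork, name: str
) -> LinkProbabilityMatrix:
    if N.n.shape != (network.R, network.C):
        raise DimensionError(
            f"copresence matrix {N.n.shape} does not match network "
            f"({network.R}, {network.C})"
        )
    hist = np.bincount(N.n.ravel(), minlength=N.f + 1)
    fit = solve_q(hist, network.R * network.C - network.L)
    probs = 1.0 - fit.q ** N.n.astype(float)
    probs[N.n == 0] = 0.0  # q^0 = 1 exactly, never a link without copresence
    return LinkProbabilityMatrix(probs, name, fit=fit)


def phenology_probabilities(
    N: CopresenceMatrix, network: BipartiteNetwork
) -> LinkProbabilityMatrix:
    """p_ij = 1 - q^{n_ij} with q solved from the copresence histogram."""
    return _copresence_model(N, network, "phenology")


def presence_probabilities(
    N_presence: CopresenceMatrix, network: BipartiteNetwork
) -> LinkProbabilityMatrix:
    """Presence-model probabilities: q re-solved against the
    rounded-up average-presence matrix from
    :func:`phenonet.temporal_data.presence_average_matrix`."""
    return _copresence_model(N_presence, network, "presence")


def sample_realizations(
    probs: LinkProbabilityMatrix | np.ndarray,
    n_realizations: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw independent Bernoulli network realizations.

    Returns an array of shape (n_realizations, R, C) with uint8 entries.
    Rows/columns that end up empty are retained so that realizations stay
    comparable cell-by-cell with the empirical incidence matrix.
    """
    if n_realizations < 1:
        raise InputError("n_realizations must be >= 1")
    p = probs.probs if isinstance(probs, LinkProbabilityMatrix) else np.asarray(probs)
    rng = np.random.default_rng(seed)
    return (rng.random((n_realizations, *p.shape)) < p).astype(np.uint8)
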