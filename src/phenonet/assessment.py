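"""Link-prediction assessment and the nested-backbone test.

Model realizations are compared cell-by-cell with the empirical incidence
matrix.  Each cell falls into one of four categories — true positive
(link in both), true negative (link in neither), false positive (model
only), false negative (empirical only) — and the confusion counts are
summarized by the phi coefficient (Pearson correlation of two binary
variables), the F-score F1 = 2TP/(2TP+FP+FN), Youden's J (informedness)
and the true positive rate.  Because all models conserve the expected
link count, FP ≈ FN on average, which makes F1 ≈ TPR and phi ≈ J.

The backbone test asks whether the empirical links a model explains
(true positives) are more nested than the links it misses (false
negatives).  Per realization both subsets are scored with the normalized
spectral radius and with their excess nestedness over matched ER
baselines relative to the maximum possible excess,

    excess = (rho_subset - rho_subset_ER) / (1 - rho_subset_ER),

and the two ratios TP/FN are reported together with the fraction of
realizations in which each exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, InputError, UndefinedStatisticError
from .link_models import LinkProbabilityMatrix, sample_realizations
from .nestedness import ERBaseline, er_baseline_rho, rho_normalized
from .temporal_data import BipartiteNetwork

__all__ = [
    "ConfusionCounts",
    "AssessmentResult",
    "BackbonePoint",
    "BackboneResult",
    "confusion_counts",
    "phi_coefficient",
    "f_score",
    "youden_j",
    "true_positive_rate",
    "ensemble_assess",
    "backbone_from_subsets",
    "backbone_ratios",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(
    model_matrix: np.ndarray, empirical: BipartiteNetwork | np.ndarray
) -> ConfusionCounts:
    """Four-way classification of cells of one model realization."""
    emp = (
        empirical.incidence
        if isinstance(empirical, BipartiteNetwork)
        else np.asarray(empirical)
    )
    mod = np.asarray(model_matrix)
    if mod.shape != emp.shape:
        raise DimensionError(
            f"model matrix {mod.shape} does not match empirical {emp.shape}"
        )
    mod = mod.astype(bool)
    emp = emp.astype(bool)
    return ConfusionCounts(
        tp=int((mod & emp).sum()),
        tn=int((~mod & ~emp).sum()),
        fp=int((mod & ~emp).sum()),
        fn=int((~mod & emp).sum()),
    )


def phi_coefficient(c: ConfusionCounts) -> float:
    """Pearson correlation for binary agreement, in [-1, 1].

    Undefined (raises) when any marginal of the 2x2 table is zero.
    """
    denom2 = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom2 == 0:
        raise UndefinedStatisticError("phi undefined: a confusion marginal is zero")
    return (c.tp * c.tn - c.fp * c.fn) / float(np.sqrt(denom2))


def f_score(c: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN), the share of links correctly explained."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedStatisticError("F-score undefined: TP = FP = FN = 0")
    return 2 * c.tp / denom


def true_positive_rate(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedStatisticError("TPR undefined: no empirical links")
    return c.tp / (c.tp + c.fn)


def youden_j(c: ConfusionCounts) -> float:
    """Informedness: sensitivity + specificity - 1."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedStatisticError("J undefined: an outcome class is empty")
    return c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp) - 1.0


@dataclass(frozen=True)
class AssessmentResult:
    """Per-realization accuracy statistics with ensemble mean and sd.

    Undefined per-realization values (zero marginals) are stored as NaN
    and excluded from the means/sds; their counts are in ``n_undefined``.
    """

    model_name: str
    n_realizations: int
    phi: np.ndarray = field(repr=False)
    f1: np.ndarray = field(repr=False)
    j: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)  # (n, 4) columns TP, TN, FP, FN
    n_undefined: dict[str, int] = field(default_factory=dict)

    def _stat(self, arr: np.ndarray) -> tuple[float, float]:
        if np.isnan(arr).all():
            return float("nan"), float("nan")
        return float(np.nanmean(arr)), float(np.nanstd(arr, ddof=1))

    @property
    def summary(self) -> dict:
        out: dict = {"model": self.model_name, "n_realizations": self.n_realizations}
        for name, arr in (
            ("phi", self.phi), ("f1", self.f1), ("j", self.j), ("tpr", self.tpr)
        ):
            mean, sd = self._stat(arr)
            out[f"{name}_mean"] = mean
            out[f"{name}_sd"] = sd
        out["n_undefined"] = dict(self.n_undefined)
        for k, name in enumerate(("tp", "tn", "fp", "fn")):
            out[f"{name}_mean"] = float(self.counts[:, k].mean())
        return out


def _vector_stats(counts: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized phi/F1/J/TPR with NaN where undefined."""
    tp, tn, fp, fn = (counts[:, k].astype(float) for k in range(4))
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        phi = np.where(denom > 0, (tp * tn - fp * fn) / denom, np.nan)
        d1 = 2 * tp + fp + fn
        f1 = np.where(d1 > 0, 2 * tp / d1, np.nan)
        pos = tp + fn
        neg = tn + fp
        tpr = np.where(pos > 0, tp / pos, np.nan)
        j = np.where((pos > 0) & (neg > 0), tp / pos + tn / neg - 1.0, np.nan)
    return phi, f1, j, tpr


def ensemble_assess(
    probs: LinkProbabilityMatrix,
    empirical: BipartiteNetwork,
    n_realizations: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> AssessmentResult:
    """Sample realizations and score them against the empirical network."""
    emp = empirical.incidence.astype(bool)
    if probs.probs.shape != emp.shape:
        raise DimensionError("probability matrix does not match network shape")
    reals = sample_realizations(probs, n_realizations, seed).astype(bool)
    tp = (reals & emp).sum(axis=(1, 2))
    fp = (reals & ~emp).sum(axis=(1, 2))
    fn = (~reals & emp).sum(axis=(1, 2))
    tn = emp.size - tp - fp - fn
    counts = np.stack([tp, tn, fp, fn], axis=1)
    phi, f1, j, tpr = _vector_stats(counts)
    n_undef = {
        name: int(np.isnan(arr).sum())
        for name, arr in (("phi", phi), ("f1", f1), ("j", j), ("tpr", tpr))
        if np.isnan(arr).any()
    }
    return AssessmentResult(
        model_name=probs.model_name,
        n_realizations=n_realizations,
        phi=phi,
        f1=f1,
        j=j,
        tpr=tpr,
        counts=counts,
        n_undefined=n_undef,
    )


@dataclass(frozen=True)
class BackbonePoint:
    """Backbone statistics for one TP/FN partition of the empirical links."""

    rho_tp: float
    rho_fn: float
    ratio_nestedness: float  # rho_tp / rho_fn
    excess_tp: float
    excess_fn: float
    ratio_excess: float  # excess_tp / excess_fn


@dataclass(frozen=True)
class BackboneResult:
    """Ensemble backbone test for one model against one empirical network."""

    n_realizations: int
    n_used: int
    n_skipped: int  # realizations with an empty TP or FN subset
    points: list[BackbonePoint] = field(repr=False)
    frac_ratio_nestedness_gt1: float = float("nan")
    frac_ratio_excess_gt1: float = float("nan")
    significance_level: float = 0.95

    @property
    def tp_more_nested(self) -> bool:
        return self.frac_ratio_nestedness_gt1 >= self.significance_level

    @property
    def tp_more_excess_nested(self) -> bool:
        return self.frac_ratio_excess_gt1 >= self.significance_level

    @property
    def summary(self) -> dict:
        med = lambda xs: float(np.median(xs)) if xs else float("nan")  # noqa: E731
        return {
            "n_realizations": self.n_realizations,
            "n_used": self.n_used,
            "n_skipped": self.n_skipped,
            "median_rho_tp": med([p.rho_tp for p in self.points]),
            "median_rho_fn": med([p.rho_fn for p in self.points]),
            "median_ratio_nestedness": med([p.ratio_nestedness for p in self.points]),
            "median_ratio_excess": med([p.ratio_excess for p in self.points]),
            "frac_ratio_nestedness_gt1": self.frac_ratio_nestedness_gt1,
            "frac_ratio_excess_gt1": self.frac_ratio_excess_gt1,
            "significance_level": self.significance_level,
            "tp_more_nested": self.tp_more_nested,
            "tp_more_excess_nested": self.tp_more_excess_nested,
        }


class _SubsetBaselines:
    """ER baselines for subset matrices, cached by link count.

    Baselines are matched on the full empirical frame (R, C) with the
    subset's own link count.  The ensemble seed is derived from the base
    seed and the link count only, so identical subsets always meet the
    identical baseline regardless of realization order.
    """

    def __init__(self, R: int, C: int, n_graphs: int, seed: int):
        self.R, self.C, self.n_graphs, self.seed = R, C, n_graphs, int(seed)
        self._cache: dict[int, ERBaseline] = {}

    def __call__(self, L: int) -> ERBaseline:
        if L not in self._cache:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, self.R, self.C, L])
            )
            self._cache[L] = er_baseline_rho(
                self.R, self.C, L, self.n_graphs, rng
            )
        return self._cache[L]


def backbone_from_subsets(
    tp_matrix: np.ndarray,
    fn_matrix: np.ndarray,
    er_graphs: int = 10_000,
    seed: int = 0,
) -> BackbonePoint:
    """Backbone statistics for one explicit TP/FN pair of link sets.

    Both matrices live on the same R x C frame; all-zero rows/columns are
    dropped before normalization (the spectral radius is unaffected, the
    normalization bound is not).  ER baselines share the frame dimensions
    and use each subset's own link count.
    """
    tp = np.asarray(tp_matrix)
    fn = np.asarray(fn_matrix)
    if tp.shape != fn.shape:
        raise DimensionError("TP and FN matrices must share a frame")
    if not tp.any() or not fn.any():
        raise InputError("backbone undefined: empty TP or FN subset")
    baselines = _SubsetBaselines(tp.shape[0], tp.shape[1], er_graphs, seed)
    rho_tp = rho_normalized(tp)
    rho_fn = rho_normalized(fn)
    er_tp = baselines(int(tp.sum())).mean
    er_fn = baselines(int(fn.sum())).mean
    excess_tp = (rho_tp - er_tp) / (1.0 - er_tp)
    excess_fn = (rho_fn - er_fn) / (1.0 - er_fn)
    return BackbonePoint(
        rho_tp=rho_tp,
        rho_fn=rho_fn,
        ratio_nestedness=rho_tp / rho_fn,
        excess_tp=excess_tp,
        excess_fn=excess_fn,
        ratio_excess=excess_tp / excess_fn if excess_fn != 0 else float("inf"),
    )


def backbone_ratios(
    probs: LinkProbabilityMatrix,
    empirical: BipartiteNetwork,
    n_realizations: int = 1_000,
    er_graphs: int = 10_000,
    seed: int = 0,
    significance_level: float = 0.95,
) -> BackboneResult:
    """Ensemble test: are explained links more nested than missed links?

    Per realization the empirical links split into true positives and
    false negatives; realizations in which either subset is empty are
    skipped and counted.  Subset ER baselines are cached per link count
    and shared across realizations.
    """
    emp = empirical.incidence.astype(bool)
    ss = np.random.SeedSequence(seed)
    real_seed, er_seed = ss.spawn(2)
    reals = sample_realizations(
        probs, n_realizations, np.random.default_rng(real_seed)
    ).astype(bool)
    baselines = _SubsetBaselines(
        empirical.R, empirical.C, er_graphs, er_seed.generate_state(1)[0] >> 1
    )
    points: list[BackbonePoint] = []
    n_skipped = 0
    for real in reals:
        tp = real & emp
        fn = ~real & emp
        if not tp.any() or not fn.any():
            n_skipped += 1
            continue
        rho_tp = rho_normalized(tp)
        rho_fn = rho_normalized(fn)
        er_tp = baselines(int(tp.sum())).mean
        er_fn = baselines(int(fn.sum())).mean
        excess_tp = (rho_tp - er_tp) / (1.0 - er_tp)
        excess_fn = (rho_fn - er_fn) / (1.0 - er_fn)
        points.append(
            BackbonePoint(
                rho_tp=rho_tp,
                rho_fn=rho_fn,
                ratio_nestedness=rho_tp / rho_fn,
                excess_tp=excess_tp,
                excess_fn=excess_fn,
                ratio_excess=excess_tp / excess_fn if excess_fn != 0 else float("inf"),
            )
        )
    n_used = len(points)
    frac1 = frac2 = float("nan")
    if n_used:
        frac1 = sum(p.ratio_nestedness > 1 for p in points) / n_used
        frac2 = sum(p.ratio_excess > 1 for p in points) / n_used
    return BackboneResult(
        n_realizations=n_realizations,
        n_used=n_used,
        n_skipped=n_skipped,
        points=points,
        frac_ratio_nestedness_gt1=frac1,
        frac_ratio_excess_gt1=frac2,
        significance_level=significance_level,
    )
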