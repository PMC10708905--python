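"""Synthetic temporal interaction data with controlled phenology.

The generator emulates the structure of daily-resolved bipartite
interaction data (market transactions, pollinator visitations): each
actor gets a contiguous activity window inside the observation period —
onset uniform over the period, duration geometric with a configurable
mean, truncated at the period end — and is present on each day of its
window independently with probability ``daily_presence_prob``.  On every
day a row/column pair is copresent it interacts with probability
``p_true``, which makes the generated data follow the phenology model
exactly and enables parameter-recovery experiments (the fitted p should
match ``p_true``).

A tunable fraction of "preference" links can additionally be injected
between pairs from the lowest quartile of positive copresence, mimicking
interactions with partners that are not routinely available; these are
exactly the links the phenology model should miss.

Heterogeneous activity windows produce the skewed presence/copresence
distributions seen in real daily interaction data, with a right tail
that fattens as the aggregation window grows.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DimensionError, InputError
from .temporal_data import BipartiteNetwork, CopresenceMatrix, TemporalDataset

__all__ = [
    "PhenologySpec",
    "Phenologies",
    "EventGenerationInfo",
    "generate_phenologies",
    "generate_events",
    "generate_dataset",
    "true_copresence_matrix",
]


@dataclass(frozen=True)
class PhenologySpec:
    """Parameters of the synthetic temporal-interaction generator.

    Defaults describe a medium-sized system: 50 x 50 actors observed for
    120 days, activity windows with geometric mean duration 40 days,
    80% daily presence inside the window, and interaction probability
    0.3 per copresent day with no injected preference links.
    """

    n_rows: int = 50
    n_cols: int = 50
    n_days: int = 120
    mean_duration: float = 40.0
    daily_presence_prob: float = 0.8
    p_true: float = 0.3
    preference_fraction: float = 0.0
    start_date: datetime.date = datetime.date(2020, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_days < 1:
            raise InputError("actor counts and n_days must be >= 1")
        for name in ("daily_presence_prob", "p_true", "preference_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        if self.mean_duration < 1.0:
            raise InputError("mean_duration must be >= 1 day")
        if self.daily_presence_prob == 0.0:
            raise InputError("daily_presence_prob must be positive")

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "n_days": self.n_days,
            "mean_duration": self.mean_duration,
            "daily_presence_prob": self.daily_presence_prob,
            "p_true": self.p_true,
            "preference_fraction": self.preference_fraction,
            "start_date": self.start_date.isoformat(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhenologySpec":
        d = dict(d)
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = datetime.date.fromisoformat(d["start_date"])
        return cls(**d)

    def with_seed(self, seed: int) -> "PhenologySpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Phenologies:
    """Boolean presence calendars (actors x days) for both categories."""

    row_presence: np.ndarray
    col_presence: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def presence_sets(self) -> dict[str, set[int]]:
        out = {}
        for labels, pres in (
            (self.row_labels, self.row_presence),
            (self.col_labels, self.col_presence),
        ):
            for a, mask in zip(labels, pres):
                out[a] = set(np.flatnonzero(mask))
        return out


@dataclass(frozen=True)
class EventGenerationInfo:
    """Bookkeeping for one generated event list."""

    n_base_links: int
    n_preference_requested: int
    n_preference_injected: int
    n_preference_skipped: int
    injected_pairs: tuple[tuple[str, str], ...] = field(repr=False, default=())


def _sample_category(
    spec: PhenologySpec, n_actors: int, rng: np.random.Generator
) -> np.ndarray:
    """Presence calendars for one actor category; every actor >= 1 day."""
    pres = np.zeros((n_actors, spec.n_days), dtype=bool)
    pending = np.arange(n_actors)
    while pending.size:
        m = pending.size
        onset = rng.integers(0, spec.n_days, size=m)
        duration = rng.geometric(1.0 / spec.mean_duration, size=m)
        for row, o, d in zip(pending, onset, duration):
            end = min(o + d, spec.n_days)
            window = rng.random(end - o) < spec.daily_presence_prob
            pres[row, o:end] = window
        pending = pending[~pres[pending].any(axis=1)]
    return pres


def generate_phenologies(
    spec: PhenologySpec, rng: np.random.Generator | None = None
) -> Phenologies:
    """Draw activity windows and day-wise presence for every actor.

    Actors that would end up with zero active days are redrawn, so every
    actor is active at least once.  Reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    rows = _sample_category(spec, spec.n_rows, rng)
    cols = _sample_category(spec, spec.n_cols, rng)
    width = max(len(str(spec.n_rows)), len(str(spec.n_cols)))
    return Phenologies(
        row_presence=rows,
        col_presence=cols,
        row_labels=tuple(f"r{i + 1:0{width}d}" for i in range(spec.n_rows)),
        col_labels=tuple(f"c{j + 1:0{width}d}" for j in range(spec.n_cols)),
    )


def generate_events(
    phenologies: Phenologies,
    spec: PhenologySpec,
    rng: np.random.Generator | None = None,
) -> tuple[TemporalDataset, EventGenerationInfo]:
    """Emit interaction records from presence calendars.

    For each (row, column, day) copresence a record is emitted with
    probability ``p_true``.  Afterwards, ``preference_fraction`` times the
    number of realized base links gives the number of extra "preference"
    links injected between unlinked pairs from the lowest quartile of
    positive copresence; each injected pair receives a single record on a
    randomly chosen shared day.  Pairs without any shared day can never
    be injected; if the quartile offers fewer candidates than requested
    the shortfall is reported in the returned info, not raised.

    The returned dataset may be empty (p_true = 0 and nothing injected);
    downstream operations will then raise their usual empty-block errors.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    copresent = (
        phenologies.row_presence[:, None, :] & phenologies.col_presence[None, :, :]
    )
    events_mask = copresent & (rng.random(copresent.shape) < spec.p_true)
    n_pair = copresent.sum(axis=2)
    linked = events_mask.any(axis=2)
    n_base_links = int(linked.sum())

    requested = injected = skipped = 0
    injected_cells: list[tuple[int, int]] = []
    if spec.preference_fraction > 0.0:
        requested = int(round(spec.preference_fraction * n_base_links))
        candidates = np.argwhere(~linked & (n_pair >= 1))
        if candidates.size:
            cand_n = n_pair[candidates[:, 0], candidates[:, 1]]
            cutoff = np.quantile(n_pair[n_pair >= 1], 0.25)
            low = candidates[cand_n <= cutoff]
            take = min(requested, len(low))
            if take:
                chosen = low[rng.choice(len(low), size=take, replace=False)]
                for i, j in chosen:
                    shared = np.flatnonzero(copresent[i, j])
                    day = int(rng.choice(shared))
                    events_mask[i, j, day] = True
                    injected_cells.append((int(i), int(j)))
                injected = take
        skipped = requested - injected

    cells = np.argwhere(events_mask)
    events = pd.DataFrame(
        {
            "day": [
                spec.start_date + datetime.timedelta(days=int(d)) for d in cells[:, 2]
            ],
            "row_actor": [phenologies.row_labels[i] for i in cells[:, 0]],
            "col_actor": [phenologies.col_labels[j] for j in cells[:, 1]],
            "count": np.ones(len(cells), dtype=int),
        }
    )
    events = events.sort_values(
        ["day", "row_actor", "col_actor"], kind="stable"
    ).reset_index(drop=True)
    info = EventGenerationInfo(
        n_base_links=n_base_links,
        n_preference_requested=requested,
        n_preference_injected=injected,
        n_preference_skipped=skipped,
        injected_pairs=tuple(
            (phenologies.row_labels[i], phenologies.col_labels[j])
            for i, j in injected_cells
        ),
    )
    return TemporalDataset(events), info


def true_copresence_matrix(
    phenologies: Phenologies, network: BipartiteNetwork
) -> CopresenceMatrix:
    """Copresence counts from the generator's known presence calendars.

    Restricted to the actors present in ``network`` (those that
    interacted).  Unlike inference from interaction records — which
    misses days an actor was present but interacted with nobody and so
    *undercounts* copresence when interactions are sparse — the known
    calendars give the exact counts; parameter-recovery experiments
    should fit against these.  ``f`` is the full observation period.
    """
    labels_r = {a: i for i, a in enumerate(phenologies.row_labels)}
    labels_c = {a: j for j, a in enumerate(phenologies.col_labels)}
    try:
        ri = [labels_r[a] for a in network.row_labels]
        ci = [labels_c[a] for a in network.col_labels]
    except KeyError as exc:
        raise DimensionError(f"network actor {exc} not in phenologies") from None
    n = (
        phenologies.row_presence[ri].astype(np.int64)
        @ phenologies.col_presence[ci].T.astype(np.int64)
    )
    return CopresenceMatrix(n, phenologies.row_presence.shape[1])


def generate_dataset(
    spec: PhenologySpec,
) -> tuple[TemporalDataset, Phenologies, EventGenerationInfo]:
    """Phenologies and events in one call, all randomness from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    phen = generate_phenologies(spec, rng)
    data, info = generate_events(phen, spec, rng)
    return data, phen, info
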