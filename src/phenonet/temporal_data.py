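"""Daily-resolved interaction events and their aggregation into networks.

An interaction dataset is a list of dated records between two categories of
actors (rows: e.g. sellers or plants; columns: e.g. buyers or pollinators).
Records are aggregated into consecutive, nonoverlapping blocks; within a
block, multiple interactions between a pair count once, giving a binary
presence/absence incidence matrix that only includes actors which
interacted during the block.

Actor presence is inferred from the data: an actor not involved in any
interaction on a given day is assumed absent that day.  The number of
distinct observation days on which a pair of actors was jointly present
(its *copresence*) drives the phenology model in :mod:`phenonet.link_models`.
"""

from __future__ import annotations

import datetime
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DimensionError,
    EmptyBlockError,
    InputError,
    SchemaError,
)

__all__ = [
    "TemporalDataset",
    "BipartiteNetwork",
    "CopresenceMatrix",
    "CopresenceSummary",
    "PresenceMap",
    "read_daily_events",
    "aggregate_blocks",
    "build_network",
    "presence_days",
    "copresence_matrix",
    "presence_average_matrix",
    "copresence_summary",
]

#: canonical event-table column names
EVENT_COLUMNS = ("day", "row_actor", "col_actor", "count")


@dataclass(frozen=True)
class TemporalDataset:
    """Dated interaction records between two actor categories.

    ``events`` has columns ``day`` (datetime.date), ``row_actor`` (str),
    ``col_actor`` (str) and ``count`` (int >= 1).  Duplicate (day, pair)
    rows are preserved; multiplicity only disappears at binarization.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise SchemaError(f"event table missing column(s): {missing}")

    @property
    def observation_days(self) -> list[datetime.date]:
        """Sorted distinct days with at least one record."""
        return sorted(self.events["day"].unique())

    @property
    def n_records(self) -> int:
        return len(self.events)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.events)


@dataclass(frozen=True)
class BipartiteNetwork:
    """Binary R x C incidence matrix with actor labels.

    Rows and columns are restricted to actors with at least one interaction
    in the originating block, so every node has degree >= 1.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=np.int8)
        object.__setattr__(self, "incidence", inc)
        if inc.shape != (len(self.row_labels), len(self.col_labels)):
            raise DimensionError("incidence shape does not match labels")
        if not np.isin(inc, (0, 1)).all():
            raise InputError("incidence matrix must be binary")
        if inc.size and ((inc.sum(axis=1) == 0).any() or (inc.sum(axis=0) == 0).any()):
            raise InputError("every row and column must have degree >= 1")

    @property
    def R(self) -> int:
        return len(self.row_labels)

    @property
    def C(self) -> int:
        return len(self.col_labels)

    @property
    def L(self) -> int:
        """Number of links (1-entries)."""
        return int(self.incidence.sum())

    @property
    def fill(self) -> float:
        """Connectance L / (R*C)."""
        return self.L / (self.R * self.C)

    @property
    def row_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    @property
    def col_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0)


@dataclass(frozen=True)
class CopresenceMatrix:
    """Per-pair counts of shared active days within a window.

    ``n[i, j]`` is the number of days row actor i and column actor j were
    both active; ``f`` is the sampling period, i.e. the number of distinct
    observation days in the window (not calendar days: days without any
    record anywhere are treated as unsampled).
    """

    n: np.ndarray
    f: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.n, dtype=np.int64)
        object.__setattr__(self, "n", arr)
        if self.f < 1:
            raise InputError("sampling period f must be >= 1")
        if arr.min(initial=0) < 0 or arr.max(initial=0) > self.f:
            raise InputError("copresence counts must satisfy 0 <= n_ij <= f")

    def histogram(self) -> dict[int, int]:
        """Counts of pairs by copresence value, keys spanning 0..f."""
        counts = np.bincount(self.n.ravel(), minlength=self.f + 1)
        return {k: int(counts[k]) for k in range(self.f + 1)}


class PresenceMap(NamedTuple):
    """Day sets per actor, one mapping per category."""

    rows: dict[str, frozenset]
    cols: dict[str, frozenset]


@dataclass(frozen=True)
class CopresenceSummary:
    median: float
    mean: float
    max: int
    histogram: dict[int, int] = field(repr=False)


def read_daily_events(
    path,
    *,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> TemporalDataset:
    """Read a dated edge list from a delimited text file.

    Parameters
    ----------
    path
        TSV/CSV file (gzip transparently supported). Must contain a header.
    delimiter
        Field separator; default ``','`` for ``.csv``(.gz) files, else tab.
    columns
        Optional mapping from canonical names (``day``, ``row_actor``,
        ``col_actor``, ``count``) to the column names used in the file.

    The ``count`` column is optional and defaults to 1.
    """
    path = str(path)
    if delimiter is None:
        delimiter = "," if path.removesuffix(".gz").endswith(".csv") else "\t"
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: no records (empty file)") from None

    colmap = dict(columns) if columns else {}
    rename = {colmap.get(name, name): name for name in EVENT_COLUMNS}
    raw = raw.rename(columns=rename)
    for required in ("day", "row_actor", "col_actor"):
        if required not in raw.columns:
            raise SchemaError(f"{path}: missing column {required!r}")
    if len(raw) == 0:
        raise InputError(f"{path}: no records")

    parsed = pd.to_datetime(raw["day"], errors="coerce", format="ISO8601")
    if parsed.isna().any():
        # +2: one for the header line, one for 0-based positional index
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise InputError(f"{path}:{line}: unparseable date {raw['day'].iloc[line - 2]!r}")

    if "count" in raw.columns:
        counts = pd.to_numeric(raw["count"], errors="coerce")
        if counts.isna().any() or (counts < 1).any() or (counts % 1 != 0).any():
            raise InputError(f"{path}: counts must be integers >= 1")
        counts = counts.astype(int)
    else:
        counts = pd.Series(1, index=raw.index)

    events = pd.DataFrame(
        {
            "day": parsed.dt.date,
            "row_actor": raw["row_actor"].astype(str),
            "col_actor": raw["col_actor"].astype(str),
            "count": counts.to_numpy(),
        }
    )
    return TemporalDataset(events)


def _subset(data: TemporalDataset, mask: pd.Series) -> TemporalDataset:
    return TemporalDataset(data.events.loc[mask].reset_index(drop=True))


def aggregate_blocks(
    data: TemporalDataset,
    window: int | str | Sequence[tuple[datetime.date, datetime.date]],
) -> list[tuple[str, TemporalDataset]]:
    """Split records into consecutive, nonoverlapping time blocks.

    ``window`` is one of:

    * an integer *n* — consecutive blocks of *n* calendar days starting at
      the first observation day;
    * ``"month"`` — calendar-month blocks;
    * ``"full"`` — a single block containing every record;
    * a sequence of explicit ``(start, end)`` date ranges (inclusive),
      which must not overlap; records outside every range are dropped.

    Blocks with zero records are omitted.  Each record lands in exactly
    one block.
    """
    if data.n_records == 0:
        raise EmptyBlockError("cannot aggregate an empty dataset")
    days = pd.Series(data.events["day"])

    if window == "full":
        return [("full", data)]

    if window == "month":
        keys = days.map(lambda d: f"{d.year:04d}-{d.month:02d}")
        return [
            (label, _subset(data, keys == label))
            for label in sorted(keys.unique())
        ]

    if isinstance(window, int):
        if window < 1:
            raise ConfigurationError("block length must be >= 1 day")
        start = min(data.observation_days)
        idx = days.map(lambda d: (d - start).days // window)
        out = []
        for k in sorted(idx.unique()):
            lo = start + datetime.timedelta(days=int(k) * window)
            hi = lo + datetime.timedelta(days=window - 1)
            out.append((f"{lo.isoformat()}..{hi.isoformat()}", _subset(data, idx == k)))
        return out

    if isinstance(window, Iterable):
        ranges = [(pd.Timestamp(a).date(), pd.Timestamp(b).date()) for a, b in window]
        for lo, hi in ranges:
            if lo > hi:
                raise ConfigurationError(f"range {lo}..{hi} has start after end")
        ordered = sorted(ranges)
        for (_, hi1), (lo2, _) in zip(ordered, ordered[1:]):
            if lo2 <= hi1:
                raise ConfigurationError(f"ranges overlap at {lo2.isoformat()}")
        out = []
        for lo, hi in ordered:
            mask = days.map(lambda d: lo <= d <= hi)
            if mask.any():
                out.append((f"{lo.isoformat()}..{hi.isoformat()}", _subset(data, mask)))
        return out

    raise ConfigurationError(f"unrecognized window specification: {window!r}")


def build_network(block: TemporalDataset) -> BipartiteNetwork:
    """Binarize a block of records into a bipartite incidence matrix.

    An entry is 1 iff the pair interacted at least once in the block;
    multiplicities and counts are discarded.  Actors are ordered
    lexicographically for a deterministic layout.
    """
    if block.n_records == 0:
        raise EmptyBlockError("cannot build a network from an empty block")
    rows = tuple(sorted(block.events["row_actor"].unique()))
    cols = tuple(sorted(block.events["col_actor"].unique()))
    ri = {a: i for i, a in enumerate(rows)}
    ci = {a: j for j, a in enumerate(cols)}
    inc = np.zeros((len(rows), len(cols)), dtype=np.int8)
    inc[
        block.events["row_actor"].map(ri).to_numpy(),
        block.events["col_actor"].map(ci).to_numpy(),
    ] = 1
    return BipartiteNetwork(rows, cols, inc)


def presence_days(block: TemporalDataset) -> PresenceMap:
    """Infer per-actor activity day sets from the records of a block.

    An actor's presence set is exactly the set of days on which it appears
    in at least one record; a day with no interaction for that actor is
    treated as a day the actor was not around, even if others were active.
    """
    if block.n_records == 0:
        raise EmptyBlockError("cannot infer presence from an empty block")
    rows = {
        actor: frozenset(group)
        for actor, group in block.events.groupby("row_actor")["day"]
    }
    cols = {
        actor: frozenset(group)
        for actor, group in block.events.groupby("col_actor")["day"]
    }
    return PresenceMap(rows, cols)


def _presence_arrays(
    block: TemporalDataset, network: BipartiteNetwork
) -> tuple[np.ndarray, np.ndarray, int]:
    """Boolean presence matrices (actors x observation days) for a block."""
    pres = presence_days(block)
    missing = [a for a in network.row_labels if a not in pres.rows] + [
        a for a in network.col_labels if a not in pres.cols
    ]
    if missing:
        raise DimensionError(f"network actors absent from block: {missing}")
    days = {d: k for k, d in enumerate(block.observation_days)}
    f = len(days)
    rp = np.zeros((network.R, f), dtype=bool)
    cp = np.zeros((network.C, f), dtype=bool)
    for i, a in enumerate(network.row_labels):
        rp[i, [days[d] for d in pres.rows[a]]] = True
    for j, a in enumerate(network.col_labels):
        cp[j, [days[d] for d in pres.cols[a]]] = True
    return rp, cp, f


def copresence_matrix(
    block: TemporalDataset, network: BipartiteNetwork
) -> CopresenceMatrix:
    """Count shared active days for every (row, column) actor pair.

    ``n[i, j] = |presence(i) ∩ presence(j)|``; the sampling period ``f`` is
    the number of distinct observation days in the block.
    """
    rp, cp, f = _presence_arrays(block, network)
    n = rp.astype(np.int64) @ cp.T.astype(np.int64)
    return CopresenceMatrix(n, f)


def presence_average_matrix(
    block: TemporalDataset, network: BipartiteNetwork
) -> CopresenceMatrix:
    """Presence-model variant: average presence per pair, rounded up.

    Entry (i, j) is ceil((|presence(i)| + |presence(j)|) / 2), replacing
    the shared-day count of :func:`copresence_matrix`.
    """
    rp, cp, f = _presence_arrays(block, network)
    ri = rp.sum(axis=1)[:, None]
    cj = cp.sum(axis=1)[None, :]
    n = -((ri + cj) // -2)  # ceiling division
    return CopresenceMatrix(n, f)


def copresence_summary(N: CopresenceMatrix) -> CopresenceSummary:
    """Order statistics and histogram of the copresence distribution."""
    vals = N.n.ravel()
    if vals.size == 0:
        raise EmptyBlockError("empty copresence matrix")
    return CopresenceSummary(
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        max=int(vals.max()),
        histogram=N.histogram(),
    )
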