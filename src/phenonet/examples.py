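"""Small worked-example datasets built in code.

``toy_block()`` is a synthetic 3 x 3 actor, 6-day event list constructed
so that the inferred copresence histogram is {0: 1, 1: 2, 2: 4, 3: 2}
with L = 6 links and Z = 3 empty cells — the configuration whose
interaction-probability polynomial

    1 + 2 q + 4 q^2 + 2 q^3 = 3

has the root q ≈ 0.4656 (0.47 at two decimals), p ≈ 0.53.  The record
list itself is synthetic: it was found by randomized search over
presence calendars and is one of many event lists consistent with that
histogram.
"""

from __future__ import annotations

import datetime

import pandas as pd

from .temporal_data import TemporalDataset

__all__ = ["toy_block", "TOY_HISTOGRAM"]

#: copresence histogram of the toy block
TOY_HISTOGRAM = {0: 1, 1: 2, 2: 4, 3: 2}

# (day index 1..6, row actor, column actor); records cover every
# copresent day of each linked pair, so presence calendars are exactly
# recoverable from the records.
_TOY_RECORDS = [
    (1, "A", "x"), (3, "A", "x"),
    (1, "B", "x"), (3, "B", "x"), (6, "B", "x"),
    (1, "B", "z"), (4, "B", "z"),
    (3, "C", "x"), (5, "C", "x"), (6, "C", "x"),
    (5, "C", "y"), (6, "C", "y"),
    (2, "C", "z"), (4, "C", "z"),
]


def toy_block(start: datetime.date = datetime.date(2020, 1, 1)) -> TemporalDataset:
    """The 6-day, 3 x 3 worked-example block as a TemporalDataset.

    Presence calendars implied by the records (day indices 1..6):
    rows A {1,3}, B {1,3,4,6}, C {2,3,4,5,6}; columns x {1,3,5,6},
    y {5,6}, z {1,2,4}.  Linked pairs: (A,x), (B,x), (B,z), (C,x),
    (C,y), (C,z); the unlinked positive-copresence pairs are (A,z) and
    (B,y), and (A,y) never overlaps.
    """
    events = pd.DataFrame(
        {
            "day": [start + datetime.timedelta(days=d - 1) for d, _, _ in _TOY_RECORDS],
            "row_actor": [r for _, r, _ in _TOY_RECORDS],
            "col_actor": [c for _, _, c in _TOY_RECORDS],
            "count": 1,
        }
    )
    return TemporalDataset(events)
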