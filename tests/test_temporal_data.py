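"""Event parsing, aggregation, binarization, presence and copresence."""

import datetime
import gzip

import numpy as np
import pandas as pd
import pytest

from phenonet.exceptions import (
    ConfigurationError,
    DimensionError,
    EmptyBlockError,
    InputError,
    SchemaError,
)
from phenonet.io import (
    read_incidence_tsv,
    read_matrix_mtx,
    write_incidence_tsv,
    write_matrix_mtx,
)
from phenonet.temporal_data import (
    TemporalDataset,
    aggregate_blocks,
    build_network,
    copresence_matrix,
    copresence_summary,
    presence_average_matrix,
    presence_days,
    read_daily_events,
)

D = datetime.date


def make_dataset(rows):
    """rows: iterable of (iso_day, row_actor, col_actor)."""
    return TemporalDataset(
        pd.DataFrame(
            {
                "day": [D.fromisoformat(d) for d, _, _ in rows],
                "row_actor": [r for _, r, _ in rows],
                "col_actor": [c for _, _, c in rows],
                "count": 1,
            }
        )
    )


class TestReadDailyEvents:
    def test_parses_records_and_days(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text(
            "day\trow_actor\tcol_actor\n"
            "2020-01-01\tA\tx\n2020-01-02\tA\ty\n2020-01-03\tB\tx\n"
        )
        data = read_daily_events(f)
        assert data.n_records == 3
        assert data.observation_days == [D(2020, 1, 1), D(2020, 1, 2), D(2020, 1, 3)]

    def test_duplicate_records_same_day_preserved(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text(
            "day\trow_actor\tcol_actor\n2020-01-01\tA\tx\n2020-01-01\tA\tx\n"
        )
        data = read_daily_events(f)
        assert data.n_records == 2
        assert len(data.observation_days) == 1

    def test_header_only_is_an_error(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("day\trow_actor\tcol_actor\n")
        with pytest.raises(InputError, match="no records"):
            read_daily_events(f)

    def test_bad_date_names_line_number(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text(
            "day\trow_actor\tcol_actor\n2020-01-01\tA\tx\nnot-a-date\tB\ty\n"
        )
        with pytest.raises(InputError, match=":3"):
            read_daily_events(f)

    def test_missing_column_is_schema_error(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("day\trow_actor\n2020-01-01\tA\n")
        with pytest.raises(SchemaError, match="col_actor"):
            read_daily_events(f)

    def test_column_mapping_and_csv_and_gzip(self, tmp_path):
        f = tmp_path / "ev.csv.gz"
        with gzip.open(f, "wt") as fh:
            fh.write("date,seller,buyer,n\n2020-01-01,A,x,3\n")
        data = read_daily_events(
            f,
            columns={"day": "date", "row_actor": "seller",
                     "col_actor": "buyer", "count": "n"},
        )
        assert data.n_records == 1
        assert data.events["count"].iloc[0] == 3

    def test_nonpositive_count_rejected(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("day\trow_actor\tcol_actor\tcount\n2020-01-01\tA\tx\t0\n")
        with pytest.raises(InputError, match="count"):
            read_daily_events(f)


class TestAggregateBlocks:
    def test_fixed_seven_day_blocks(self):
        rows = [(f"2020-01-{d:02d}", "A", "x") for d in range(1, 15)]
        blocks = aggregate_blocks(make_dataset(rows), 7)
        assert len(blocks) == 2
        assert all(len(b.observation_days) == 7 for _, b in blocks)

    def test_full_period_is_identity(self):
        data = make_dataset([("2020-01-01", "A", "x"), ("2020-03-05", "B", "y")])
        blocks = aggregate_blocks(data, "full")
        assert len(blocks) == 1
        assert blocks[0][1].n_records == 2

    def test_calendar_month_partition(self):
        data = make_dataset([("2020-01-30", "A", "x"), ("2020-02-02", "A", "x")])
        blocks = aggregate_blocks(data, "month")
        assert [label for label, _ in blocks] == ["2020-01", "2020-02"]

    def test_no_record_lost_or_duplicated(self):
        rows = [(f"2020-01-{d:02d}", "A", "x") for d in range(1, 29, 3)]
        data = make_dataset(rows)
        blocks = aggregate_blocks(data, 5)
        assert sum(b.n_records for _, b in blocks) == data.n_records

    def test_explicit_ranges_and_overlap_error(self):
        data = make_dataset([("2020-01-05", "A", "x"), ("2020-02-05", "B", "y")])
        ranges = [(D(2020, 1, 1), D(2020, 1, 31)), (D(2020, 2, 1), D(2020, 2, 28))]
        assert len(aggregate_blocks(data, ranges)) == 2
        with pytest.raises(ConfigurationError, match="overlap"):
            aggregate_blocks(
                data,
                [(D(2020, 1, 1), D(2020, 2, 10)), (D(2020, 2, 1), D(2020, 2, 28))],
            )


class TestBuildNetwork:
    def test_multiple_interactions_binarized(self):
        data = make_dataset([("2020-01-0%d" % d, "A", "x") for d in range(1, 6)])
        net = build_network(data)
        assert net.incidence.tolist() == [[1]]
        assert net.L == 1

    def test_enumerated_small_block(self):
        data = make_dataset(
            [("2020-01-01", "A", "x"), ("2020-01-01", "A", "y"),
             ("2020-01-02", "B", "x")]
        )
        net = build_network(data)
        assert (net.R, net.C, net.L) == (2, 2, 3)

    def test_single_record_network(self):
        net = build_network(make_dataset([("2020-01-01", "A", "x")]))
        assert (net.R, net.C, net.L, net.fill) == (1, 1, 1, 1.0)

    def test_binarization_idempotent_under_deduplication(self, worked_block):
        deduped = TemporalDataset(
            worked_block.events.drop_duplicates(["day", "row_actor", "col_actor"])
        )
        a, b = build_network(worked_block), build_network(deduped)
        assert a.row_labels == b.row_labels and a.col_labels == b.col_labels
        assert np.array_equal(a.incidence, b.incidence)

    def test_empty_block_errors(self):
        empty = TemporalDataset(
            pd.DataFrame(columns=["day", "row_actor", "col_actor", "count"])
        )
        with pytest.raises(EmptyBlockError):
            build_network(empty)


class TestPresenceAndCopresence:
    def test_presence_sets_are_record_days(self):
        data = make_dataset(
            [("2020-01-01", "A", "x"), ("2020-01-02", "A", "y"),
             ("2020-01-05", "A", "x"), ("2020-01-03", "B", "y")]
        )
        pres = presence_days(data)
        assert pres.rows["A"] == {D(2020, 1, 1), D(2020, 1, 2), D(2020, 1, 5)}
        # B interacted only on day 3; A's activity on day 3 is irrelevant
        assert D(2020, 1, 3) not in pres.rows["A"]
        assert pres.cols["y"] == {D(2020, 1, 2), D(2020, 1, 3)}

    def test_copresence_is_set_intersection(self):
        # presence(A) = {1,2,3}, presence(x) = {2,3,6} via shared records
        data = make_dataset(
            [("2020-01-02", "A", "x"), ("2020-01-03", "A", "x"),
             ("2020-01-01", "A", "y"), ("2020-01-06", "B", "x")]
        )
        net = build_network(data)
        N = copresence_matrix(data, net)
        i, j = net.row_labels.index("A"), net.col_labels.index("x")
        assert N.n[i, j] == 2

    def test_worked_example_histogram(self, worked_copresence):
        assert worked_copresence.f == 6
        hist = worked_copresence.histogram()
        assert {k: v for k, v in hist.items() if v} == {0: 1, 1: 2, 2: 4, 3: 2}

    def test_interaction_implies_copresence(self, worked_block, worked_network,
                                            worked_copresence):
        assert (worked_copresence.n[worked_network.incidence == 1] >= 1).all()
        assert worked_copresence.n.max() <= worked_copresence.f

    def test_presence_average_rounds_up(self):
        # |presence(A)| = 3, |presence(x)| = 4 -> ceil(3.5) = 4
        rows = [("2020-01-01", "A", "x"), ("2020-01-02", "A", "x"),
                ("2020-01-03", "A", "x"), ("2020-01-04", "B", "x")]
        data = make_dataset(rows)
        net = build_network(data)
        Np = presence_average_matrix(data, net)
        i, j = net.row_labels.index("A"), net.col_labels.index("x")
        assert Np.n[i, j] == 4
        k = net.row_labels.index("B")
        # |presence(B)| = 1, |presence(x)| = 4 -> ceil(2.5) = 3
        assert Np.n[k, j] == 3

    def test_dimension_mismatch_rejected(self, worked_block):
        other = build_network(make_dataset([("2020-01-01", "Q", "w")]))
        with pytest.raises(DimensionError):
            copresence_matrix(worked_block, other)


class TestCopresenceSummary:
    def test_order_statistics(self):
        from phenonet.temporal_data import CopresenceMatrix

        N = CopresenceMatrix(np.array([[0, 1], [2, 4]]), f=5)
        s = copresence_summary(N)
        assert s.max == 4 and s.median == 1.5
        assert sorted(s.histogram) == [0, 1, 2, 3, 4, 5]

    def test_worked_example_max(self, worked_copresence):
        assert copresence_summary(worked_copresence).max == 3


class TestMatrixIO:
    def test_incidence_roundtrip_tsv_and_mtx(self, tmp_path, worked_network):
        write_incidence_tsv(worked_network, tmp_path / "inc.tsv")
        back = read_incidence_tsv(tmp_path / "inc.tsv")
        assert back.row_labels == worked_network.row_labels
        assert np.array_equal(back.incidence, worked_network.incidence)

        write_matrix_mtx(worked_network.incidence, tmp_path / "inc.mtx")
        assert np.array_equal(
            read_matrix_mtx(tmp_path / "inc.mtx"), worked_network.incidence
        )
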