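"""Preload and visit-log CSV parsing, validation, archiving, round-trips."""

from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

import fieldtrack as ft
from fieldtrack.preload_io import MAIN_LOG_NAME

from conftest import MONDAY, SATURDAY, TUESDAY, build_log


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadPreload:
    def test_parses_valid_rows(self, tmp_path):
        path = write(
            tmp_path, "preload.csv",
            "HHID,CLUSTER,LAT,LONG\nH001,CA,18.01,-66.61\nH002,CA,18.02,-66.62\n",
        )
        structures = ft.read_preload(path)
        assert [s.hhid for s in structures] == ["H001", "H002"]
        assert structures[0].lat == pytest.approx(18.01)
        assert structures[0].area_type is ft.AreaType.NEIGHBORHOOD

    def test_headers_case_and_order_insensitive(self, tmp_path):
        path = write(
            tmp_path, "p.csv", "long,lat,hhid,cluster\n-66.61,18.01,H001,CA\n"
        )
        (s,) = ft.read_preload(path)
        assert (s.hhid, s.lon) == ("H001", -66.61)

    def test_duplicate_hhid_named_in_error(self, tmp_path):
        path = write(
            tmp_path, "p.csv",
            "HHID,CLUSTER,LAT,LONG\nH001,CA,18.0,-66.6\nH001,CA,18.1,-66.7\n",
        )
        with pytest.raises(ft.DuplicateIDError, match="H001"):
            ft.read_preload(path)

    def test_out_of_range_latitude_reports_row(self, tmp_path):
        path = write(
            tmp_path, "p.csv",
            "HHID,CLUSTER,LAT,LONG\nH001,CA,18.0,-66.6\nH002,CA,95.0,-66.6\n",
        )
        with pytest.raises(ft.ValidationError, match="row 3"):
            ft.read_preload(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = write(tmp_path, "p.csv", "HHID,CLUSTER,LAT\nH001,CA,18.0\n")
        with pytest.raises(ft.SchemaError, match="LONG"):
            ft.read_preload(path)

    def test_area_type_map_applied(self, tmp_path):
        path = write(
            tmp_path, "p.csv", "HHID,CLUSTER,LAT,LONG\nH001,AP,18.0,-66.6\n"
        )
        (s,) = ft.read_preload(path, {"AP": ft.AreaType.APARTMENT})
        assert s.area_type is ft.AreaType.APARTMENT


class TestReadVisitLog:
    def test_groups_and_orders_by_visit(self, tmp_path):
        log = build_log([
            ("NO_ANSWER", "NO_ONE_HOME", MONDAY),
            ("CONTACT_MADE", "RECRUITED", TUESDAY),
        ])
        path = ft.write_visit_log({log.hhid: log}, tmp_path / "v.csv")
        loaded = ft.read_visit_log(path)
        assert set(loaded) == {"H001"}
        assert [r.visit for r in loaded["H001"].records] == [0, 1, 2]

    def test_gap_in_visit_numbers_is_integrity_error(self, tmp_path):
        header = ",".join(ft.preload_io.LOG_COLUMNS)
        rows = [
            "0,H001,CA,-66.6,18.0,0,,,,,,,",
            "0,H001,CA,-66.6,18.0,2,HOUSE,NO_ANSWER,NO_ONE_HOME,"
            "2018-04-02T09:00:00,,,AB",
        ]
        path = write(tmp_path, "v.csv", header + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(ft.IntegrityError, match="contiguous"):
            ft.read_visit_log(path)

    def test_disallowed_details_is_vocabulary_error(self, tmp_path):
        header = ",".join(ft.preload_io.LOG_COLUMNS)
        rows = [
            "0,H001,CA,-66.6,18.0,0,,,,,,,",
            "0,H001,CA,-66.6,18.0,1,HOUSE,NO_ANSWER,RECRUITED,"
            "2018-04-02T09:00:00,,,AB",
        ]
        path = write(tmp_path, "v.csv", header + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(ft.VocabularyError):
            ft.read_visit_log(path)

    def test_header_only_file_yields_empty_collection(self, tmp_path):
        path = write(tmp_path, "v.csv", ",".join(ft.preload_io.LOG_COLUMNS) + "\n")
        assert ft.read_visit_log(path) == {}


@st.composite
def household_logs(draw):
    n_hh = draw(st.integers(1, 5))
    logs = {}
    for i in range(n_hh):
        hhid = f"H{i:03d}"
        n_visits = draw(st.integers(0, 3))
        visits = []
        for v in range(n_visits):
            day = MONDAY if v == 0 else (TUESDAY if v == 1 else SATURDAY)
            status = draw(st.sampled_from(["NO_ANSWER", "CONTACT_MADE"]))
            details = draw(st.sampled_from(
                {"NO_ANSWER": ["NO_ONE_HOME", "INACCESSIBLE"],
                 "CONTACT_MADE": ["UNDECIDED", "RECRUITED"]}[status]
            ))
            fu = draw(st.sampled_from([None, SATURDAY]))
            visits.append((status, details, day, fu))
            if details == "RECRUITED":
                break
        logs[hhid] = build_log(visits, hhid=hhid)
    return logs


class TestRoundTripAndArchive:
    @settings(max_examples=25, deadline=None)
    @given(logs=household_logs())
    def test_write_read_round_trip_is_lossless(self, tmp_path_factory, logs):
        tmp = tmp_path_factory.mktemp("rt")
        path = ft.write_visit_log(logs, tmp / "v.csv")
        loaded = ft.read_visit_log(path)
        assert set(loaded) == set(logs)
        for hhid in logs:
            assert loaded[hhid].records == logs[hhid].records

    def test_archive_copy_is_byte_identical(self, tmp_path):
        log = build_log([("NO_ANSWER", "NO_ONE_HOME", MONDAY)])
        main, archive = ft.save_with_archive(
            {log.hhid: log}, tmp_path, date(2018, 4, 2)
        )
        assert main.name == MAIN_LOG_NAME
        assert archive.name == "visits_2018-04-02.csv"
        assert main.read_bytes() == archive.read_bytes()

    def test_same_date_resave_keeps_one_snapshot(self, tmp_path):
        log = build_log()
        ft.save_with_archive({log.hhid: log}, tmp_path, date(2018, 4, 2))
        log2 = build_log([("NO_ANSWER", "NO_ONE_HOME", MONDAY)])
        _, archive = ft.save_with_archive(
            {log2.hhid: log2}, tmp_path, date(2018, 4, 2)
        )
        snapshots = list((tmp_path / "archive").iterdir())
        assert [p.name for p in snapshots] == ["visits_2018-04-02.csv"]
        assert archive.read_bytes() == (tmp_path / MAIN_LOG_NAME).read_bytes()

    def test_other_date_snapshots_untouched(self, tmp_path):
        log = build_log()
        _, first = ft.save_with_archive({log.hhid: log}, tmp_path, date(2018, 4, 2))
        original = first.read_bytes()
        log2 = build_log([("NO_ANSWER", "NO_ONE_HOME", MONDAY)])
        ft.save_with_archive({log2.hhid: log2}, tmp_path, date(2018, 4, 3))
        assert first.read_bytes() == original

    def test_unwritable_target_raises_and_leaves_main_file_intact(self, tmp_path):
        log = build_log()
        ft.save_with_archive({log.hhid: log}, tmp_path, date(2018, 4, 2))
        before = (tmp_path / MAIN_LOG_NAME).read_bytes()
        log2 = build_log([("NO_ANSWER", "NO_ONE_HOME", MONDAY)])
        with pytest.raises(OSError):
            # a plain file is not a valid base directory
            ft.save_with_archive({log2.hhid: log2},
                                 tmp_path / MAIN_LOG_NAME, date(2018, 4, 3))
        with pytest.raises(OSError):
            ft.save_with_archive({log2.hhid: log2},
                                 tmp_path / "missing", date(2018, 4, 3))
        assert (tmp_path / MAIN_LOG_NAME).read_bytes() == before


class TestEpiInfoLinkKey:
    def test_identity_and_deterministic(self):
        assert ft.epiinfo_link_key("H001") == "H001"
        assert ft.epiinfo_link_key("H001") == ft.epiinfo_link_key("H001")

    def test_empty_hhid_rejected(self):
        with pytest.raises(ft.ValidationError):
            ft.epiinfo_link_key("")
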