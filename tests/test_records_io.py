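"""Round-trip and validation behaviour of the delimited-text readers/writers."""

from __future__ import annotations

from collections import Counter
from datetime import datetime

import pytest

from painvol.features import extract_features, feature_names
from painvol.cohort import build_windows
from painvol.records_io import (
    RECORDS_DIALECT,
    USERS_DIALECT,
    RECORD_COLUMNS,
    USER_COLUMNS,
    Medication,
    PainRecord,
    UserProfile,
    read_feature_matrix,
    read_records,
    read_users,
    write_feature_matrix,
    write_records,
    write_users,
)
from painvol.synthetic_data import GeneratorConfig, generate_cohort


def _users_file(tmp_path, rows):
    path = tmp_path / "users.txt"
    lines = [USERS_DIALECT, "|".join(USER_COLUMNS), *rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _records_file(tmp_path, rows):
    path = tmp_path / "records.txt"
    lines = [RECORDS_DIALECT, "|".join(RECORD_COLUMNS), *rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


class TestUsersIO:
    def test_round_trip_is_identity(self, tmp_path):
        users, _, _ = generate_cohort(GeneratorConfig(n_users=50, seed=3))
        path = tmp_path / "u.txt"
        write_users(users, path)
        assert read_users(path) == users

    def test_empty_gender_maps_to_unknown(self, tmp_path):
        path = _users_file(tmp_path, ["u1||43|||"])
        (user,) = read_users(path)
        assert user.gender == "unknown"

    def test_unparseable_age_maps_to_unknown(self, tmp_path):
        path = _users_file(tmp_path, ["u1|female|forty|||"])
        (user,) = read_users(path)
        assert user.age_at_first_record is None

    def test_header_only_file_gives_empty_list(self, tmp_path):
        assert read_users(_users_file(tmp_path, [])) == []

    def test_duplicate_user_id_raises_with_line_number(self, tmp_path):
        path = _users_file(tmp_path, ["u1|male|30|||", "u1|male|30|||"])
        with pytest.raises(ValueError, match="line 4.*duplicate"):
            read_users(path)

    def test_malformed_row_names_line_number(self, tmp_path):
        path = _users_file(tmp_path, ["u1|male|30||"])
        with pytest.raises(ValueError, match="line 3"):
            read_users(path)

    def test_row_order_preserved(self, tmp_path):
        rows = [f"u{i}|female|{20 + i}|||" for i in (5, 1, 9)]
        users = read_users(_users_file(tmp_path, rows))
        assert [u.user_id for u in users] == ["u5", "u1", "u9"]


class TestRecordsIO:
    def test_round_trip_preserves_multiset(self, tmp_path):
        _, records, _ = generate_cohort(GeneratorConfig(n_users=10, seed=4))
        records = records[:500]
        path = tmp_path / "r.txt"
        write_records(records, path)
        assert Counter(read_records(path)) == Counter(records)

    def test_multivalued_field_parsing(self, tmp_path):
        path = _records_file(
            tmp_path, ["u1|2023-01-01T08:00:00|7|head;neck||||||||chronic|"]
        )
        (rec,) = read_records(path)
        assert rec.severity == 7
        assert rec.locations == {"head", "neck"}
        assert rec.pain_type == "chronic"
        assert rec.pain_duration is None

    def test_severity_out_of_range_raises(self, tmp_path):
        path = _records_file(tmp_path, ["u1|2023-01-01T08:00:00|11|||||||||c|"])
        with pytest.raises(ValueError, match="line 3.*severity"):
            read_records(path)

    def test_unknown_token_raises_naming_token(self, tmp_path):
        path = _records_file(
            tmp_path, ["u1|2023-01-01T08:00:00|5|knuckle||||||||c|"]
        )
        with pytest.raises(ValueError, match="knuckle"):
            read_records(path)

    def test_output_order_independent_of_row_order(self, tmp_path):
        rows = [
            "u2|2023-01-03T08:00:00|5|||||||||c|",
            "u1|2023-01-05T08:00:00|4|||||||||c|",
            "u1|2023-01-02T08:00:00|3|||||||||c|",
        ]
        first = read_records(_records_file(tmp_path, rows))
        second = read_records(_records_file(tmp_path, rows[::-1]))
        assert first == second
        assert [(r.user_id, r.timestamp.day) for r in first] == [
            ("u1", 2), ("u1", 5), ("u2", 3),
        ]

    def test_timestamp_ties_warn_and_keep_file_order(self, tmp_path):
        rows = [
            "u1|2023-01-02T08:00:00|3|head||||||||c|",
            "u1|2023-01-02T08:00:00|9|neck||||||||c|",
        ]
        with pytest.warns(UserWarning, match="ambiguous"):
            records = read_records(_records_file(tmp_path, rows))
        assert [r.severity for r in records] == [3, 9]


class TestFeatureMatrixIO:
    @pytest.fixture()
    def vectors(self, small_cohort, small_dataset):
        users, records, _ = small_cohort
        windows = build_windows(records)
        by_id = {u.user_id: u for u in users}
        thr = small_dataset.classification.threshold
        uids = small_dataset.eligible[:3]
        return [
            extract_features(by_id[u], windows[u].predictor, thr) for u in uids
        ]

    def test_shape_is_users_by_132_columns(self, tmp_path, vectors):
        path = tmp_path / "fm.csv"
        write_feature_matrix(vectors, ["low", "high", "low"], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0].split(",") == ["user_id", *feature_names(), "label"]

    def test_round_trip_full_precision(self, tmp_path, vectors):
        path = tmp_path / "fm.csv"
        write_feature_matrix(vectors, ["low", "high", "low"], path)
        frame = read_feature_matrix(path)
        for vec in vectors:
            row = frame.loc[vec.user_id]
            for name, value in vec.to_series().items():
                assert row[name] == value

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "fm.csv"
        write_feature_matrix([], [], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert read_feature_matrix(path).empty

    def test_schema_mismatch_raises(self, tmp_path, vectors):
        class Rogue:
            user_id = "ux"

            def to_series(self):
                import pandas as pd

                return pd.Series({"alien": 1.0})

        with pytest.raises(ValueError, match="schema"):
            write_feature_matrix([vectors[0], Rogue()], ["low", "low"], tmp_path / "x.csv")


class TestDomainTypes:
    def test_severity_must_be_integer_in_range(self):
        with pytest.raises(ValueError):
            PainRecord("u1", datetime(2023, 1, 1), 11)
        with pytest.raises(ValueError):
            PainRecord("u1", datetime(2023, 1, 1), -1)

    def test_vocabulary_tokens_validated_at_construction(self):
        with pytest.raises(ValueError, match="elbowz"):
            PainRecord(
                "u1", datetime(2023, 1, 1), 5, locations=frozenset({"elbowz"})
            )

    def test_unknown_states_are_explicit(self):
        u = UserProfile("u1")
        assert u.gender == "unknown"
        assert u.age_at_first_record is None

    def test_other_gender_representable(self):
        assert UserProfile("u1", gender="other").gender == "other"

    def test_medication_round_trips_in_users_file(self, tmp_path):
        u = UserProfile(
            "u1",
            gender="male",
            medications=(Medication("gabapentin", ("anticonvulsants",)),
                         Medication("ibuprofen", ())),
        )
        path = tmp_path / "u.txt"
        write_users([u], path)
        assert read_users(path) == [u]
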