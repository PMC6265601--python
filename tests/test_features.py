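"""The 130-feature extraction: schema identity, binning rules, clinical flags."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from painvol.cohort import ObservationWindow, build_windows
from painvol.features import (
    categorize_age,
    categorize_n_conditions,
    categorize_severity,
    compute_trend_change,
    count_flags,
    extract_features,
    feature_names,
    feature_schema,
    flag_mental_health,
    flag_neuropathic,
)
from painvol.records_io import PainRecord, UserProfile

T0 = datetime(2023, 6, 1, 10, 0)


def _rec(days, severity=5, **kwargs):
    kwargs = {k: frozenset(v) for k, v in kwargs.items()}
    return PainRecord("u1", T0 + timedelta(days=days), severity, **kwargs)


def _window(records):
    return ObservationWindow(
        "u1", "predictor", T0, T0 + timedelta(days=30), tuple(records)
    )


@pytest.fixture()
def plain_window():
    return _window([_rec(d, s) for d, s in zip((0, 2, 5, 9, 14), (3, 4, 4, 3, 5))])


class TestSchema:
    def test_canonical_names_are_130_and_stable(self):
        names = feature_names()
        assert len(names) == 130
        assert len(set(names)) == 130
        assert names == feature_names()

    def test_schema_blocks_have_documented_widths(self):
        schema = feature_schema()
        assert len(schema) == 130
        widths = schema.groupby("block").size().to_dict()
        assert widths["descriptors"] == 64
        assert widths["factors"] == 43
        assert widths["medications"] == 5

    def test_every_synthetic_user_yields_130_features(self, small_cohort, small_dataset):
        X = small_dataset.X
        assert X.shape == (len(small_dataset.eligible), 130)
        assert list(X.columns) == feature_names()

    def test_extraction_is_pure(self, plain_window):
        profile = UserProfile("u1", gender="female", age_at_first_record=44)
        a = extract_features(profile, plain_window, 1.6).to_series()
        b = extract_features(profile, plain_window, 1.6).to_series()
        assert a.equals(b)

    def test_all_missing_profile_maps_to_unknowns_not_errors(self, plain_window):
        profile = UserProfile("u1")  # no gender, age, conditions, medications
        vec = extract_features(profile, plain_window, 1.6)
        assert vec.gender_cat == "unknown"
        assert vec.age_cat == "unknown"
        assert vec.n_conditions_cat == "unknown"
        flags = (vec.condition_flags + vec.descriptor_flags + vec.factor_flags
                 + vec.medication_flags)
        assert len(flags) == 117
        assert set(flags) == {0}

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_features(UserProfile("u1"), _window([]), 1.6)

    def test_active_days_bounded_by_records_and_month(self, small_cohort, small_dataset):
        X = small_dataset.X
        assert (X["n_active_days"] <= X["n_records"]).all()
        assert (X["n_active_days"] <= 30).all()


class TestBinning:
    @pytest.mark.parametrize(
        ("age", "expected"),
        [
            (None, "unknown"),
            (1, "(0,20]"),
            (20, "(0,20]"),
            (21, "(20,30]"),
            (70, "(60,70]"),
            (71, ">70"),
            (99, ">70"),
        ],
    )
    def test_age_bins_lower_exclusive_upper_inclusive(self, age, expected):
        assert categorize_age(age) == expected

    def test_nonpositive_known_age_rejected(self):
        with pytest.raises(ValueError):
            categorize_age(0)

    @pytest.mark.parametrize(
        ("mean", "expected"),
        [(0.0, "mild"), (3.99, "mild"), (4.0, "moderate"), (7.0, "moderate"),
         (7.01, "severe"), (10.0, "severe")],
    )
    def test_severity_group_boundaries(self, mean, expected):
        assert categorize_severity(mean) == expected

    @pytest.mark.parametrize(
        ("n", "expected"), [(0, "unknown"), (1, "1"), (3, "3"), (4, ">3")]
    )
    def test_condition_count_bins(self, n, expected):
        assert categorize_n_conditions(n) == expected

    def test_mean_3_8_is_mild(self, plain_window):
        vec = extract_features(UserProfile("u1"), plain_window, 1.6)
        assert vec.severity_mean == pytest.approx(3.8)
        assert vec.severity_group == "mild"


class TestTrend:
    def test_perfect_line_returns_total_rise(self):
        records = [_rec(3 * i, severity=i) for i in range(11)]  # 0..10 linearly
        assert compute_trend_change(records) == pytest.approx(10.0)

    def test_constant_severities_give_zero(self):
        records = [_rec(i, severity=6) for i in range(10)]
        assert compute_trend_change(records) == pytest.approx(0.0)

    def test_coincident_timestamps_give_zero(self):
        records = [_rec(0, severity=s) for s in (2, 8, 5)]
        assert compute_trend_change(records) == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(13)
        days = np.sort(rng.uniform(0, 29, size=12))
        sev = rng.integers(0, 11, size=12)
        records = [_rec(float(d), int(s)) for d, s in zip(days, sev)]
        x = days - days.mean()
        slope = float((x * (sev - sev.mean())).sum() / (x * x).sum())
        expected = slope * (days.max() - days.min())
        assert compute_trend_change(records) == pytest.approx(expected)


class TestClinicalFlags:
    def test_two_qualifying_characteristics_in_one_record(self):
        assert flag_neuropathic([_rec(0, characteristics={"burning", "numbness"})]) == 1

    def test_qualifying_items_split_across_records_do_not_fire(self):
        records = [
            _rec(0, characteristics={"burning"}),
            _rec(1, characteristics={"numbness"}),
        ]
        assert flag_neuropathic(records) == 0

    def test_aggravating_factor_counts_toward_neuropathic(self):
        rec = _rec(0, characteristics={"burning"},
                   aggravating_factors={"light touch or clothing"})
        assert flag_neuropathic([rec]) == 1

    def test_single_item_insufficient(self):
        assert flag_neuropathic([_rec(0, characteristics={"burning"})]) == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"symptoms": {"anxiety"}},
            {"symptoms": {"depression"}},
            {"aggravating_factors": {"stress"}},
            {"aggravating_factors": {"negative mood"}},
        ],
    )
    def test_any_single_mental_health_item_fires(self, kwargs):
        assert flag_mental_health([_rec(0, **kwargs)]) == 1

    def test_no_qualifying_items_anywhere(self):
        records = [_rec(0, symptoms={"fever"}), _rec(1, aggravating_factors={"noise"})]
        assert flag_mental_health(records) == 0


class TestFlagBlocks:
    def test_descriptor_block_width(self):
        records = [_rec(0, locations={"head"}, symptoms={"fever"})]
        widths = [len(count_flags(records, v))
                  for v in ("locations", "symptoms", "characteristics", "environments")]
        assert widths == [24, 20, 13, 7]
        assert sum(widths) == 64

    def test_factor_block_width(self):
        records = [_rec(0)]
        widths = [len(count_flags(records, v))
                  for v in ("aggravating_factors", "alleviating_factors",
                            "ineffective_factors")]
        assert widths == [15, 14, 14]
        assert sum(widths) == 43

    def test_presence_is_window_level_union(self):
        records = [_rec(0, locations={"head"}), _rec(1, locations={"neck"})]
        flags = count_flags(records, "locations")
        assert sum(flags) == 2

    def test_empty_window_gives_zero_vector(self):
        assert set(count_flags([], "symptoms")) == {0}

    def test_medication_flag_requires_record_attachment(self, small_cohort):
        from painvol.records_io import Medication

        profile = UserProfile(
            "u1", medications=(Medication("gabapentin", ("anticonvulsants",)),)
        )
        # profile-listed but never attached to a record: no flag
        w1 = _window([_rec(0), _rec(1)])
        v1 = extract_features(profile, w1, 1.6)
        assert set(v1.medication_flags) == {0}
        # attached to a record in the window: flag fires
        rec = PainRecord(
            "u1", T0 + timedelta(days=2), 5,
            medications_used=frozenset({("gabapentin", "effective")}),
        )
        v2 = extract_features(profile, _window([_rec(0), rec]), 1.6)
        assert v2.medication_flags[2] == 1  # anticonvulsants position
        assert sum(v2.medication_flags) == 1
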