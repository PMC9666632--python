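"""Weekly featurization, categorical encoding, and standardization."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpaprank import (
    FeatureSchema,
    Standardizer,
    classify_presence,
    classify_severity,
    compute_weekly_features,
    segment_weeks,
    weekly_mode,
)
from cpaprank.features import PRESENCE_LEVELS, SEVERITY_LEVELS
from cpaprank.records import WeekWindow
from conftest import build_log


def week_of(usages, physio=None, mode="auto"):
    log = build_log(usages, physio=physio, mode=mode)
    return WeekWindow(log.patient_id, 1, log.cpap_start, log.records)


class TestDailyClassification:
    @pytest.mark.parametrize(
        "ahi,expected",
        [
            (0.0, "Normal"),
            (4.9, "Normal"),
            (5.0, "Mild"),
            (14.9, "Mild"),
            (15.0, "Moderate"),
            (30.0, "Severe"),
            (47.3, "Severe"),  # typical untreated-OSAS clinic mean
        ],
    )
    def test_severity_bands_inclusive_upward(self, ahi, expected):
        assert classify_severity(ahi) == expected

    @pytest.mark.parametrize(
        "ai,expected", [(0.0, "Normal"), (4.99, "Normal"), (5.0, "OSAS")]
    )
    def test_presence_threshold_at_five(self, ai, expected):
        assert classify_presence(ai) == expected


class TestWeeklyMode:
    def test_majority_wins(self):
        assert weekly_mode(["Mild", "Mild", "Severe"], SEVERITY_LEVELS) == "Mild"

    def test_tie_breaks_toward_more_abnormal(self):
        assert weekly_mode(["Mild", "Severe"], SEVERITY_LEVELS) == "Severe"
        assert weekly_mode(["Normal", "OSAS"], PRESENCE_LEVELS) == "OSAS"

    def test_unanimous_week(self):
        assert weekly_mode(["Normal"] * 7, SEVERITY_LEVELS) == "Normal"

    def test_no_valid_days_gives_missing(self):
        assert weekly_mode([], SEVERITY_LEVELS) is None
        assert weekly_mode([None, None], SEVERITY_LEVELS) is None

    def test_matches_bruteforce_count_on_all_short_sequences(self):
        # every sequence of length <= 7 over the four severity levels
        for length in range(1, 8):
            for seq in itertools.product(SEVERITY_LEVELS, repeat=length):
                got = weekly_mode(list(seq), SEVERITY_LEVELS)
                counts = Counter(seq)
                best = max(counts.values())
                tied = {v for v, c in counts.items() if c == best}
                assert got in tied
                assert all(
                    SEVERITY_LEVELS.index(got) >= SEVERITY_LEVELS.index(v) for v in tied
                )


class TestComputeWeeklyFeatures:
    def test_constant_week(self):
        f = compute_weekly_features(week_of([300] * 7), sex="male")
        assert f.pct_days_over_4h == 100.0
        assert f.mean_usage == 300.0
        assert f.sd_usage == 0.0
        assert f.total_usage == 2100.0

    def test_partial_usage_week(self):
        f = compute_weekly_features(week_of([250, 250, 250, 250, 250, 0, 0]), sex="male")
        assert f.pct_days_used == pytest.approx(100 * 5 / 7)
        assert f.pct_days_unused == pytest.approx(100 * 2 / 7)
        assert f.pct_days_over_4h == pytest.approx(100 * 5 / 7)
        assert f.total_usage == 1250.0

    def test_leak_statistics_over_valid_nights_only(self):
        physio = {
            0: (0.1, 1.0, 2.0, 8.0),
            1: (0.1, 1.0, 2.0, 8.0),
            2: (0.3, 1.0, 2.0, 8.0),
        }
        f = compute_weekly_features(week_of([300, 300, 300, 0, 0, 0, 0], physio), "male")
        assert f.mean_leak == pytest.approx(0.5 / 3)
        # population-SD convention
        assert f.sd_leak == pytest.approx(np.std([0.1, 0.1, 0.3]))

    def test_short_nights_excluded_from_physiology_not_usage(self):
        from cpaprank import apply_short_night_filter

        physio = {0: (0.1, 1.0, 2.0, 8.0), 1: (0.9, 9.0, 9.0, 8.0)}
        log = apply_short_night_filter(build_log([300, 20, 0, 0, 0, 0, 0], physio=physio))
        window = WeekWindow(log.patient_id, 1, log.cpap_start, log.records)
        f = compute_weekly_features(window, "male")
        assert f.mean_leak == pytest.approx(0.1)  # short night's leak ignored
        assert f.mean_usage == pytest.approx(320 / 7)  # but its usage counted

    def test_pressure_features_need_auto_mode(self):
        physio = {0: (0.1, 1.0, 2.0, None)}
        f = compute_weekly_features(
            week_of([300, 0, 0, 0, 0, 0, 0], physio, mode="fixed"), "male"
        )
        assert f.mean_pressure is None and f.sd_pressure is None

    def test_weekly_classes_from_daily_votes(self):
        physio = {i: (0.1, 6.0, 20.0, 8.0) for i in range(4)}
        physio.update({i: (0.1, 1.0, 2.0, 8.0) for i in range(4, 7)})
        f = compute_weekly_features(week_of([300] * 7, physio), "male")
        assert f.weekly_severity == "Moderate"  # 4 Moderate vs 3 Normal days
        assert f.weekly_presence == "OSAS"  # 4 OSAS vs 3 Normal days

    @given(
        usage=st.lists(
            st.floats(min_value=0, max_value=700, allow_nan=False), min_size=7, max_size=7
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_usage_identities(self, usage):
        f = compute_weekly_features(week_of(usage), sex="male")
        assert f.pct_days_used + f.pct_days_unused == pytest.approx(100.0)
        assert f.total_usage == pytest.approx(7 * f.mean_usage)
        assert f.pct_days_over_4h <= f.pct_days_used + 1e-12
        assert f.sd_usage >= 0

    @given(
        usage=st.lists(
            st.floats(min_value=1, max_value=700, allow_nan=False), min_size=7, max_size=7
        ),
        perm=st.permutations(list(range(7))),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_of_night_order(self, usage, perm):
        schema = FeatureSchema()
        f1 = compute_weekly_features(week_of(usage), sex="male")
        f2 = compute_weekly_features(week_of([usage[i] for i in perm]), sex="male")
        assert np.allclose(schema.encode(f1), schema.encode(f2), equal_nan=True)


class TestEncoding:
    schema = FeatureSchema()

    def features(self, **overrides):
        base = dict(
            sex="male",
            cpap_mode="fixed",
            pct_days_over_4h=100.0,
            pct_days_used=100.0,
            pct_days_unused=0.0,
            mean_usage=300.0,
            sd_usage=10.0,
            total_usage=2100.0,
            mean_leak=0.1,
            sd_leak=0.05,
            mean_ai=1.0,
            sd_ai=0.5,
            mean_ahi=2.0,
            sd_ahi=0.5,
            mean_pressure=None,
            sd_pressure=None,
            weekly_severity="Normal",
            weekly_presence="Normal",
        )
        base.update(overrides)
        from cpaprank import WeeklyFeatures

        return WeeklyFeatures(**base)

    def test_indicator_layout(self):
        v = self.schema.encode(
            self.features(sex="female", cpap_mode="auto", weekly_severity="Severe",
                          weekly_presence="OSAS")
        )
        cols = self.schema.columns
        get = dict(zip(cols, v))
        assert get["sex_female"] == 1.0 and get["cpap_mode_auto"] == 1.0
        assert [get[f"severity_{l.lower()}"] for l in SEVERITY_LEVELS] == [0, 0, 0, 1]
        assert get["presence_normal"] == 0.0

    def test_sex_changes_exactly_one_column(self):
        a = self.schema.encode(self.features(sex="male"))
        b = self.schema.encode(self.features(sex="female"))
        diff = ~np.isclose(a, b) & ~(np.isnan(a) & np.isnan(b))
        assert diff.sum() == 1

    def test_decode_round_trip_on_categorical_labels(self):
        for sex, mode, sev, pres in itertools.product(
            ("male", "female"), ("auto", "fixed"), SEVERITY_LEVELS, PRESENCE_LEVELS
        ):
            f = self.features(
                sex=sex, cpap_mode=mode, weekly_severity=sev, weekly_presence=pres
            )
            got = self.schema.decode_categoricals(self.schema.encode(f))
            assert got == {
                "sex": sex,
                "cpap_mode": mode,
                "weekly_severity": sev,
                "weekly_presence": pres,
            }

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            self.schema.encode(self.features(weekly_severity="Extreme"))

    def test_ordinal_severity_option(self):
        schema = FeatureSchema(severity_encoding="ordinal")
        v = schema.encode(self.features(weekly_severity="Moderate"))
        assert dict(zip(schema.columns, v))["severity_ordinal"] == 2.0
        assert schema.dim == self.schema.dim - 3

    def test_missing_classes_encode_as_nan(self):
        v = self.schema.encode(
            self.features(weekly_severity=None, weekly_presence=None)
        )
        get = dict(zip(self.schema.columns, v))
        assert np.isnan(get["severity_normal"]) and np.isnan(get["presence_normal"])


class TestStandardizer:
    def test_column_1_2_3_maps_to_unit_scores(self):
        z = Standardizer().fit_transform(np.array([[1.0], [2.0], [3.0]]))
        assert z[:, 0] == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_training_columns_become_mean0_sd1(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(40, 6))
        Z = Standardizer().fit_transform(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        Z = Standardizer().fit_transform(X)
        assert np.all(Z[:, 0] == 0.0)

    def test_missing_values_map_to_training_mean(self):
        X = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]])
        s = Standardizer().fit(X)
        z = s.transform(np.array([np.nan, 5.0]))
        assert z[0] == 0.0  # imputed at the standardized training mean

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            Standardizer().transform(np.zeros(3))

    @given(
        data=st.lists(
            st.lists(st.floats(-100, 100), min_size=3, max_size=3),
            min_size=2,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invertibility(self, data):
        X = np.asarray(data)
        s = Standardizer().fit(X)
        back = s.inverse_transform(s.transform(X))
        varying = s.sigma > 0
        assert np.allclose(back[:, varying], X[:, varying], atol=1e-10)
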