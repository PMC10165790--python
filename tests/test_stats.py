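"""In-brace correction, Spearman correlation, strength bins and tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torsofit.displacement import SEGMENT_CODES, SegmentPeaks
from torsofit.stats import (
    PEAK_FEATURES,
    PatientRecord,
    classify_strength,
    compute_ibc,
    correlation_table,
    spearman_rho,
    summarize_cohort,
)


def _rank_formula(x, y):
    """Independent tie-free oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1))."""
    xr = np.argsort(np.argsort(x))
    yr = np.argsort(np.argsort(y))
    d = xr - yr
    n = len(x)
    return 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))


class TestComputeIbc:
    @pytest.mark.parametrize(
        "pre,inb,expected",
        [(40.0, 30.0, 25.0), (30.5, 30.5, 0.0), (38.4, 32.2, 100 * 6.2 / 38.4)],
    )
    def test_arithmetic(self, pre, inb, expected):
        assert compute_ibc(pre, inb) == pytest.approx(expected, abs=1e-9)

    def test_worsening_is_negative(self):
        assert compute_ibc(30.0, 33.0) == pytest.approx(-10.0)

    def test_zero_pre_angle_rejected(self):
        with pytest.raises(ValueError):
            compute_ibc(0.0, 10.0)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        # d^2 sums to 4: rho = 1 - 24/60 = 0.6
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_all_permutations_match_rank_formula(self):
        x = np.arange(6, dtype=float)
        for perm in itertools.permutations(range(6)):
            y = np.asarray(perm, dtype=float)
            assert spearman_rho(x, y) == pytest.approx(
                _rank_formula(x, y), abs=1e-12
            )

    def test_average_rank_ties(self):
        # y ties at rank (2+3)/2; agreement with scipy's documented behaviour
        # checked against a hand computation of the rank-vector Pearson r
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 2.0, 2.0, 3.0]
        xr = np.array([1.0, 2.0, 3.0, 4.0])
        yr = np.array([1.0, 2.5, 2.5, 4.0])
        expected = np.corrcoef(xr, yr)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged_not_raised(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])

    @given(
        st.lists(st.integers(-1000, 1000), min_size=4, max_size=20, unique=True),
        st.lists(st.integers(-1000, 1000), min_size=4, max_size=20, unique=True),
    )
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_increasing_transform(self, x, y):
        n = min(len(x), len(y))
        x = [float(v) for v in x[:n]]
        y = [float(v) for v in y[:n]]
        base = spearman_rho(x, y)
        # cubing is strictly increasing and exact for these integers
        warped = spearman_rho([v**3 for v in x], y)
        assert warped == pytest.approx(base, abs=1e-12)


class TestClassifyStrength:
    @pytest.mark.parametrize(
        "rho,expected",
        [
            (-0.85, "strong"),
            (0.64, "moderate"),
            (-0.72, "strong"),
            (0.10, "little if any"),
            (0.25, "little if any"),
            (0.26, "weak"),
            (0.495, "weak"),
            (0.50, "moderate"),
            (0.695, "moderate"),
            (0.70, "strong"),
            (0.8999, "strong"),
            (0.90, "very strong"),
            (1.0, "very strong"),
            (0.0, "little if any"),
        ],
    )
    def test_bins(self, rho, expected):
        assert classify_strength(rho) == expected

    def test_sign_symmetric(self):
        for mag in np.linspace(0.0, 1.0, 101):
            assert classify_strength(mag) == classify_strength(-mag)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(1.2)

    def test_nan_is_undefined(self):
        assert classify_strength(float("nan")) == "undefined"


def _record(pid, lenke, ibc, feature_values):
    pos = {c: feature_values.get(f"peak_positive_{c}", 0.0) for c in SEGMENT_CODES}
    neg = {c: feature_values.get(f"peak_negative_{c}", 0.0) for c in SEGMENT_CODES}
    peaks = SegmentPeaks(
        peak_positive=pos, peak_negative=neg, counts={c: 10 for c in SEGMENT_CODES}
    )
    pre = 40.0
    return PatientRecord(
        patient_id=pid,
        lenke_type=lenke,
        pre_ca_ap=pre,
        inbrace_ca_ap=pre * (1 - ibc / 100.0),
        pre_ca_lat=30.0,
        inbrace_ca_lat=25.0,
        segment_peaks=peaks,
    )


class TestCorrelationTable:
    def _cohort(self, n=8):
        rng = np.random.default_rng(5)
        recs = []
        for i in range(n):
            depth = float(rng.uniform(-10, -2))
            ibc = 10.0 - 2.0 * depth  # strictly decreasing in the feature
            feats = {"peak_negative_PLM": depth,
                     "peak_positive_ARM": float(rng.uniform(2, 9))}
            recs.append(_record(f"p{i}", 5, ibc, feats))
        return recs

    def test_planted_monotone_feature_has_rho_minus_one(self):
        table = correlation_table(self._cohort(), lenke_type=5).rows
        row = table[table.feature == "peak_negative_PLM"].iloc[0]
        assert row.rho == pytest.approx(-1.0)
        assert row.category == "very strong"

    def test_row_order_matches_feature_listing(self):
        table = correlation_table(self._cohort(), lenke_type=5).rows
        assert list(table.feature) == list(PEAK_FEATURES)

    def test_record_order_invariance(self):
        recs = self._cohort()
        a = correlation_table(recs, 5).rows
        b = correlation_table(list(reversed(recs)), 5).rows
        pd.testing.assert_frame_equal(a, b)

    def test_constant_feature_flagged_undefined(self):
        table = correlation_table(self._cohort(), lenke_type=5).rows
        row = table[table.feature == "peak_positive_ALU"].iloc[0]
        assert math.isnan(row.rho)
        assert row.category == "undefined"

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            correlation_table(self._cohort()[:2], lenke_type=5)

    def test_wrong_group_excluded(self):
        with pytest.raises(ValueError):
            correlation_table(self._cohort(), lenke_type=1)


class TestSummaries:
    def test_small_group_mean_sd(self):
        recs = [
            _record("a", 1, ibc, {}) for ibc in (10.0, 20.0, 30.0)
        ]
        df = summarize_cohort(recs)
        row = df[df.lenke_type == 1].iloc[0]
        assert row["ibc_ap_percent_mean"] == pytest.approx(20.0)
        assert row["ibc_ap_percent_std"] == pytest.approx(10.0)

    def test_identical_values_zero_sd(self):
        recs = [_record(str(i), 5, 15.0, {}) for i in range(4)]
        row = summarize_cohort(recs).iloc[0]
        assert row["ibc_ap_percent_std"] == pytest.approx(0.0)

    def test_single_record_sd_undefined(self):
        row = summarize_cohort([_record("x", 1, 12.0, {})]).iloc[0]
        assert math.isnan(row["ibc_ap_percent_std"])

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(0, 50, 1000)
        recs = [_record(str(i), 1, v, {}) for i, v in enumerate(values)]
        row = summarize_cohort(recs).iloc[0]
        mean = values.sum() / len(values)
        sd = math.sqrt(((values - mean) ** 2).sum() / (len(values) - 1))
        assert row["ibc_ap_percent_mean"] == pytest.approx(mean, abs=1e-10)
        assert row["ibc_ap_percent_std"] == pytest.approx(sd, abs=1e-10)


class TestPatientRecord:
    def test_invalid_lenke_rejected(self):
        with pytest.raises(ValueError):
            _record("x", 3, 10.0, {})

    def test_negative_angle_rejected(self):
        with pytest.raises(ValueError):
            PatientRecord("x", 1, -5.0, 3.0, 10.0, 8.0)

    def test_ibc_consistent_with_formula(self):
        r = _record("x", 1, 17.5, {})
        assert r.ibc_ap_percent == pytest.approx(
            compute_ibc(r.pre_ca_ap, r.inbrace_ca_ap), abs=1e-9
        )
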