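"""Statistical machinery against brute-force oracles and known values."""

import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from steatoquant import (
    categorize_mfpa,
    cohort_report,
    kruskal_wallis,
    mann_whitney,
    roc,
    sensitivity_specificity,
    spearman,
)
from steatoquant.stats import BRACKET_LABELS, categorize_mfpa_series
from steatoquant.synthetic import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# oracles (independent, brute force)
# ---------------------------------------------------------------------------

def concordance_auroc(scores, labels):
    """O(n^2) pairwise concordance: P(score+ > score-) + 0.5 P(equal)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def enumerate_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n_a]) - n_a * (n_a + 1) / 2)
    mid = n_a * (len(pooled) - n_a) / 2.0
    dev_obs = abs(u_obs - mid)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = float(np.sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2)
        total += 1
        if abs(u - mid) >= dev_obs - 1e-12:
            count += 1
    return count / total


def enumerate_spearman_p(x, y):
    """Exact two-sided Spearman p by enumerating all pairings."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rs_obs = abs(sps.pearsonr(rx, ry).statistic)
    count = total = 0
    for perm in itertools.permutations(rx):
        total += 1
        if abs(sps.pearsonr(np.asarray(perm), ry).statistic) >= rs_obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# brackets
# ---------------------------------------------------------------------------

class TestCategorize:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.0, "<5"), (4.99, "<5"), (4.999, "<5"),
            (5.0, "5-9.9"), (9.999, "5-9.9"),
            (10.0, "10-19.9"), (19.999, "10-19.9"),
            (20.0, ">=20"), (100.0, ">=20"),
        ],
    )
    def test_boundaries_assigned_upward(self, value, label):
        assert categorize_mfpa(value) == label

    @given(st.floats(0, 100, allow_nan=False))
    @settings(deadline=None)
    def test_partition_of_range(self, value):
        assert categorize_mfpa(value) in BRACKET_LABELS

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(ValueError):
                categorize_mfpa(bad)


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        rs, _ = spearman([1, 2, 3], [1, 4, 9])
        assert rs == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        rs, _ = spearman([1, 2, 3], [3, 2, 1])
        assert rs == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle_at_n8(self, rng):
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p = spearman(x, y)
            assert p == pytest.approx(enumerate_spearman_p(x, y), abs=5e-4)

    def test_exact_p_with_ties(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = rng.normal(size=7)
        _, p = spearman(x, y)
        assert p == pytest.approx(enumerate_spearman_p(x, y), abs=5e-4)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3, lambda v: 5 * v - 2])
    def test_invariant_under_strictly_monotone_transforms(self, rng, transform):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        rs, p = spearman(x, y)
        rs2, p2 = spearman(transform(x), y)
        assert rs2 == pytest.approx(rs, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)

    def test_missing_values_dropped_pairwise(self):
        rs, _ = spearman([1, 2, 3, 4, np.nan], [1, 2, 3, 4, 100])
        assert rs == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="3"):
            spearman([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# mann-whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-9)  # 2/20 under exact enumeration

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for n_a, n_b in [(3, 4), (5, 5), (7, 7), (4, 8)]:
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(enumerate_mw_p(a, b), abs=1e-10), (n_a, n_b)

    def test_type_one_error_rate_under_null(self, rng):
        # asymptotic path (n=30 per group): size close to nominal alpha
        rejections = sum(
            mann_whitney(rng.normal(size=30), rng.normal(size=30))[1] < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# kruskal-wallis
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_rank_statistic(self):
        # groups [1,2],[3,4],[5,6]: rank sums 3, 7, 11 over N=6, so
        # H = 12/(6*7) * (3^2 + 7^2 + 11^2)/2 - 3*7 = 32/7
        h, _ = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32.0 / 7.0)

    def test_monte_carlo_p_consistent_with_chi_square(self, rng):
        groups = [rng.normal(size=30) for _ in range(3)]
        h, p_chi2 = kruskal_wallis(groups)
        _, p_mc = kruskal_wallis(groups, monte_carlo=True, n_resamples=4999, seed=1)
        assert p_mc == pytest.approx(p_chi2, abs=0.01 + 2 * math.sqrt(p_chi2 * (1 - p_chi2) / 4999))

    def test_fewer_than_three_groups_redirects(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_wallis([[1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# roc
# ---------------------------------------------------------------------------

class TestRoc:
    def test_perfect_separation(self):
        curve = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auroc == pytest.approx(1.0)

    def test_auroc_equals_concordance_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            curve = roc(scores, labels)
            assert curve.auroc == pytest.approx(
                concordance_auroc(scores, labels), abs=1e-12
            )

    def test_sweep_monotonicity_and_bounds(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        curve = roc(scores, labels)
        assert (np.diff(curve.sensitivity) >= 0).all()  # thresholds descend
        assert curve.sensitivity[0] == 0.0 and curve.sensitivity[-1] == 1.0
        assert ((0 <= curve.specificity) & (curve.specificity <= 1)).all()

    def test_null_auroc_near_half(self, rng):
        scores = rng.normal(size=1000)
        labels = rng.random(1000) < 0.5
        assert roc(scores, labels).auroc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1])


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "cutoff, expected",
        [(25.0, (1.0, 1.0)), (100.0, (0.0, 1.0)), (5.0, (1.0, 0.0))],
    )
    def test_separating_and_extreme_cutoffs(self, cutoff, expected):
        result = sensitivity_specificity([10, 20, 30, 40], [0, 0, 1, 1], cutoff)
        assert result == pytest.approx(expected)

    def test_two_by_two_table_arithmetic(self):
        # TP=9 FN=1 TN=5 FP=5 -> sens 0.9, spec 0.5
        scores = [1] * 5 + [0] * 5 + [1] * 9 + [0] * 1
        labels = [0] * 10 + [1] * 10
        assert sensitivity_specificity(scores, labels, 0.5) == pytest.approx((0.9, 0.5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_specificity([1, 2], [1, 1], 1.5)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortSpec(seed=3))


class TestCohortReport:
    def test_report_structure(self, cohort):
        report = cohort_report(cohort)
        assert report["n_patients"] == 136
        assert set(report["summary"]) == {"all", "male", "female", "mfpa_lt5", "mfpa_ge5"}
        assert "rs" in report["correlations"]["pooled"]["ha_um2"]
        assert set(report["brackets"]["counts"]) == set(BRACKET_LABELS)
        assert "auroc" in report["roc"]["alt_vs_mfpa_ge_5"]

    def test_programmed_links_recovered(self, cohort):
        report = cohort_report(cohort)
        assert report["correlations"]["pooled"]["ha_um2"]["rs"] > 0.6
        assert report["correlations"]["pooled"]["alt_u_l"]["rs"] > 0
        assert report["brackets"]["kruskal_wallis"]["alt_u_l"]["p"] < 0.05

    def test_deterministic_serialisation(self, cohort):
        a = json.dumps(cohort_report(cohort), sort_keys=True)
        b = json.dumps(cohort_report(cohort.copy()), sort_keys=True)
        assert a == b

    def test_degenerate_occupancy_flags_skips(self, rng):
        df = generate_cohort(CohortSpec(seed=9)).copy()
        df["mfpa_pct"] = rng.uniform(0, 4.9, size=len(df))
        report = cohort_report(df)
        counts = report["brackets"]["counts"]
        assert counts["<5"] == len(df) and sum(counts.values()) == len(df)
        assert report["brackets"]["kruskal_wallis"]["alt_u_l"]["skipped"] is True
        pairs = report["brackets"]["pairwise_mann_whitney"]["alt_u_l"]
        assert all(entry.get("skipped") for entry in pairs.values())
        assert report["roc"]["alt_vs_mfpa_ge_5"]["skipped"] is True

    def test_holm_adjustment_monotone(self, cohort):
        report = cohort_report(cohort, holm=True)
        for entry in report["brackets"]["pairwise_mann_whitney"]["alt_u_l"].values():
            if "p" in entry:
                assert entry["p_holm"] >= entry["p"] - 1e-15

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="hpl"):
            cohort_report(pd.DataFrame({"patient_id": [], "mfpa_pct": []}))

    def test_too_few_records_rejected(self):
        df = generate_cohort(CohortSpec(n_patients=12, seed=1)).iloc[:8]
        with pytest.raises(ValueError, match="10"):
            cohort_report(df)

    def test_bracket_series_matches_scalar(self, cohort):
        series = np.asarray(categorize_mfpa_series(cohort["mfpa_pct"]))
        scalar = [categorize_mfpa(v) for v in cohort["mfpa_pct"]]
        assert list(series) == scalar
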