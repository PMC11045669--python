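"""Cohort statistics: medians, correlations, rank tests, ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sage_quant import stats as cs


class TestRoiMedians:
    def test_uniform_map(self):
        mask = np.ones((4, 4, 2), bool)
        out = cs.extract_roi_medians({"trate": np.full((4, 4, 2), 150.0)}, mask)
        assert out["trate"] == 150.0

    def test_nan_policy(self):
        vol = np.array([[[1.0, 2.0, 3.0, np.nan]]])
        mask = np.ones(vol.shape, bool)
        assert cs.extract_roi_medians({"m": vol}, mask)["m"] == 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cs.extract_roi_medians({"m": np.ones((2, 2, 2))}, np.zeros((2, 2, 2), bool))

    def test_phantom_medians_match_truth(self, noiseless_phantom, noiseless_maps):
        ds, maps = noiseless_phantom, noiseless_maps
        rec = cs.extract_roi_medians(maps.as_dict(), ds.masks.lesion)
        truth = cs.extract_roi_medians(
            {"trate": ds.truth.trate_true, "ktrans": ds.truth.ktrans},
            ds.masks.lesion,
        )
        assert rec["trate"] == pytest.approx(truth["trate"], rel=0.005)
        assert rec["ktrans"] == pytest.approx(truth["ktrans"], rel=0.01)


def brute_force_pearson(x, y):
    x = np.asarray(x, float); y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestCorrelation:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = cs.pairwise_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_textbook_set_matches_formula(self):
        x = [1.0, 2.0, 4.0, 5.0, 8.0]
        y = [3.0, 2.0, 7.0, 6.0, 10.0]
        res = cs.pairwise_correlation(x, y)
        assert abs(res.r - brute_force_pearson(x, y)) < 1e-12
        assert abs(res.r_squared - res.r**2) < 1e-15

    def test_null_simulation(self):
        rng = np.random.default_rng(21)
        x, y = rng.standard_normal((2, 1000))
        res = cs.pairwise_correlation(x, y)
        assert abs(res.r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cs.pairwise_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 30))
        perm = rng.permutation(30)
        a = cs.pairwise_correlation(x, y)
        b = cs.pairwise_correlation(x[perm], y[perm])
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-9)


def brute_force_mannwhitney(a, b):
    """Exact two-sided p by enumerating all rank assignments of the pooled
    sample; U counts pairs a > b (+0.5 per tie)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    mu = len(a) * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), len(a)):
        sel = np.zeros(n, bool); sel[list(idx)] = True
        u = sum((x > y) + 0.5 * (x == y) for x in pooled[sel] for y in pooled[~sel])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


class TestGroupCompare:
    def test_fully_separated_small_groups(self):
        """a={1,2,3} vs b={4,5,6}: U=0 and exact two-sided p = 2/20 = 0.1."""
        res = cs.group_compare([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples(self):
        res = cs.group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.u == pytest.approx(4.5)  # n_a*n_b/2 with ties
        assert res.p > 0.9

    def test_exact_path_matches_enumeration(self):
        """Exact U/p equal brute-force enumeration for all sizes <= 8."""
        rng = np.random.default_rng(6)
        for n_a, n_b in [(2, 2), (3, 3), (3, 5), (4, 4), (2, 6)]:
            a = rng.standard_normal(n_a)
            b = rng.standard_normal(n_b) + 0.5
            res = cs.group_compare(a, b)
            u_ref, p_ref = brute_force_mannwhitney(a, b)
            assert res.u == pytest.approx(u_ref)
            assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_shifted_normals_significant(self):
        rng = np.random.default_rng(30)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        assert cs.group_compare(a, b).p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cs.group_compare([], [1.0])


def trapezoid_auc(curve: pd.DataFrame) -> float:
    return float(np.trapezoid(curve["tpr"], curve["fpr"]))


class TestRoc:
    def test_perfect_separation(self):
        res = cs.roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_null_simulation(self):
        rng = np.random.default_rng(14)
        values = rng.standard_normal(2000)
        labels = rng.integers(0, 2, 2000)
        res = cs.roc_analysis(values, labels)
        assert abs(res.auc - 0.5) < 0.03

    def test_rank_auc_equals_trapezoidal_area(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            values = rng.standard_normal(60)
            labels = rng.integers(0, 2, 60)
            if labels.all() or not labels.any():
                continue
            res = cs.roc_analysis(values, labels)
            assert abs(res.auc - trapezoid_auc(res.curve)) < 1e-10

    def test_rank_auc_equals_trapezoid_with_ties(self):
        rng = np.random.default_rng(16)
        values = rng.integers(0, 5, 80).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 80)
        res = cs.roc_analysis(values, labels)
        assert abs(res.auc - trapezoid_auc(res.curve)) < 1e-10

    def test_fixed_cutoff_operating_point(self):
        """9 positives (8 above cutoff) and 10 negatives (8 below) give
        sensitivity 0.889 and specificity 0.800 at the fixed cutoff."""
        cutoff = 142.0
        positives = [150, 160, 170, 180, 190, 200, 210, 145, 130]
        negatives = [80, 90, 100, 110, 120, 130, 135, 140, 150, 160]
        values = np.array(positives + negatives, float)
        labels = np.r_[np.ones(9), np.zeros(10)].astype(bool)
        res = cs.roc_analysis(values, labels, fixed_cutoff=cutoff)
        assert res.sensitivity == pytest.approx(8 / 9, abs=1e-12)
        assert res.specificity == pytest.approx(8 / 10, abs=1e-12)
        assert res.cutoff_source == "fixed"

    def test_youden_cutoff_reported_without_fixed(self):
        res = cs.roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.cutoff_source == "youden"
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cs.roc_analysis([1.0, 2.0], [1, 1])

    def test_monotone_subject_order_invariance(self):
        rng = np.random.default_rng(17)
        values = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        perm = rng.permutation(50)
        a = cs.roc_analysis(values, labels)
        b = cs.roc_analysis(values[perm], labels[perm])
        assert a.auc == pytest.approx(b.auc, abs=1e-12)


class TestKi67:
    @pytest.mark.parametrize("value,expected", [(5.0, 0.0), (10.0, 0.0), (10.1, 1.0)])
    def test_binarization_boundary(self, value, expected):
        out = cs.binarize_ki67(np.array([value]))
        assert out[0] == expected

    def test_missing_stays_missing(self):
        out = cs.binarize_ki67(np.array([np.nan, 20.0]))
        assert np.isnan(out[0]) and out[1] == 1.0


class TestCohortReport:
    def test_full_battery_on_synthetic_table(self):
        rng = np.random.default_rng(18)
        n = 20
        trate = rng.uniform(50, 200, n)
        table = pd.DataFrame({
            "trate": trate,
            "psr": 250 - trate + rng.normal(0, 10, n),  # anticorrelated
            "nrcbv": rng.uniform(0.5, 3, n),
            "group": ["TN"] * 10 + ["R"] * 10,
            "ki67_high": (trate > 140).astype(int),
        })
        rep = cs.cohort_report(
            table, group_column="group", roc_label_column="ki67_high",
            roc_metric="trate", fixed_cutoff=142.0,
        )
        assert rep["correlations"]["trate~psr"].r < -0.9
        assert "trate" in rep["group_tests"]
        assert rep["roc"].auc > 0.9
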