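"""ROI statistics: Mann-Whitney, ROC/Youden, Spearman, report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliodki import CohortSpec, compare_rois, marker_correlations, report, \
    roc_analysis, simulate_cohort
from gliodki.roistats import (auc_concordance, mann_whitney, roi_means,
                              spearman_ci, _youden_cutoff)


# independent oracles --------------------------------------------------------

def mw_exact_p_enumeration(a, b) -> float:
    """Two-sided exact Mann-Whitney p by exhaustive label enumeration."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_of(idx):
        x = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in rest)

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in
                   itertools.combinations(range(len(pooled)), n1)])
    mid = len(a) * len(b) / 2.0
    return float(np.mean(np.abs(us - mid) >= np.abs(u_obs - mid) - 1e-12))


def auc_brute_force(a, b) -> float:
    pairs = [(x > y) + 0.5 * (x == y) for x in a for y in b]
    return float(np.mean(pairs))


class TestMannWhitney:
    def test_textbook_example(self):
        u, p, degen = mann_whitney(np.array([1., 2., 3.]),
                                   np.array([4., 5., 6.]))
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)
        assert not degen

    def test_identical_groups(self):
        u, p, _ = mann_whitney(np.array([1., 2., 3.]), np.array([1., 2., 3.]))
        assert p == 1.0

    def test_all_tied_degenerate(self):
        u, p, degen = mann_whitney(np.full(4, 2.0), np.full(5, 2.0))
        assert p == 1.0 and degen

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_enumeration(self, trial):
        """Exact small-sample p agrees with brute-force label enumeration."""
        rng = np.random.default_rng(1000 + trial)
        n1, n2 = rng.integers(3, 9, size=2)
        pooled = rng.permutation(np.arange(n1 + n2, dtype=float))  # tie-free
        a, b = pooled[:n1], pooled[n1:]
        _, p, _ = mann_whitney(a, b)
        assert p == pytest.approx(mw_exact_p_enumeration(a, b), abs=1e-10)


class TestAUC:
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_concordant_pair_oracle(self, trial):
        rng = np.random.default_rng(2000 + trial)
        n1, n2 = rng.integers(5, 51, size=2)
        a = np.round(rng.normal(1.0, 1.0, n1), 1)  # rounding induces ties
        b = np.round(rng.normal(0.5, 1.0, n2), 1)
        assert auc_concordance(a, b) == pytest.approx(
            auc_brute_force(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(1, 1, 30), rng.normal(0, 1, 25)
        assert auc_concordance(np.exp(a), np.exp(b)) == pytest.approx(
            auc_concordance(a, b), abs=1e-12)

    def test_matches_sklearn_roc_auc(self):
        """Independent library cross-check of the rank-based AUC."""
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(12)
        a = np.round(rng.normal(1, 1, 40), 1)
        b = np.round(rng.normal(0, 1, 35), 1)
        labels = np.r_[np.ones(len(a)), np.zeros(len(b))]
        scores = np.r_[a, b]
        assert auc_concordance(a, b) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestRankStatisticProperties:
    from hypothesis import given, settings, strategies as st

    values = st.lists(st.floats(-50, 50, allow_nan=False).map(
        lambda v: round(v, 1)), min_size=3, max_size=20)

    @given(a=values, b=values)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_auc_complement_and_range(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        auc = auc_concordance(a, b)
        assert 0.0 <= auc <= 1.0
        assert auc == pytest.approx(1.0 - auc_concordance(b, a), abs=1e-12)

    @given(a=values, b=values)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mann_whitney_p_valid(self, a, b):
        u, p, _ = mann_whitney(np.asarray(a), np.asarray(b))
        assert 0.0 <= p <= 1.0
        assert 0.0 <= u <= len(a) * len(b)


def _toy_table(a_vals, b_vals, param="MK", roi_a=1, roi_b=2):
    rows = []
    for i, v in enumerate(a_vals):
        rows.append({"case_id": f"c{i}", "roi": roi_a, param: v})
    for i, v in enumerate(b_vals):
        rows.append({"case_id": f"c{i}", "roi": roi_b, param: v})
    return pd.DataFrame(rows)


class TestROCAnalysis:
    def test_perfect_separation(self):
        t = _toy_table([5., 6., 7., 8.], [1., 2., 3., 4.])
        r = roc_analysis(t, 1, 2, n_boot=200, seed=0)[0]
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 4.0 < r.cutoff < 5.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(9)
        t = _toy_table(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        r = roc_analysis(t, 1, 2, n_boot=200, seed=0)[0]
        assert 0.4 <= r.auc <= 0.6

    def test_orientation_flip_recorded(self):
        t = _toy_table([1., 2., 3., 4.], [5., 6., 7., 8.])
        r = roc_analysis(t, 1, 2, n_boot=200, seed=0)[0]
        assert r.auc == 1.0 and r.direction == "less"
        assert 4.0 < r.cutoff < 5.0

    def test_degenerate_constant_groups(self):
        t = _toy_table([2., 2., 2.], [2., 2., 2.])
        r = roc_analysis(t, 1, 2, n_boot=200, seed=0)[0]
        assert r.auc == 0.5 and r.degenerate

    def test_bootstrap_ci_ordered_and_seeded(self):
        rng = np.random.default_rng(10)
        t = _toy_table(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        r1 = roc_analysis(t, 1, 2, n_boot=300, seed=5)[0]
        r2 = roc_analysis(t, 1, 2, n_boot=300, seed=5)[0]
        assert r1.ci_low <= r1.ci_high
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_small_nboot_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            roc_analysis(_toy_table([1.], [2.]), 1, 2, n_boot=50)

    def test_youden_tie_prefers_specificity(self):
        # J is maximised (J=0.5) at several thresholds; the chosen cutoff
        # must be the one with the highest specificity
        pos = np.array([1.0, 3.0])
        neg = np.array([0.0, 2.0])
        cut, sens, spec = _youden_cutoff(pos, neg)
        assert spec == 1.0 and cut > 2.0


class TestCompareRois:
    def test_power_at_calibrated_effect(self):
        """Edema vs NAWM MK gap is detectable at the strict alpha, n=50."""
        table = simulate_cohort(CohortSpec(n_cases=50, seed=5))
        res = {r.parameter: r for r in compare_rois(table, 2, 3)}
        assert res["MK"].significant
        assert res["AWF"].significant

    def test_requires_three_cases_per_group(self):
        t = _toy_table([1., 2.], [3., 4.])
        with pytest.raises(ValueError, match=">=3 cases"):
            compare_rois(t, 1, 2, params=["MK"])

    def test_holm_correction_never_adds_discoveries(self):
        table = simulate_cohort(CohortSpec(n_cases=50, seed=5))
        plain = compare_rois(table, 2, 3)
        holm = compare_rois(table, 2, 3, correction="holm")
        for r_plain, r_holm in zip(plain, holm):
            assert r_holm.significant <= r_plain.significant
        # the calibrated large effects survive the correction
        holm_map = {r.parameter: r.significant for r in holm}
        assert holm_map["MK"] and holm_map["AWF"]


class TestMarkerCorrelations:
    def _table(self, x, y, roi=1):
        return pd.DataFrame({"case_id": [f"c{i}" for i in range(len(x))],
                             "roi": roi, "MK": x, "Ki67_LI": y})

    def test_perfectly_monotone(self):
        x = np.arange(1.0, 9.0)
        res = marker_correlations(self._table(x, x**3), 1,
                                  markers=["Ki67_LI"], params=["MK"],
                                  n_boot=200)[0]
        assert res.rho == pytest.approx(1.0)
        assert res.significant

    def test_anti_monotone(self):
        x = np.arange(1.0, 9.0)
        res = marker_correlations(self._table(x, -x), 1,
                                  markers=["Ki67_LI"], params=["MK"],
                                  n_boot=200)[0]
        assert res.rho == pytest.approx(-1.0)

    def test_constant_column_flagged(self):
        res = marker_correlations(self._table(np.ones(6), np.arange(6.0)), 1,
                                  markers=["Ki67_LI"], params=["MK"],
                                  n_boot=200)[0]
        assert res.degenerate and not res.significant

    def test_minimum_pairs_enforced(self):
        with pytest.raises(ValueError, match=">=5 paired"):
            marker_correlations(self._table(np.arange(4.0), np.arange(4.0)),
                                1, markers=["Ki67_LI"], params=["MK"])

    def test_copula_target_recovered(self):
        """Spearman target 0.363 between core CBF and Ki-67 at n=500."""
        table = simulate_cohort(CohortSpec(n_cases=500, seed=0))
        res = marker_correlations(table, 1, markers=["Ki67_LI"],
                                  params=["CBF"], n_boot=200, seed=0)[0]
        assert res.rho == pytest.approx(0.363, abs=0.05)
        assert res.ci_low <= res.rho <= res.ci_high

    def test_bootstrap_ci_coverage(self):
        """Percentile bootstrap 95% CI covers the generating rho with
        nominal frequency (within [0.90, 0.98]) at n=50."""
        target = 0.363
        r_latent = 2 * np.sin(np.pi * target / 6)
        rng = np.random.default_rng(77)
        hits = 0
        reps = 200
        for k in range(reps):
            z = rng.standard_normal((2, 50))
            x = z[0]
            y = r_latent * z[0] + np.sqrt(1 - r_latent**2) * z[1]
            lo, hi = spearman_ci(x, y, n_boot=500, seed=k)
            hits += lo <= target <= hi
        assert 0.90 <= hits / reps <= 0.98


class TestTypeIError:
    def test_null_cohort_flag_rate(self):
        """Under identical zones the strict-alpha flag rate stays tiny."""
        from gliodki.cohort import null_cohort_spec
        flags = total = 0
        for rep in range(60):
            table = simulate_cohort(null_cohort_spec(n_cases=50,
                                                     seed=50_000 + rep))
            for a, b in ((1, 2), (2, 3), (3, 4)):
                res = compare_rois(table, a, b, alpha=0.001)
                flags += sum(r.significant for r in res)
                total += len(res)
        assert flags / total <= 0.005


class TestROIMeans:
    def _setup(self, qc_all_removed=False):
        from gliodki.metrics import ScalarMapSet
        from gliodki.wmti import WMTIMapSet
        shape = (4, 4, 1)
        ones = np.ones(shape)
        valid = np.ones(shape, bool)
        kvalid = valid.copy()
        rois = np.zeros(shape, int)
        rois[0, :2] = 1
        rois[1, :2] = 2
        rois[2, :2] = 3
        rois[3, :2] = 4
        if qc_all_removed:
            kvalid[0] = False
        sm = ScalarMapSet(md=ones * 1.1, fa=ones * 0.4, mk=ones * 0.9,
                          ak=ones, rk=ones, ka=ones, valid=kvalid,
                          valid_diffusion=valid)
        wm = WMTIMapSet(awf=ones * 0.3, ax_ead=ones * 2, rad_ead=ones * 0.8,
                        ax_iad=ones * 0.8, rad_iad=ones * 0.0,
                        tort=ones * 2.5, valid=valid, valid_intra=valid)
        return sm, wm, ones * 42.0, rois

    def test_constant_maps_give_exact_means(self):
        sm, wm, cbf, rois = self._setup()
        t = roi_means(sm, wm, cbf, rois, "caseA")
        assert len(t) == 4
        assert (t["MK"] == 0.9).all()
        assert (t["CBF"] == 42.0).all()

    def test_qc_emptied_roi_yields_missing(self):
        sm, wm, cbf, rois = self._setup(qc_all_removed=True)
        t = roi_means(sm, wm, cbf, rois, "caseA")
        row1 = t[t["roi"] == 1].iloc[0]
        assert np.isnan(row1["MK"])
        assert row1["MD"] == 1.1  # diffusion maps keep their own validity

    def test_missing_label_warns_and_omits_row(self):
        sm, wm, cbf, rois = self._setup()
        rois[rois == 4] = 0
        with pytest.warns(UserWarning, match="missing ROI 4"):
            t = roi_means(sm, wm, cbf, rois, "caseA")
        assert set(t["roi"]) == {1, 2, 3}


class TestReport:
    def _inputs(self):
        rng = np.random.default_rng(3)
        t = _toy_table(rng.normal(1, 1, 12), rng.normal(0, 1, 12))
        comps = compare_rois(t, 1, 2, params=["MK"])
        rocs = roc_analysis(t, 1, 2, n_boot=200, seed=0, params=["MK"])
        return comps, rocs

    def test_deterministic_output(self):
        comps, rocs = self._inputs()
        _, md1 = report(comps, rocs)
        _, md2 = report(comps, rocs)
        assert md1 == md2

    def test_without_correlations(self):
        comps, rocs = self._inputs()
        frames, md = report(comps, rocs, None)
        assert "correlations" not in frames
        assert "ROC ranking" in md and "Mann-Whitney" in md

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            report([], [])
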