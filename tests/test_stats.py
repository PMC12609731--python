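"""Statistical battery: enumeration oracles, worked examples, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from swallow_ersp.stats import (
    chi_square_independence,
    cliffs_delta,
    kruskal_wallis,
    levene_test,
    lilliefors_test,
    mann_whitney_u,
    rank_biserial,
    run_group_analysis,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# brute-force oracles (exhaustive enumeration of the null distribution)


def mw_exact_p(x, y):
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, N = len(x), len(x) + len(y)
    us = []
    for comb in itertools.combinations(range(N), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(xi > yj for xi in xs for yj in ys))
    us = np.array(us)
    u_obs = sum(xi > yj for xi in x for yj in y)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def wsr_exact_p(d):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    ts = np.array([sum(r for s, r in zip(signs, ranks) if s)
                   for signs in itertools.product([0, 1], repeat=len(d))])
    return min(1.0, 2 * min((ts <= t_obs).mean(), (ts >= t_obs).mean()))


class TestNormalityScreens:
    def test_lilliefors_keeps_normal_samples(self):
        rng = np.random.default_rng(0)
        hits = sum(lilliefors_test(rng.normal(size=1000)).p_value > 0.05
                   for _ in range(100))
        assert hits >= 90

    def test_lilliefors_rejects_exponential_samples(self):
        rng = np.random.default_rng(1)
        hits = sum(lilliefors_test(rng.exponential(size=1000)).p_value < 0.05
                   for _ in range(100))
        assert hits >= 99

    def test_lilliefors_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lilliefors_test(np.full(10, 3.0))

    def test_levene_ignores_location_shift(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        res = levene_test([x, x + 5.0])
        assert res.p_value > 0.05

    def test_levene_detects_heteroscedasticity(self):
        rng = np.random.default_rng(3)
        res = levene_test([rng.normal(size=200), 5 * rng.normal(size=200)])
        assert res.p_value < 0.001


class TestKruskalWallis:
    def test_identical_groups_give_h_zero(self):
        res = kruskal_wallis([[1.0, 2.0]] * 3)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_rank_value(self):
        # ranks 1..6, H = 12/42 * (2*(1.5-3.5)^2 + 0 + 2*(5.5-3.5)^2)
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32.0 / 7.0, rel=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        gs = [rng.normal(size=8), rng.normal(size=9), rng.normal(size=7)]
        h1 = kruskal_wallis(gs).statistic
        h2 = kruskal_wallis([g + 100.0 for g in gs]).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestMannWhitney:
    def test_exact_against_enumeration_all_small_n(self):
        """Implementation p equals exhaustive enumeration for all tie-free
        sample-size pairs up to a combined n of 8."""
        rng = np.random.default_rng(5)
        for nx in range(1, 8):
            for ny in range(1, 9 - nx):
                if nx + ny < 3:
                    continue
                for _ in range(3):
                    z = rng.permutation(rng.normal(size=nx + ny))
                    x, y = z[:nx], z[nx:]
                    got = mann_whitney_u(x, y).p_value
                    assert got == pytest.approx(mw_exact_p(x, y), abs=1e-12)

    def test_worked_exact_example(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_complete_separation_delta(self):
        assert cliffs_delta([1, 2, 3], [4, 5, 6]) == -1.0
        assert cliffs_delta([4, 5, 6], [1, 2, 3]) == 1.0

    def test_identical_samples_delta_zero(self):
        assert cliffs_delta([1, 2, 2, 3], [1, 2, 2, 3]) == 0.0

    def test_delta_brute_force_equivalence(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 5, size=20).astype(float)
        y = rng.integers(0, 5, size=17).astype(float)
        brute = np.mean(np.sign(x[:, None] - y[None, :]))
        assert cliffs_delta(x, y) == pytest.approx(brute, abs=1e-15)

    @given(st.lists(st.integers(-3, 3), min_size=1, max_size=30),
           st.lists(st.integers(-3, 3), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_delta_bounded_under_ties_and_duplicates(self, x, y):
        assert -1.0 <= cliffs_delta(x, y) <= 1.0


class TestWilcoxonSignedRank:
    def test_exact_against_enumeration_all_small_n(self):
        rng = np.random.default_rng(7)
        for n in range(4, 9):
            for _ in range(4):
                d = rng.normal(size=n)
                while len(np.unique(np.abs(d))) < n:
                    d = rng.normal(size=n)
                got = wilcoxon_signed_rank(d, np.zeros(n)).p_value
                assert got == pytest.approx(wsr_exact_p(d), abs=1e-12)

    def test_all_positive_differences_n5(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], np.zeros(5))
        assert res.p_value == pytest.approx(2.0 / 2 ** 5, abs=1e-12)

    def test_uniform_shift_gives_r_minus_one(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x + 1.0)
        assert res.effect_size == -1.0

    def test_symmetric_differences_give_r_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + np.array([0.5, -0.5, 0.7, -0.7])
        assert rank_biserial(x, y) == 0.0

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0] * 5, [1.0] * 5)

    @given(st.lists(st.integers(-5, 5), min_size=4, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_rank_biserial_bounded(self, d):
        d = np.asarray(d, float)
        if np.all(d == 0):
            return
        assert -1.0 <= rank_biserial(d, np.zeros_like(d)) <= 1.0


class TestChiSquare:
    def test_stroke_laterality_contingency(self):
        """Control vs dysphagic stroke-laterality counts (right/left/
        bilateral): Pearson chi-square without continuity correction."""
        res = chi_square_independence([[18, 13, 1], [27, 20, 3]],
                                      ("control", "dysphagic"),
                                      ("right", "left", "bilateral"))
        assert res.p_value == pytest.approx(0.8392, abs=5e-5)
        assert "expected count < 5" in res.note

    def test_proportional_rows_give_zero(self):
        res = chi_square_independence([[10, 20, 30], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_2x2(self):
        res = chi_square_independence([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.extra["dof"] == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [1, 2]])


def _synthetic_eri_table(rng, n_per_group=(10, 10, 10),
                         means=(-2.0, -1.2, -0.5), sd=0.5):
    rows = []
    for g, n, mu in zip(("healthy", "control", "dysphagic"), n_per_group, means):
        for i in range(n):
            sid = f"{g}{i}"
            for ch in ("C3", "Cz", "C4"):
                for band in ("alpha", "beta"):
                    rows.append({"subject_id": sid, "group": g, "channel": ch,
                                 "band": band,
                                 "eri_db": mu + rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestGroupAnalysis:
    def test_report_test_counts_for_three_groups(self):
        rng = np.random.default_rng(8)
        eri = _synthetic_eri_table(rng)
        li_rows = []
        for g in ("healthy", "control", "dysphagic"):
            for i in range(10):
                for band in ("alpha", "beta"):
                    li_rows.append({"subject_id": f"{g}{i}", "group": g,
                                    "band": band, "li": rng.normal(0, 0.2),
                                    "denominator_flag": False})
        li = pd.DataFrame(li_rows)
        report = run_group_analysis(eri, li)
        assert (report.test == "kruskal_wallis").sum() == 6 + 2  # ERI + LI omnibus
        mw = report[report.test == "mann_whitney_u"]
        assert len(mw[~mw.context.str.startswith("LI")]) == 18  # 6 cells x 3 pairs
        assert len(mw[mw.context.str.startswith("LI")]) == 6
        assert (report.test == "wilcoxon_signed_rank").sum() == 6

    def test_single_group_runs_without_between_group_tests(self):
        rng = np.random.default_rng(9)
        eri = _synthetic_eri_table(rng, n_per_group=(8,), means=(-2.0,))
        report = run_group_analysis(eri)
        assert (report.test == "mann_whitney_u").sum() == 0
        assert (report.test == "kruskal_wallis").sum() == 0
        assert (report.test == "wilcoxon_signed_rank").sum() == 2

    def test_correction_flag_adds_adjusted_pvalues(self):
        rng = np.random.default_rng(10)
        eri = _synthetic_eri_table(rng)
        report = run_group_analysis(eri, correction="holm")
        mw = report[report.test == "mann_whitney_u"]
        assert mw["p_adjusted"].notna().all()
        assert (mw["p_adjusted"] >= mw["p_value"] - 1e-15).all()


def test_type_one_error_calibration_under_the_null():
    """Identical generative groups: pairwise Mann-Whitney rejects at the
    nominal 5% rate (no correction), within the binomial 99% interval
    over 200 seeded replicates of three independent group pairs."""
    rng = np.random.default_rng(123)
    n_rep, pairs_per_rep, n = 200, 3, 20
    rejections = 0
    total = n_rep * pairs_per_rep
    for _ in range(n_rep):
        for _ in range(pairs_per_rep):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if mann_whitney_u(x, y).p_value < 0.05:
                rejections += 1
    rate = rejections / total
    half = 2.576 * np.sqrt(0.05 * 0.95 / total)
    assert 0.05 - half <= rate <= 0.05 + half


def test_preset_contrast_is_detectable_at_study_sample_sizes():
    """With ERI spreads matching the synthetic presets (healthy vs
    dysphagic beta-band C3, n = 21 vs 50), Mann-Whitney rejects in at
    least 80% of seeded replicates."""
    from swallow_ersp.synthgen import expected_plateau_db, group_preset
    mu_h = expected_plateau_db(group_preset("healthy"), "C3", "beta")
    mu_d = expected_plateau_db(group_preset("dysphagic"), "C3", "beta")
    rng = np.random.default_rng(321)
    hits = sum(
        mann_whitney_u(rng.normal(mu_h, 0.8, size=21),
                       rng.normal(mu_d, 0.8, size=50)).p_value < 0.05
        for _ in range(100))
    assert hits >= 80
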