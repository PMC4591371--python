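"""FDR control, screens, locus clumping and pattern classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import stratinteract as si
from stratinteract.screening import ScreenSpec, run_screen


def bh_reject_oracle(pvals, q):
    """Classical step-up rejection set at level q, straight from the
    definition: reject all P at or below the largest p_(k) with
    p_(k) <= k q / n."""
    n = len(pvals)
    srt = sorted(pvals)
    kmax = 0
    # the tiny relative slack absorbs float round-trip of the candidate
    # levels; the procedure itself is the textbook step-up
    for k in range(1, n + 1):
        if srt[k - 1] <= k * q / n * (1 + 1e-12):
            kmax = k
    if kmax == 0:
        return [False] * n
    thresh = srt[kmax - 1]
    return [p <= thresh for p in pvals]


def qvalue_oracle(pvals):
    """q_i = smallest level at which marker i is rejected, scanning the
    exhaustive candidate set {p_(j) n / j}."""
    n = len(pvals)
    srt = sorted(pvals)
    candidates = sorted(srt[j] * n / (j + 1) for j in range(n))
    qs = []
    for i in range(n):
        qi = 1.0
        for cand in candidates:
            if bh_reject_oracle(pvals, cand)[i]:
                qi = min(cand, 1.0)
                break
        qs.append(qi)
    return qs


class TestBHFDR:
    def test_hand_example(self):
        q = si.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(si.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert si.bh_fdr([]).size == 0

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=200)
        assert (si.bh_fdr(p) >= p - 1e-15).all()

    @settings(deadline=None, max_examples=80)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_matches_exhaustive_step_up_oracle(self, pvals):
        np.testing.assert_allclose(si.bh_fdr(pvals), qvalue_oracle(pvals),
                                   rtol=1e-12, atol=1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(si.bh_fdr(p), q_sm, rtol=1e-12)


class TestClumping:
    def test_hand_traced_greedy(self):
        df = pd.DataFrame({
            "MARKER": ["a", "b", "c"], "CHR": 1,
            "POS": [1_000_000, 1_300_000, 2_000_000],
            "P": [1e-10, 1e-8, 1e-9]})
        loci = si.clump_loci(df, window=500_000)
        assert len(loci) == 2
        assert [l.lead_marker for l in loci] == ["a", "c"]
        assert loci[0].members == ["a", "b"]
        assert loci[0].lead_p == 1e-10

    def test_single_marker(self):
        df = pd.DataFrame({"MARKER": ["a"], "CHR": 2, "POS": [5], "P": [0.1]})
        loci = si.clump_loci(df)
        assert len(loci) == 1 and loci[0].members == ["a"]

    def test_window_boundary_strict(self):
        df = pd.DataFrame({"MARKER": ["a", "b"], "CHR": 1,
                           "POS": [1_000_000, 1_500_000], "P": [1e-9, 1e-8]})
        assert len(si.clump_loci(df, window=500_000)) == 2
        assert len(si.clump_loci(df, window=500_001)) == 1

    def test_order_invariance(self, rng):
        n = 50
        df = pd.DataFrame({
            "MARKER": [f"m{i}" for i in range(n)],
            "CHR": rng.integers(1, 4, n),
            "POS": rng.integers(1, 5_000_000, n),
            "P": rng.uniform(size=n)})
        base = si.clump_loci(df)
        shuffled = si.clump_loci(df.sample(frac=1, random_state=1))
        assert [l.lead_marker for l in base] == [l.lead_marker for l in shuffled]
        assert [sorted(l.members) for l in base] == \
               [sorted(l.members) for l in shuffled]


def _make_table(n, rng, p_overall=None, p_sexdiff=None):
    from scipy import stats as st_
    df = pd.DataFrame({
        "MARKER": [f"1:{1_000_000 * (i + 1)}" for i in range(n)],
        "CHR": 1, "POS": 1_000_000 * (np.arange(n) + 1),
        "P_overall": p_overall if p_overall is not None
        else rng.uniform(size=n),
        "P_SEXDIFF": p_sexdiff if p_sexdiff is not None
        else rng.uniform(size=n)})
    return df


class TestRunScreen:
    def test_opposite_sign_marker_only_in_unfiltered(self, rng):
        """A marker with equal-magnitude opposite effects in men and women
        cancels in the overall association: the unfiltered sex-difference
        screen finds it, the a-priori-filtered screen cannot."""
        n = 100
        p_overall = rng.uniform(0.2, 1.0, n)
        p_sexdiff = rng.uniform(0.2, 1.0, n)
        p_overall[0] = 0.97      # b_F = +0.05, b_M = -0.05 cancel
        p_sexdiff[0] = 1e-25
        df = _make_table(n, rng, p_overall, p_sexdiff)
        unfiltered = run_screen(df, ScreenSpec(test="sexdiff"))
        filtered = run_screen(df, ScreenSpec(test="sexdiff", prefilter=1e-5))
        assert list(unfiltered.significant["MARKER"]) == ["1:1000000"]
        assert filtered.n_tested == 0
        assert len(filtered.significant) == 0

    def test_dominant_marker_discovered_alone(self, rng):
        n = 10_000
        p = rng.uniform(size=n)
        p[42] = 1e-30
        df = _make_table(n, rng, p_sexdiff=p)
        res = run_screen(df, ScreenSpec(test="sexdiff"))
        assert list(res.significant["MARKER"]) == [df.loc[42, "MARKER"]]

    def test_fdr_denominator_is_filtered_count(self, rng):
        n = 1_000
        p_overall = np.ones(n)
        p_overall[:10] = 1e-7
        p_sex = np.ones(n)
        p_sex[:10] = 0.004       # significant over 10 tests, not over 1000
        df = _make_table(n, rng, p_overall, p_sex)
        filtered = run_screen(df, ScreenSpec(test="sexdiff", prefilter=1e-5))
        assert filtered.n_tested == 10
        assert len(filtered.significant) == 10
        unfiltered = run_screen(df, ScreenSpec(test="sexdiff"))
        assert len(unfiltered.significant) == 0

    def test_null_fdr_control_across_replicates(self):
        """Global null: the chance of any discovery at q < 0.05 equals the
        FDR level, so most replicates yield zero discoveries."""
        n, reps = 10_000, 200
        rng = np.random.default_rng(77)
        zero = 0
        any_count = 0
        for _ in range(reps):
            q = si.bh_fdr(rng.uniform(size=n))
            k = (q < 0.05).sum()
            zero += k == 0
            any_count += k > 0
        # P(any) = 0.05 exactly under independence: 3.3-sigma band
        band = 3.3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(any_count / reps - 0.05) < band
        assert zero / reps > 0.9

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            ScreenSpec(test="banana")

    def test_main_effect_screen_fixed_threshold(self, rng):
        n = 500
        p = rng.uniform(size=n)
        p[3], p[7] = 1e-9, 4e-8
        df = _make_table(n, rng, p_overall=p)
        res = run_screen(df, ScreenSpec(test="overall", fdr_q=None,
                                        threshold=5e-8))
        assert set(res.significant["MARKER"]) == {df.loc[3, "MARKER"],
                                                  df.loc[7, "MARKER"]}

    def test_novelty_flagging(self, rng):
        df = _make_table(3, rng, p_sexdiff=np.array([1e-10, 0.5, 1e-12]))
        known = pd.DataFrame({"CHR": [1], "START": [900_000],
                              "END": [1_100_000]})
        res = run_screen(df, ScreenSpec(test="sexdiff"), known=known)
        flags = {l.lead_marker: l.novel for l in res.loci}
        assert flags["1:1000000"] is False   # within 500kb of known interval
        assert flags["1:3000000"] is True


class TestClassifyPattern:
    def test_stronger_in_women(self):
        # one sex carries the effect, the other is null
        label = si.classify_pattern(0.063, 5.2e-36, 0.000, 0.98, axis="sex")
        assert label == "stronger-in-women"

    def test_opposite(self):
        label = si.classify_pattern(-0.017, 2.0e-4, 0.018, 4.1e-4, axis="sex")
        assert label == "opposite"

    def test_tie_prefers_first_group(self):
        assert si.classify_pattern(0.02, 0.5, -0.02, 0.5,
                                   axis="sex") == "stronger-in-women"
        assert si.classify_pattern(0.02, 0.5, -0.02, 0.5,
                                   axis="age") == "stronger-in-younger"

    def test_age_axis_labels(self):
        assert si.classify_pattern(0.04, 1e-10, 0.01, 0.2,
                                   axis="age") == "stronger-in-younger"
        assert si.classify_pattern(-0.001, 0.9, 0.02, 1e-9,
                                   axis="age") == "stronger-in-older"
        assert si.classify_pattern(0.02, 0.001, -0.02, 0.001,
                                   axis="age") == "opposite-by-age"


class TestScreenUnionConsistency:
    def test_no_leakage_between_screens(self, planted_consortium):
        """Every discovery of every screen satisfies its own criterion."""
        _, _, results = planted_consortium
        for name, res in results.run_default_screens().items():
            col = si.screening.TEST_COLUMNS[res.spec.test]
            if res.spec.threshold is not None:
                assert (res.significant[col] < res.spec.threshold).all()
            else:
                assert (res.significant["Q"] < res.spec.fdr_q).all()
            if res.spec.prefilter is not None:
                assert (res.significant["P_overall"] < res.spec.prefilter).all()
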