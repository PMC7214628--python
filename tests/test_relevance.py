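import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import piecewisefc as pfc
from piecewisefc.errors import ParameterError, ValidationError


def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating every rank split.

    Uses the symmetry of the null distribution of U around n*m/2.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    dev_obs = abs(u_obs - n * m / 2)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - n * m / 2) >= dev_obs - 1e-12:
            count += 1
    return count / total


def bh_oracle(pvals, alpha):
    """Benjamini-Hochberg step-up by the textbook rule."""
    pvals = np.asarray(pvals, float)
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= alpha * rank / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        U, p = pfc.mannwhitney_p([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70, rel=1e-9)

    def test_identical_samples_p_one(self):
        _, p = pfc.mannwhitney_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @given(seed=st.integers(0, 10 ** 6), n=st.integers(2, 6))
    def test_exact_path_matches_enumeration(self, seed, n):
        g = np.random.default_rng(seed)
        a, b = g.random(n), g.random(n)
        _, p = pfc.mannwhitney_p(a, b)
        assert p == pytest.approx(mw_exact_oracle(a, b), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            pfc.mannwhitney_p([], [1, 2])

    def test_large_samples_use_tie_corrected_approximation(self):
        g = np.random.default_rng(0)
        a = g.integers(0, 5, size=20).astype(float)  # heavy ties
        b = a + 1.0
        _, p = pfc.mannwhitney_p(a, b)
        assert 0.0 < p < 0.05


class TestFDR:
    def test_step_up_by_hand(self):
        mask = pfc.fdr_bh([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert mask.tolist() == [True, True, True, False]

    def test_all_ones_reject_none(self):
        assert not pfc.fdr_bh([1.0, 1.0, 1.0], 0.05).any()

    def test_boundary_equality_rejected(self):
        assert pfc.fdr_bh([0.05], 0.05).tolist() == [True]

    @given(seed=st.integers(0, 10 ** 6), m=st.integers(1, 30))
    def test_matches_brute_force_step_up(self, seed, m):
        g = np.random.default_rng(seed)
        p = g.random(m)
        np.testing.assert_array_equal(pfc.fdr_bh(p, 0.05), bh_oracle(p, 0.05))

    @given(seed=st.integers(0, 10 ** 5))
    def test_between_bonferroni_and_uncorrected(self, seed):
        g = np.random.default_rng(seed)
        p = g.random(15)
        bh = pfc.fdr_bh(p, 0.05)
        bonf = p <= 0.05 / len(p)
        assert np.all(bh[bonf])          # superset of Bonferroni
        assert np.all(p[bh] <= 0.05)     # subset of uncorrected


class TestPUTh:
    def _wc(self, subject_means):
        # one window, M=1 subject carrying the stated per-link means
        vals = np.asarray(subject_means, float)[None, None, :]
        scheme = pfc.whole_window((0.0, 1.0))
        return pfc.WindowedConnectivity(vals, scheme)

    def test_hand_case(self):
        mask = pfc.puth(self._wc([0.9, 0.7, 0.5, 0.2]), q=0.7)
        assert mask.values[0].tolist() == [True, True, False, False]

    def test_q_zero_selects_all_q_one_only_max(self):
        wc = self._wc([0.9, 0.7, 0.5, 0.2])
        assert pfc.puth(wc, 0.0).values.all()
        assert pfc.puth(wc, 1.0).values[0].tolist() == \
            [True, False, False, False]

    @given(seed=st.integers(0, 10 ** 5))
    def test_monotone_in_q(self, seed):
        g = np.random.default_rng(seed)
        wc = pfc.WindowedConnectivity(g.random((3, 2, 8)),
                                      pfc.make_fixed_windows((0, 1), 0.5))
        prev = None
        for q in (0.4, 0.6, 0.8, 0.9):
            mask = pfc.puth(wc, q).values
            if prev is not None:
                assert np.all(mask <= prev)  # raising q never adds links
            prev = mask

    def test_invalid_q(self):
        with pytest.raises(ParameterError):
            pfc.puth(self._wc([0.5]), 1.5)


def _labelled_wc(target, nontarget, scheme=None):
    """Build labelled WindowedConnectivity from (M, N_w, V) arrays."""
    target = np.asarray(target, float)
    nontarget = np.asarray(nontarget, float)
    vals = np.stack([nontarget, target], axis=-1)
    if scheme is None:
        scheme = pfc.make_fixed_windows((0.0, 1.0), 1.0 / target.shape[1])
    return pfc.WindowedConnectivity(vals, scheme, conditions=(0, 1))


class TestPSThAcrossSubjects:
    def test_planted_link_detected(self, planted_windowed):
        wc, truth = planted_windowed
        mask, tests = pfc.psth_across_subjects(wc, alpha=0.05)
        v = int(np.flatnonzero(truth.link_mask())[0])
        assert mask.values[:, v].any()
        # and detection happens in a window overlapping the coupling
        hit = truth.window_link_mask(wc.scheme.intervals)[:, v]
        assert (mask.values[:, v] & hit).any()

    def test_identical_conditions_select_nothing(self, rng):
        base = rng.random((6, 2, 5))
        mask, _ = pfc.psth_across_subjects(_labelled_wc(base, base))
        assert not mask.values.any()

    def test_requires_labels_and_enough_subjects(self, rng):
        wc = pfc.WindowedConnectivity(rng.random((6, 2, 5)),
                                      pfc.make_fixed_windows((0, 1), 0.5))
        with pytest.raises(ValidationError):
            pfc.psth_across_subjects(wc)
        small = _labelled_wc(rng.random((3, 2, 5)), rng.random((3, 2, 5)))
        with pytest.raises(ParameterError, match="M >= 4"):
            pfc.psth_across_subjects(small)


class TestPSThAcrossWindows:
    def test_uniformly_larger_target_series_detected(self, rng):
        M, Nw, V = 2, 6, 4
        non = 0.2 + 0.05 * rng.random((M, Nw, V))
        tgt = non.copy()
        tgt[:, :, 0] += 0.5  # one link separated in every window
        mask, _ = pfc.psth_across_windows(_labelled_wc(tgt, non), 0.05)
        assert mask.values[:, 0].all()
        assert not mask.values[:, 1:].any()

    def test_constant_equal_series_not_selected(self):
        vals = np.full((2, 6, 3), 0.4)
        mask, _ = pfc.psth_across_windows(_labelled_wc(vals, vals))
        assert not mask.values.any()

    def test_too_few_windows_rejected(self, rng):
        wc = _labelled_wc(rng.random((2, 2, 3)), rng.random((2, 2, 3)))
        with pytest.raises(ParameterError, match="3 windows"):
            pfc.psth_across_windows(wc)

    def test_shared_kernel_with_across_subjects(self, rng):
        """Transposing subject/window axes maps one test onto the other."""
        M, Nw, V = 5, 5, 4
        tgt, non = rng.random((M, Nw, V)), rng.random((M, Nw, V))
        wc = _labelled_wc(tgt, non)
        m_sub, t_sub = pfc.psth_across_windows(wc, 0.05)
        wc_T = _labelled_wc(tgt.transpose(1, 0, 2), non.transpose(1, 0, 2),
                            scheme=pfc.make_fixed_windows((0, 1), 1.0 / M))
        m_win, t_win = pfc.psth_across_subjects(wc_T, 0.05)
        np.testing.assert_array_equal(m_sub.values, m_win.values)
        np.testing.assert_allclose(t_sub["p"], t_win["p"])


class TestCombineRelevance:
    def test_and_of_ors(self):
        wm = np.array([[1, 0], [0, 0]], bool)
        sm = np.array([[0, 0], [0, 0]], bool)
        assert pfc.combine_relevance(wm, sm).values.tolist() == [False, False]
        sm[1, 0] = True
        assert pfc.combine_relevance(wm, sm).values.tolist() == [True, False]

    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_boolean_oracle(self, seed):
        g = np.random.default_rng(seed)
        wm = g.random((4, 6)) < 0.3
        sm = g.random((5, 6)) < 0.3
        got = pfc.combine_relevance(wm, sm).values
        for v in range(6):
            expect = any(wm[i, v] for i in range(4)) and \
                any(sm[m, v] for m in range(5))
            assert got[v] == expect

    @given(seed=st.integers(0, 10 ** 5))
    def test_invariant_to_mask_order(self, seed):
        g = np.random.default_rng(seed)
        wm = g.random((4, 6)) < 0.4
        sm = g.random((3, 6)) < 0.4
        base = pfc.combine_relevance(wm, sm).values
        perm = pfc.combine_relevance(wm[g.permutation(4)],
                                     sm[g.permutation(3)]).values
        np.testing.assert_array_equal(base, perm)

    def test_dimension_mismatch(self):
        with pytest.raises(ParameterError, match="link dimensions"):
            pfc.combine_relevance(np.zeros((2, 5), bool),
                                  np.zeros((2, 4), bool))


class TestFullPSTh:
    def test_planted_link_in_combined_mask(self, planted_windowed):
        wc, truth = planted_windowed
        res = pfc.psth(wc, alpha=0.05)
        v = int(np.flatnonzero(truth.link_mask())[0])
        assert res["combined"].values[v]

    def test_confidence_summary_on_selection(self, planted_windowed):
        wc, _ = planted_windowed
        res = pfc.psth(wc, alpha=0.05)
        summary = pfc.confidence_summary(res["tests_windows"],
                                         res["combined"])
        assert 0 <= summary["min_p"] <= summary["median_p"] \
            <= summary["max_p"] <= 1

    def test_link_table_export(self, planted_windowed, tmp_path):
        wc, _ = planted_windowed
        res = pfc.psth(wc, alpha=0.05)
        from piecewisefc.relevance import export_link_table
        names = [f"ch{i:02d}" for i in range(6)]
        tab = export_link_table(tmp_path / "t.tsv", wc,
                                res["tests_windows"], names)
        assert (tmp_path / "t.tsv").exists()
        assert list(tab.columns)[:5] == ["band", "window_start", "window_end",
                                         "ch_a", "ch_b"]
        assert len(tab) == wc.n_windows * wc.n_links
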