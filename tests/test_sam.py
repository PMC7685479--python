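"""The permutation SAM procedure, checked against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from driverscan.sam import (SamConfig, UntestableGroup, call_significant,
                            compute_stats, estimate_fdr, estimate_pi0,
                            estimate_s0, fit_sam, permute, run_sam)


def brute_force_call(d, dbar, delta):
    """Independent O(n^2) rank scan of the thresholding rule."""
    n = len(d)
    order = sorted(range(n), key=lambda i: d[i])
    dsort = [d[i] for i in order]
    cut_up, cut_low = math.inf, -math.inf
    for k in range(n):
        if dsort[k] >= 0 and dsort[k] - dbar[k] > delta:
            cut_up = min(cut_up, dsort[k])
        if dsort[k] <= 0 and dbar[k] - dsort[k] > delta:
            cut_low = max(cut_low, dsort[k])
    up = {i for i in range(n) if d[i] >= cut_up}
    down = {i for i in range(n) if d[i] <= cut_low and i not in up}
    return cut_up, cut_low, up, down


def test_compute_stats_hand_example():
    x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
    labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
    r, s, d = compute_stats(x, labels, s0=0.0)
    assert r[0] == pytest.approx(3.0)
    assert s[0] == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-12)
    assert d[0] == pytest.approx(3.674235, abs=1e-6)


def test_compute_stats_zero_difference_and_s0_limit():
    x = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
    labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
    _, _, d = compute_stats(x, labels, s0=0.0)
    assert d[0] == 0.0
    rng = np.random.default_rng(2)
    x = rng.normal(size=(50, 12))
    labels = np.array([0] * 6 + [1] * 6, dtype=bool)
    prev = None
    for s0 in [0.0, 0.5, 2.0, 10.0, 1e6]:
        _, _, d = compute_stats(x, labels, s0=s0)
        mag = np.abs(d)
        if prev is not None:
            assert (mag <= prev + 1e-15).all()
        prev = mag
    assert np.abs(d).max() < 1e-4  # d -> 0 as s0 -> inf


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), n1=st.integers(3, 8), n2=st.integers(3, 8))
def test_d_ranking_equals_pooled_t_ranking(seed, n1, n2):
    """With s0 = 0 the moderated statistic IS the pooled-variance t statistic."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(30, n1 + n2))
    labels = np.array([0] * n1 + [1] * n2, dtype=bool)
    _, _, d = compute_stats(x, labels, s0=0.0)
    t = sps.ttest_ind(x[:, labels], x[:, ~labels], axis=1, equal_var=True).statistic
    assert np.allclose(d, t, atol=1e-10)
    assert (np.argsort(d) == np.argsort(t)).all()


class TestEstimateS0:
    def test_all_scatters_equal_ties_to_common_value(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=100)
        s = np.full(100, 0.7)
        assert estimate_s0(r, s) == pytest.approx(0.7)

    def test_small_gene_count_falls_back_to_median(self):
        rng = np.random.default_rng(1)
        r, s = rng.normal(size=10), rng.uniform(0.5, 2.0, size=10)
        assert estimate_s0(r, s) == pytest.approx(float(np.median(s)))

    def test_heavy_mean_variance_dependence_yields_positive_s0(self):
        rng = np.random.default_rng(8)
        s = np.exp(rng.normal(-2, 1.5, size=500))  # scatters spanning orders of magnitude
        r = rng.normal(size=500) * 0.2
        s0 = estimate_s0(r, s)
        assert s0 > 0

        def cv(s0_val):  # independent re-evaluation of the criterion
            d = r / (s + s0_val)
            order = np.argsort(s)
            mads = [np.median(np.abs(d[w] - np.median(d[w])))
                    for w in np.array_split(order, 100)]
            return np.std(mads) / np.mean(mads)

        assert cv(s0) <= cv(0.0) + 1e-12


class TestPermute:
    def test_exhaustive_enumeration_when_small(self):
        labels = np.array([1, 1, 0, 0, 0], dtype=bool)
        sets, exact = permute(labels, B=100, seed=0)
        assert exact and sets.shape == (10, 5)  # C(5,2) = 10
        seen = {tuple(row.tolist()) for row in sets}
        assert len(seen) == 10
        assert all(row.sum() == 2 for row in sets)

    def test_sampled_distinct_and_seeded(self):
        labels = np.zeros(30, dtype=bool)
        labels[:10] = True
        a, exact = permute(labels, B=100, seed=42)
        b, _ = permute(labels, B=100, seed=42)
        c, _ = permute(labels, B=100, seed=43)
        assert not exact and a.shape == (100, 30)
        assert len({tuple(r.tolist()) for r in a}) == 100
        assert (a == b).all() and not (a == c).all()

    def test_single_draw_is_uniform_over_assignments(self):
        """chi-square over all C(5,2)=10 assignments across many seeds."""
        labels = np.array([1, 1, 0, 0, 0, 0], dtype=bool)  # C(6,2)=15 > B=1
        counts = {}
        n_seeds = 10_000
        for seed in range(n_seeds):
            sets, _ = permute(labels, B=1, seed=seed)
            key = tuple(np.flatnonzero(sets[0]).tolist())
            counts[key] = counts.get(key, 0) + 1
        observed = np.array(list(counts.values()))
        assert len(counts) == 15
        chi2 = ((observed - n_seeds / 15) ** 2 / (n_seeds / 15)).sum()
        assert sps.chi2.sf(chi2, df=14) > 1e-4


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(20, 12))
    x[:4, 6:] += 2.5
    labels = np.array([0] * 6 + [1] * 6, dtype=bool)
    return fit_sam(x, labels, SamConfig(n_permutations=5, seed=3))


class TestCallSignificant:

    def test_delta_zero_calls_everything_off_diagonal(self, fit):
        call = call_significant(fit, 0.0)
        brute = brute_force_call(fit.d, fit.dbar, 0.0)
        assert set(call.significant_up) == {fit.genes[i] for i in brute[2]}
        assert set(call.significant_down) == {fit.genes[i] for i in brute[3]}

    def test_huge_delta_calls_nothing(self, fit):
        order = np.argsort(fit.d)
        delta = float(np.abs(fit.d[order] - fit.dbar).max()) + 1.0
        call = call_significant(fit, delta)
        assert call.n_called == 0
        assert call.cut_up == math.inf and call.cut_low == -math.inf
        assert call.fdr_estimate == 0.0  # no calls -> defined 0

    @pytest.mark.parametrize("delta_frac", [0.1, 0.3, 0.5, 0.8])
    def test_matches_brute_force_scan(self, fit, delta_frac):
        order = np.argsort(fit.d)
        delta = delta_frac * float(np.abs(fit.d[order] - fit.dbar).max())
        call = call_significant(fit, delta)
        cut_up, cut_low, up, down = brute_force_call(fit.d, fit.dbar, delta)
        assert call.cut_up == pytest.approx(cut_up)
        assert call.cut_low == pytest.approx(cut_low)
        assert set(call.significant_up) == {fit.genes[i] for i in up}
        assert set(call.significant_down) == {fit.genes[i] for i in down}
        assert not set(call.significant_up) & set(call.significant_down)

    def test_n_called_nonincreasing_in_delta(self, fit):
        order = np.argsort(fit.d)
        max_dev = float(np.abs(fit.d[order] - fit.dbar).max())
        counts = [call_significant(fit, d).n_called
                  for d in np.linspace(0, max_dev, 25)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPi0AndFdr:
    def test_pi0_near_one_under_complete_null(self):
        rng = np.random.default_rng(0)
        values = [estimate_pi0(rng.normal(size=1000), rng.normal(size=(50, 1000)))
                  for _ in range(40)]
        assert 0.95 < np.mean(values) <= 1.0

    def test_pi0_boundary_cases(self):
        perm = np.linspace(-1, 1, 400).reshape(4, 100)
        outside = np.full(100, 5.0)
        assert estimate_pi0(outside, perm) == 0.0
        q25, q75 = np.percentile(perm, [25, 75])
        half_inside = np.concatenate([np.full(50, (q25 + q75) / 2), np.full(50, 10.0)])
        assert estimate_pi0(half_inside, perm) == 1.0  # capped from #/(0.5 n) = 1

    def test_fdr_matches_exhaustive_tally(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(50, 14))
        x[:5, 7:] += 2.0
        labels = np.array([0] * 7 + [1] * 7, dtype=bool)
        fit = fit_sam(x, labels, SamConfig(n_permutations=10, seed=5))
        call = call_significant(fit, 0.3)
        v = []
        for b in range(fit.perm_d.shape[0]):
            v.append(sum(1 for val in fit.perm_d[b]
                         if val >= call.cut_up or val <= call.cut_low))
        expected = call.pi0 * float(np.median(v)) / call.n_called if call.n_called else 0.0
        assert estimate_fdr(call, fit) == pytest.approx(expected)


class TestRunSam:
    def test_planted_targets_recovered(self):
        rng = np.random.default_rng(101)
        n_genes, n = 200, 60
        targets = list(range(30))
        x = rng.normal(size=(n_genes, n))
        labels = np.zeros(n, dtype=bool)
        labels[:20] = True
        for t in targets:
            x[t, labels] += 2.0
        call = run_sam(x, labels, SamConfig(seed=9))
        up = {int(g[1:]) for g in call.significant_up}
        recovered = up & set(targets)
        assert len(recovered) == 30  # every planted target, pinned oracle run
        extras = (up | {int(g[1:]) for g in call.significant_down}) - set(targets)
        # pinned from the oracle run at this seed: 11 extras among 41 calls,
        # consistent with the run's estimated FDR of 0.18
        assert len(extras) == 11
        assert call.fdr_estimate <= 0.2

    def test_determinism_and_untestable(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 20))
        labels = np.zeros(20, dtype=bool)
        labels[:6] = True
        a = run_sam(x, labels, SamConfig(seed=4))
        b = run_sam(x, labels, SamConfig(seed=4))
        assert a == b
        two = np.zeros(20, dtype=bool)
        two[:2] = True
        with pytest.raises(UntestableGroup):
            run_sam(x, two, SamConfig(seed=4))

    def test_negating_expression_swaps_directions(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(80, 24))
        x[:10, 12:] += 1.5
        labels = np.array([0] * 12 + [1] * 12, dtype=bool)
        cfg = SamConfig(seed=6)
        call = run_sam(x, labels, cfg)
        flipped = run_sam(-x, labels, cfg)
        assert set(call.significant_up) == set(flipped.significant_down)
        assert set(call.significant_down) == set(flipped.significant_up)

    def test_exact_enumeration_is_seed_invariant(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=(30, 8))
        x[:5, 5:] += 2.5
        labels = np.zeros(8, dtype=bool)
        labels[5:] = True  # C(8,3) = 56 <= B = 100: exhaustive
        calls = [run_sam(x, labels, SamConfig(seed=s)) for s in (1, 99)]
        assert calls[0] == calls[1]
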