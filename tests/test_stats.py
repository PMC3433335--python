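"""Uncertainty (analytic + bootstrap) and Specificity statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from npascore.contrasts import bh_fdr
from npascore.hyp import DownstreamEdge, Hyp
from npascore.scoring import gpi, strength
from npascore.stats import (
    StatsError,
    bootstrap_ci,
    build_cadres,
    gamma_weights,
    gpi_ci,
    specificity,
    strength_ci,
    two_tailed_p,
    welch_satterthwaite,
)
from npascore.synthetic import SyntheticSpec, generate_contrast, generate_hyp, generate_universe

from conftest import matched


class TestWelchSatterthwaite:
    def test_equal_variance_gives_n_times_df(self):
        n = 10
        df = welch_satterthwaite(np.full(n, 1 / n), np.ones(n), np.full(n, 4.0))
        assert df == pytest.approx(40.0, abs=1e-12)

    def test_single_term_returns_own_df(self):
        assert welch_satterthwaite([2.0], [0.5], [7.0]) == pytest.approx(7.0)

    def test_hand_computed_example(self):
        df = welch_satterthwaite([0.5, 0.5], [1.0, 2.0], [2.0, 10.0])
        assert df == pytest.approx(1.5625 / 0.13125, abs=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(StatsError):
            welch_satterthwaite([1.0], [0.0], [2.0])
        with pytest.raises(StatsError):
            welch_satterthwaite([], [], [])


class TestStrengthCI:
    def test_closed_form_two_gene_case(self):
        m = matched([1, 1], [1.0, 1.0], sd=[1.0, 1.0], df=[10.0, 10.0])
        res = strength_ci(m, alpha=0.05)
        assert res.value == pytest.approx(1.0)
        sd = np.sqrt(0.5)
        assert res.eff_df == pytest.approx(20.0)
        tq = sps.t.ppf(0.975, 20.0)
        assert res.ci_low == pytest.approx(1.0 - tq * sd)
        assert res.ci_high == pytest.approx(1.0 + tq * sd)

    def test_zero_variance_collapses(self):
        m = matched([1, -1], [1.0, 2.0], sd=[0.0, 0.0], df=[5.0, 5.0])
        res = strength_ci(m)
        assert res.ci_low == res.ci_high == res.value

    def test_larger_alpha_narrower_interval(self):
        m = matched([1, 1, 1], [0.5, 0.2, 0.9], sd=[0.3] * 3, df=[8.0] * 3)
        wide = strength_ci(m, alpha=0.05)
        narrow = strength_ci(m, alpha=0.5)
        assert narrow.ci_high - narrow.ci_low < wide.ci_high - wide.ci_low


def gamma_fd_oracle(m, h=1e-6):
    """Central finite difference of fndr(beta)*beta holding the BH factor fixed."""
    out = np.empty(m.n_used)
    for i in range(m.n_used):
        ratio = m.fdr[i] / m.p[i] if m.fdr[i] > 0 else 0.0

        def f(b):
            p = 2.0 * sps.t.sf(abs(b / m.sd[i]), m.df[i])
            return (1.0 - ratio * p) * b

        step = h * max(1.0, abs(m.beta[i]))
        out[i] = (f(m.beta[i] + step) - f(m.beta[i] - step)) / (2 * step)
    return out


class TestGpiCI:
    def make_input(self, seed=0, n=5):
        rng = np.random.default_rng(seed)
        s = rng.choice([1, -1], size=n)
        sd = rng.uniform(0.2, 0.6, size=n)
        beta = rng.normal(0, 1, size=n)
        df = np.full(n, 10.0)
        p = 2.0 * sps.t.sf(np.abs(beta / sd), df)
        fdr = bh_fdr(p)
        return matched(s, beta, sd=sd, df=df, p=p, fdr=fdr)

    def test_gamma_matches_finite_difference_oracle(self):
        for seed in range(5):
            m = self.make_input(seed)
            assert np.allclose(gamma_weights(m), gamma_fd_oracle(m), atol=1e-4)

    def test_fdr_zero_reduces_to_scaled_strength_ci(self):
        n = 4
        m = matched([1, -1, 1, 1], [1.0, -2.0, 0.5, 1.5], sd=[0.3] * n,
                    df=[12.0] * n, p=[1e-9] * n, fdr=[0.0] * n)
        res = gpi_ci(m)
        assert np.allclose(gamma_weights(m), 1.0)
        # Sd_GPI^2 = (1/N) sum sd^2 = N * Sd_Strength^2
        s_res = strength_ci(m)
        assert res.value == pytest.approx(np.sqrt(n) * s_res.value)
        assert (res.ci_high - res.ci_low) == pytest.approx(
            np.sqrt(n) * (s_res.ci_high - s_res.ci_low))
        assert res.eff_df == pytest.approx(s_res.eff_df)

    def test_zero_sd_collapses(self):
        m = matched([1], [1.0], sd=[0.0], df=[5.0], p=[0.01], fdr=[0.01])
        res = gpi_ci(m)
        assert res.ci_low == res.ci_high == res.value

    def test_p_zero_with_positive_fdr_rejected(self):
        m = matched([1], [1.0], sd=[0.5], df=[5.0], p=[0.0], fdr=[0.5])
        with pytest.raises(StatsError):
            gpi_ci(m)


class TestBootstrapCI:
    def test_degenerate_zero_sd(self):
        m = matched([1, -1], [1.0, 0.5], sd=[0.0, 0.0], df=[5.0] * 2,
                    treated=[4.0, 2.0], control=[2.0, 4.0])
        res = bootstrap_ci(m, "mass", B=200, seed=1)
        assert res.ci_low == res.ci_high == res.value

    def test_b_floor_enforced(self):
        m = matched([1], [1.0], sd=[0.5])
        with pytest.raises(StatsError):
            bootstrap_ci(m, "strength", B=50)

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        m = matched(rng.choice([1, -1], 20), rng.normal(size=20),
                    sd=np.full(20, 0.4))
        r1 = bootstrap_ci(m, "strength", B=500, seed=9)
        r2 = bootstrap_ci(m, "strength", B=500, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_strength_bc_close_to_analytic(self):
        """BC percentile interval tracks the analytic t interval (N=50, B=4000)."""
        rng = np.random.default_rng(21)
        n = 50
        m = matched(rng.choice([1, -1], n), rng.normal(0.5, 0.5, n),
                    sd=np.full(n, 0.5), df=np.full(n, 10.0))
        analytic = strength_ci(m)
        boot = bootstrap_ci(m, "strength", B=4000, seed=3)
        w_a = analytic.ci_high - analytic.ci_low
        w_b = boot.ci_high - boot.ci_low
        assert abs(w_b - w_a) / w_a < 0.05
        assert abs(boot.ci_low - analytic.ci_low) < 0.05 * w_a

    def test_mass_bootstrap_abundances_stay_positive(self):
        rng = np.random.default_rng(2)
        n = 10
        m = matched(rng.choice([1, -1], n), rng.normal(0, 1, n),
                    sd=np.full(n, 1.0), treated=rng.uniform(1, 50, n),
                    control=rng.uniform(1, 50, n))
        res = bootstrap_ci(m, "mass", B=300, seed=4)
        # MASS is bounded by 2 in absolute value; resampled abundances >= 0
        assert -2.0 <= res.ci_low <= res.ci_high <= 2.0


class TestCadres:
    def test_remainder_merged_into_last(self):
        counts = {f"g{i:03d}": i for i in range(250)}
        idx = build_cadres(counts, cadre_size=100)
        assert [len(c) for c in idx.cadres] == [100, 150]
        # first cadre holds the highest controller counts
        assert min(counts[g] for g in idx.cadres[0]) >= max(
            counts[g] for g in idx.cadres[1])

    @pytest.mark.parametrize("n,expected", [(100, [100]), (199, [199]),
                                            (300, [100, 100, 100])])
    def test_cadre_sizes(self, n, expected):
        counts = {f"g{i:04d}": i % 17 for i in range(n)}
        assert [len(c) for c in build_cadres(counts, cadre_size=100).cadres] == expected

    def test_partition_property(self):
        counts = {f"g{i:04d}": i % 11 for i in range(437)}
        idx = build_cadres(counts, cadre_size=100)
        all_genes = [g for c in idx.cadres for g in c]
        assert len(all_genes) == len(set(all_genes)) == 437
        assert set(all_genes) == set(counts)

    def test_too_few_genes(self):
        with pytest.raises(StatsError):
            build_cadres({"a": 1}, cadre_size=100)


class TestTwoTailedP:
    def test_counting_rule(self):
        null = np.concatenate([np.full(975, -1.0), np.full(25, 1.0)])
        assert two_tailed_p(null, 0.0) == pytest.approx(0.05)

    def test_centered_observation(self):
        null = np.concatenate([np.full(500, -1.0), np.full(500, 1.0)])
        assert two_tailed_p(null, 0.0) == 1.0

    def test_ties_in_neither_tail(self):
        null = np.array([0.0] * 10 + [1.0] * 2 + [-1.0] * 8)
        assert two_tailed_p(null, 0.0) == pytest.approx(2 * 2 / 20)


@pytest.fixture(scope="module")
def study():
    spec = SyntheticSpec(n_background=600, n_downstream=50, amplitude=1.0,
                         noise_sd=0.5, seed=3)
    universe, counts = generate_universe(spec)
    h = generate_hyp(spec, universe)
    c = generate_contrast(h, universe, spec)
    cadres = build_cadres(counts, set(universe), cadre_size=100)
    return h, c, cadres


class TestSpecificity:
    def test_perturbed_hyp_is_specific(self, study):
        h, c, cadres = study
        p = specificity(h, c, "strength", cadres, n_null=200, seed=0)
        assert p < 0.05

    def test_reproducible_and_order_invariant(self, study):
        h, c, cadres = study
        p1 = specificity(h, c, "strength", cadres, n_null=150, seed=8)
        p2 = specificity(h, c, "strength", cadres, n_null=150, seed=8)
        assert p1 == p2
        shuffled = Hyp(h.upstream, list(reversed(h.downstreams)))
        p3 = specificity(shuffled, c, "strength", cadres, n_null=150, seed=8)
        assert p3 == p1

    def test_gpi_and_mass_methods_run(self, study):
        h, c, cadres = study
        for method in ("gpi", "mass", "epi"):
            p = specificity(h, c, method, cadres, n_null=100, seed=1)
            assert 0.0 <= p <= 1.0

    def test_hyp_gene_outside_universe_rejected(self, study):
        h, c, cadres = study
        bad = Hyp("U", [DownstreamEdge("NOT_A_GENE", 1)])
        with pytest.raises(Exception):
            specificity(bad, c, "strength", cadres, n_null=100, seed=0)

    def test_replacements_never_reuse_original_position_gene(self, study):
        """Comparable HYPs use different genes with matched controller counts."""
        from npascore.stats import _comparable_indices

        rng = np.random.default_rng(0)
        orig_idx = np.arange(10)
        positions = {0: np.arange(10)}
        pools = {0: np.arange(12)}
        for _ in range(50):
            pick = _comparable_indices(positions, orig_idx, pools, rng)
            assert len(set(pick)) == 10  # unique within the comparable HYP
            assert np.all(pick != orig_idx)  # never the original gene
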