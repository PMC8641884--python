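"""The synthetic designs reproduce their stated moments and dependence
structure: DE-equivalent genes whose only distinguishing property is joint."""

import math

import numpy as np
import pytest
from scipy import stats

from dfcselect import (
    Case1Design,
    Case2Design,
    generate_case1,
    generate_case2,
    generate_two_population_counts,
    mixture_moments,
)


class TestMixtureMoments:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0, 5, 1, 1, 2 / 3), (5 / 3, 59 / 9)),
            ((3.2, 3.2, 0.7, 0.7, 0.25), (3.2, 0.7)),  # identical components
            ((0, 4, 1, 2, 0.5), (2.0, 5.5)),
            ((1, 9, 2, 3, 1.0), (1.0, 2.0)),  # degenerate p=1 collapses to comp 1
        ],
    )
    def test_closed_form(self, args, expected):
        mu, s2 = mixture_moments(*args)
        assert mu == pytest.approx(expected[0], rel=1e-12)
        assert s2 == pytest.approx(expected[1], rel=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            mixture_moments(0, 5, 1, 1, 1.2)


class TestCase1:
    def test_deterministic(self):
        a = generate_case1(seed=5).matrix.values
        b = generate_case1(seed=5).matrix.values
        np.testing.assert_array_equal(a, b)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            Case1Design(rho=1.0)
        with pytest.raises(ValueError):
            Case1Design(sigma2=0.0)
        with pytest.raises(ValueError):
            Case1Design(n_per_group=1)

    def test_within_group_correlation(self, case1):
        # corr(X3, X4) ~ 0.7 in each group within 3 SE (SE ~ (1-rho^2)/sqrt(n))
        se = (1 - 0.7**2) / math.sqrt(1000)
        for grp in ("A", "B"):
            sub = case1.matrix.values[case1.group == grp]
            r = np.corrcoef(sub[:, 2], sub[:, 3])[0, 1]
            assert abs(r - 0.7) < 3 * se

    def test_rho_zero_all_independent(self):
        ds = generate_case1(Case1Design(rho=0.0, seed=3))
        for grp in ("A", "B"):
            sub = ds.matrix.values[ds.group == grp]
            c = np.corrcoef(sub.T)
            off = c[~np.eye(4, dtype=bool)]
            assert np.max(np.abs(off)) < 3.5 / math.sqrt(1000)

    def test_moments_over_seeds(self):
        # aggregated over 50 seeds the per-variable variance and |mean gap|
        # match (1, 2) within 3 closed-form standard errors
        n, n_seeds = 200, 50
        gaps = np.zeros((n_seeds, 4))
        var = np.zeros((n_seeds, 4))
        for s in range(n_seeds):
            ds = generate_case1(Case1Design(n_per_group=n, seed=s))
            a = ds.matrix.values[ds.group == "A"]
            b = ds.matrix.values[ds.group == "B"]
            gaps[s] = np.abs(a.mean(0) - b.mean(0))
            var[s] = (a.var(0, ddof=1) + b.var(0, ddof=1)) / 2
        se_gap = math.sqrt(2.0 / n / n_seeds)  # var of mean-difference / seeds
        se_var = math.sqrt(2.0 / (2 * (n - 1)) / n_seeds)  # var of pooled s^2
        assert np.all(np.abs(gaps.mean(0) - 2.0) < 3 * se_gap)
        assert np.all(np.abs(var.mean(0) - 1.0) < 3 * se_var)

    def test_welch_t_equivalence_across_variables(self):
        # DE-equivalence: over 100 seeds the four per-variable |t| samples are
        # statistically indistinguishable (pairwise two-sample KS, alpha 0.01)
        tstats = np.zeros((100, 4))
        for s in range(100):
            ds = generate_case1(Case1Design(n_per_group=300, seed=1000 + s))
            a = ds.matrix.values[ds.group == "A"]
            b = ds.matrix.values[ds.group == "B"]
            tstats[s] = np.abs(stats.ttest_ind(a, b, axis=0, equal_var=False).statistic)
        for i in range(4):
            for j in range(i + 1, 4):
                assert stats.ks_2samp(tstats[:, i], tstats[:, j]).pvalue > 0.01


class TestCase2:
    def test_deterministic(self):
        a = generate_case2(seed=5).matrix.values
        b = generate_case2(seed=5).matrix.values
        np.testing.assert_array_equal(a, b)

    def test_group_b_marginal_mean(self, case2):
        b1 = case2.matrix.values[case2.group == "B", 0]
        se = math.sqrt(59 / 9 / b1.size)
        assert abs(b1.mean() - 5 / 3) < 3 * se

    def test_group_b_variance_over_seeds(self):
        # empirical group-B variance of X1 ~ 59/9; kurtosis-aware SE for the
        # trimodal mixture, aggregated over 50 seeds
        n_seeds = 50
        v = np.zeros(n_seeds)
        draws = []
        for s in range(n_seeds):
            ds = generate_case2(Case2Design(n_per_subgroup_b=111, seed=s))
            x = ds.matrix.values[ds.group == "B", 0]
            v[s] = x.var(ddof=1)
            draws.append(x)
        x = np.concatenate(draws)
        mu4 = np.mean((x - x.mean()) ** 4)
        se = math.sqrt((mu4 - (59 / 9) ** 2) / 333 / n_seeds)
        assert abs(v.mean() - 59 / 9) < 3 * se

    def test_subgroup_exclusivity(self, case2):
        vals = case2.matrix.to_frame()
        sub = case2.subgroup
        # B1 expresses X1 high, X2 low; B2 the reverse; B3 neither
        assert vals.loc[sub == "B1", "X1"].mean() > 4
        assert vals.loc[sub == "B1", "X2"].mean() < 1
        assert vals.loc[sub == "B2", "X2"].mean() > 4
        assert vals.loc[sub == "B2", "X1"].mean() < 1
        assert vals.loc[sub == "B3", ["X1", "X2"]].to_numpy().mean() < 1

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            Case2Design(p=1.0)

    def test_subgroup_only_in_group_b(self, case2):
        assert set(case2.subgroup[case2.group == "A"]) == {""}
        assert set(case2.subgroup[case2.group == "B"]) == {"B1", "B2", "B3"}


class TestCountSimulator:
    def test_network_correlation_structure(self):
        ds = generate_two_population_counts(seed=9)
        a = ds.matrix.values[ds.group == "A"]
        c = np.corrcoef(a[:, :8].T)
        within = np.r_[c[:4, :4][~np.eye(4, dtype=bool)], c[4:, 4:][~np.eye(4, dtype=bool)]]
        cross = c[:4, 4:].ravel()
        assert within.mean() > cross.mean() + 0.2

    def test_dropout_rate_recovered(self):
        # same seed, different dropout: latent counts identical, so the
        # zeroed fraction among nonzero-latent entries estimates the rate
        rate = 0.25
        latent = generate_two_population_counts(dropout_rate=0.0, seed=4).matrix.values
        dropped = generate_two_population_counts(dropout_rate=rate, seed=4).matrix.values
        nz = latent > 0
        assert np.array_equal(latent[dropped > 0], dropped[dropped > 0])
        frac = np.mean(dropped[nz] == 0)
        se = math.sqrt(rate * (1 - rate) / nz.sum())
        assert abs(frac - rate) < 3 * se

    def test_no_dropout_no_extra_zeros(self):
        a = generate_two_population_counts(dropout_rate=0.0, seed=4)
        assert (a.matrix.values >= 0).all()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_two_population_counts(dropout_rate=1.0, seed=0)
        with pytest.raises(ValueError):
            generate_two_population_counts(n_genes=5, n_markers_per_network=4, seed=0)
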