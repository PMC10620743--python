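"""FNC statistics: modularity, permutation/FDR inference, association
statistics, and the demographic-table tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from fmribss.network import (bh_fdr, boosted_association, chi_square_2x2,
                             compute_fnc, edge_group_ttest, fisher_z,
                             fisher_z_fnc, louvain_modularity, mean_fnc,
                             modularity_signed, normalized_mutual_info,
                             permutation_test_group, residualize_covariates,
                             shepherd_pi, ttest_from_summary, upper_triangle)


# ---------------------------------------------------------------------------
# FNC construction

class TestComputeFnc:
    def test_duplicated_column_gives_unit_edge(self, rng):
        tcs = rng.standard_normal((100, 3))
        tcs[:, 2] = tcs[:, 0]
        fnc = compute_fnc(tcs)
        assert fnc.values[0, 2] == pytest.approx(1.0)
        assert np.all(np.diag(fnc.values) == 0)

    def test_negated_column_gives_minus_one(self, rng):
        tcs = rng.standard_normal((50, 2))
        tcs[:, 1] = -tcs[:, 0]
        assert compute_fnc(tcs).values[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        fnc = compute_fnc(rng.standard_normal((10000, 4)))
        assert np.max(np.abs(upper_triangle(fnc.values))) < 0.1

    def test_constant_column_rejected(self, rng):
        tcs = rng.standard_normal((50, 2))
        tcs[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            compute_fnc(tcs)


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_function(self):
        assert fisher_z(-0.3) == -fisher_z(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_mean_fnc_averages_on_z_scale(self, rng):
        fncs = [compute_fnc(rng.standard_normal((200, 3))) for _ in range(5)]
        mean = mean_fnc(fncs)
        zs = np.mean([np.arctanh(np.clip(f.values, -0.999999, 0.999999))
                      for f in fncs], axis=0)
        np.fill_diagonal(zs, 0)
        expected = np.tanh(zs)
        np.fill_diagonal(expected, 0)
        assert np.allclose(mean, expected)


class TestResidualize:
    def test_uncorrelated_covariate_keeps_demeaned_values(self, rng):
        y = rng.standard_normal(2000)
        cov = rng.standard_normal((2000, 1))
        resid = residualize_covariates(y, cov)
        assert np.corrcoef(resid, y - y.mean())[0, 1] > 0.99

    def test_exact_linear_function_gives_zero_residuals(self, rng):
        cov = rng.standard_normal((50, 2))
        y = 2.0 * cov[:, 0] - cov[:, 1] + 3.0
        resid = residualize_covariates(y, cov)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_to_covariates(self, rng):
        y = rng.standard_normal(100)
        cov = rng.standard_normal((100, 3))
        resid = residualize_covariates(y, cov)
        assert np.all(np.abs(cov.T @ resid) < 1e-8)

    def test_partial_correlation_survives_confound_removal(self, rng):
        # x and y share a confound c but also a direct link
        c = rng.standard_normal(500)
        x = c + 0.7 * rng.standard_normal(500)
        y = c + 0.5 * x + 0.7 * rng.standard_normal(500)
        rx = residualize_covariates(x, c[:, None])
        ry = residualize_covariates(y, c[:, None])
        naive = np.corrcoef(x, y)[0, 1]
        partial = np.corrcoef(rx, ry)[0, 1]
        assert 0.2 < partial < naive

    def test_rank_deficient_rejected(self, rng):
        cov = np.ones((30, 2))
        with pytest.raises(ValueError):
            residualize_covariates(rng.standard_normal(30), cov)


# ---------------------------------------------------------------------------
# modularity

def set_partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_q(w):
    n = w.shape[0]
    best, best_labels = -np.inf, None
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, community in enumerate(part):
            labels[community] = ci
        q = modularity_signed(w, labels)
        if q > best:
            best, best_labels = q, labels
    return best, best_labels


def two_cliques():
    w = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i, j in itertools.permutations(block, 2):
            w[i, j] = 1.0
    return w


class TestModularity:
    def test_two_disconnected_triangles(self):
        res = louvain_modularity(two_cliques(), n_repeats=20, seed=0)
        assert res.q == pytest.approx(0.5)
        assert res.n_modules == 2

    def test_complete_graph_single_module(self):
        w = np.ones((4, 4)) - np.eye(4)
        res = louvain_modularity(w, n_repeats=20, seed=0)
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.n_modules == 1

    def test_block_fnc_recovers_planted_blocks(self):
        w = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.permutations(block, 2):
                w[i, j] = 0.8
        res = louvain_modularity(w, n_repeats=20, seed=1)
        part = res.partition
        assert len({part[0], part[1], part[2]}) == 1
        assert len({part[3], part[4], part[5]}) == 1
        assert part[0] != part[3]

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_exhaustive_maximum_on_signed_graphs(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 9))
        w = rng.normal(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        best_q, _ = exhaustive_best_q(w)
        res = louvain_modularity(w, n_repeats=100, seed=trial)
        assert res.q == pytest.approx(best_q, abs=1e-10)

    def test_q_recomputed_from_partition(self):
        w = two_cliques()
        res = louvain_modularity(w, n_repeats=5, seed=2)
        assert res.q == pytest.approx(modularity_signed(w, res.partition))

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            louvain_modularity(np.zeros((4, 4)))

    def test_asymmetric_matrix_rejected(self, rng):
        with pytest.raises(ValueError):
            louvain_modularity(rng.standard_normal((4, 4)))


# ---------------------------------------------------------------------------
# permutation tests and FDR

class TestPermutationTest:
    def test_identical_paired_samples_give_p_one(self, rng):
        a = rng.standard_normal(20)
        assert permutation_test_group(a, a, n_perm=500, paired=True) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_large_shift_detected(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(2.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        p = permutation_test_group(a, b, n_perm=10000, seed=seed)
        assert p <= 0.001

    def test_type_one_error_calibrated(self):
        # 500 null replicates at nominal 0.05
        rejections = 0
        for rep in range(500):
            rng = np.random.default_rng(10000 + rep)
            a = rng.standard_normal(15)
            b = rng.standard_normal(15)
            p = permutation_test_group(a, b, n_perm=500, seed=rep)
            rejections += p < 0.05
        assert 0.03 <= rejections / 500 <= 0.07

    def test_paired_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test_group(rng.standard_normal(5),
                                   rng.standard_normal(6), paired=True)


def stepup_oracle(pvals, q):
    """Literal BH step-up: find the largest i with p_(i) <= i*q/m."""
    p = np.asarray(pvals)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[:below[-1] + 1]] = True
    return reject


class TestBhFdr:
    def test_handworked_example_all_rejected(self):
        q, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], q_level=0.05)
        assert reject.all()

    def test_large_ps_not_rejected(self):
        _, reject = bh_fdr([0.5, 0.6])
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        _, reject = bh_fdr([0.04], q_level=0.05)
        assert reject.all()

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=100)
        q, _ = bh_fdr(p)
        assert np.all(q >= p - 1e-12)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            _, reject = bh_fdr(p, q_level=0.05)
            assert np.array_equal(reject, stepup_oracle(p, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestEdgeTtest:
    def test_null_groups_no_discoveries(self, rng):
        a = rng.standard_normal((20, 100))
        b = rng.standard_normal((20, 100))
        res = edge_group_ttest(a, b)
        assert res.significant.sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_shifted_edge_survives_fdr(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((20, 50))
        b = rng.standard_normal((20, 50))
        a[:, 7] += 1.5
        res = edge_group_ttest(a, b)
        assert res.significant[7]

    def test_group_swap_negates_t(self, rng):
        a = rng.standard_normal((10, 30))
        b = rng.standard_normal((12, 30))
        assert np.allclose(edge_group_ttest(a, b).t,
                           -edge_group_ttest(b, a).t)

    def test_q_at_least_p(self, rng):
        a = rng.standard_normal((5, 40))
        b = rng.standard_normal((5, 40))
        res = edge_group_ttest(a, b)
        assert np.all(res.q_fdr >= res.p - 1e-12)


# ---------------------------------------------------------------------------
# association statistics

class TestNmi:
    def test_identity_is_one(self, rng):
        x = rng.standard_normal(500)
        assert normalized_mutual_info(x, x) == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        x = rng.standard_normal(10000)
        y = rng.standard_normal(10000)
        assert normalized_mutual_info(x, y) <= 0.05

    def test_symmetric(self, rng):
        x = rng.standard_normal(300)
        y = x ** 2 + rng.standard_normal(300)
        assert normalized_mutual_info(x, y) == pytest.approx(
            normalized_mutual_info(y, x))

    def test_constant_rejected(self, rng):
        with pytest.raises(ValueError):
            normalized_mutual_info(np.ones(50), rng.standard_normal(50))


class TestBoosted:
    def test_formula_on_identity(self, rng):
        x = rng.standard_normal(400)
        assert boosted_association(x, x) == pytest.approx(2.0)

    def test_sign_follows_pearson(self, rng):
        x = rng.standard_normal(1000)
        y = 0.6 * x + 0.8 * rng.standard_normal(1000)
        pos = boosted_association(x, y)
        neg = boosted_association(x, -y)
        pc = stats.pearsonr(x, y).statistic
        nmi = normalized_mutual_info(x, y)
        assert pos == pytest.approx(pc + nmi)
        assert neg == pytest.approx(-pos, abs=0.05)  # NMI re-estimated on -y


class TestShepherdPi:
    def test_clean_data_reduces_to_spearman(self):
        # bounded (uniform) monotone cloud: no point reaches the
        # Mahalanobis threshold, so pi must equal full-sample Spearman
        gen = np.random.default_rng(1)
        x = gen.uniform(0, 1, 40)
        y = x + gen.uniform(-0.3, 0.3, 40)
        pi, p, outliers = shepherd_pi(x, y, seed=0)
        assert not outliers.any()
        assert pi == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_planted_outliers_flagged_and_sign_corrected(self):
        rng = np.random.default_rng(5)
        n = 28
        x = rng.standard_normal(n)
        y = -0.6 * x + 0.6 * rng.standard_normal(n)
        # two extreme leverage points dragging Pearson positive
        x_full = np.concatenate([x, [8.0, 9.0]])
        y_full = np.concatenate([y, [8.5, 9.5]])
        assert stats.pearsonr(x_full, y_full).statistic > 0
        pi, p, outliers = shepherd_pi(x_full, y_full, seed=1)
        assert outliers[-2:].all()
        assert pi < 0
        expected = stats.spearmanr(x_full[~outliers], y_full[~outliers])
        assert pi == pytest.approx(expected.statistic)

    def test_same_seed_same_mask(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        _, _, m1 = shepherd_pi(x, y, seed=3)
        _, _, m2 = shepherd_pi(x, y, seed=3)
        assert np.array_equal(m1, m2)


# ---------------------------------------------------------------------------
# summary-statistic tests

class TestSummaryTests:
    def test_equal_summaries_give_null(self):
        t, p = ttest_from_summary(10, 1.0, 2.0, 10, 1.0, 2.0)
        assert t == 0.0 and p == 1.0

    def test_closed_form_small_case(self):
        # pooled t with n1=n2=2, means 0/2, sds 1: t = -2, df = 2
        t, p = ttest_from_summary(2, 0.0, 1.0, 2, 2.0, 1.0)
        assert t == pytest.approx(-2.0)
        assert p == pytest.approx(2 * stats.t.sf(2.0, 2), abs=1e-4)
        assert p == pytest.approx(0.1835, abs=1e-3)

    def test_antisymmetric_under_group_swap(self):
        t1, p1 = ttest_from_summary(12, 3.0, 1.5, 15, 2.2, 1.1)
        t2, p2 = ttest_from_summary(15, 2.2, 1.1, 12, 3.0, 1.5)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_demographics_table_chi_square(self):
        # male/female counts 65/10 vs 76/26: chi2 ~ 3.94, p ~ 0.047
        chi2, p = chi_square_2x2(65, 10, 76, 26)
        assert chi2 == pytest.approx(3.9424, abs=1e-3)
        assert p == pytest.approx(0.047, abs=5e-4)

    def test_balanced_table_is_null(self):
        chi2, p = chi_square_2x2(10, 10, 10, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_perfect_association(self):
        chi2, _ = chi_square_2x2(20, 0, 0, 20)
        assert chi2 == pytest.approx(40.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(5, 5, 0, 0)
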