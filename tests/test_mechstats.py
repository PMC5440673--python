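"""Map cleaning, summaries, inverse-Gaussian MLE, Lilliefors, adhesion
energy and the group-comparison designs."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from cellmech import (AdhesionEnergyInput, ElasticityMap, adhesion_energy,
                      clean_elasticity_map, compare_groups,
                      equivalent_contact_radius, invgauss_mle,
                      lilliefors_normality, select_representative_sample,
                      summarize)


def _emap(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return ElasticityMap(modulus_Pa=values, valid=np.asarray(valid, bool))


class TestCleanMap:
    def test_all_valid_wide_bounds_keeps_all(self):
        emap = _emap(np.full((4, 4), 500.0))
        vals, kept = clean_elasticity_map(emap)
        assert vals.size == 16 and kept == 1.0

    def test_invalid_pixels_excluded(self):
        grid = np.full((4, 4), 500.0)
        valid = np.ones((4, 4), bool)
        valid[0, 0] = valid[1, 1] = valid[2, 2] = valid[3, 3] = False
        vals, kept = clean_elasticity_map(_emap(grid, valid))
        assert vals.size == 12 and kept == pytest.approx(12 / 16)

    def test_bounds_exclude_substrate_values(self):
        grid = np.full((3, 3), 500.0)
        grid[0, 0] = 5.0e6        # glass-like
        grid[2, 2] = 1.0          # sub-threshold junk
        vals, _ = clean_elasticity_map(_emap(grid))
        assert vals.size == 7
        assert np.all(vals == 500.0)

    def test_cell_mask_restriction(self):
        grid = np.full((4, 4), 100.0)
        grid[:2] = 900.0
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        vals, _ = clean_elasticity_map(_emap(grid), cell_mask=mask)
        assert np.all(vals == 900.0)

    def test_empty_after_cleaning_errors(self):
        with pytest.raises(ValueError, match="survive"):
            clean_elasticity_map(_emap(np.full((2, 2), 1.0e7)))

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            clean_elasticity_map(_emap(np.ones((2, 2))), bounds_Pa=(10, 10))


class TestSummarize:
    def test_closed_form_mle_two_values(self):
        # {1, 2}: mu = 1.5, lambda = 2 / (1 + 1/2 - 2/1.5) = 12
        mu, lam = invgauss_mle([1.0, 2.0])
        assert mu == pytest.approx(1.5)
        assert lam == pytest.approx(12.0)

    def test_constant_values(self):
        s = summarize([5.0, 5.0, 5.0])
        assert s.median_Pa == 5.0
        assert s.iqr_Pa == 0.0

    def test_mle_recovery_at_10k_draws(self, rng):
        x = rng.wald(1000.0, 5000.0, size=10_000)
        s = summarize(x)
        assert s.inv_gauss_mu_Pa == pytest.approx(1000.0, rel=0.03)

    def test_nonpositive_values_error(self):
        with pytest.raises(ValueError, match="positive"):
            summarize([1.0, -2.0, 3.0])

    def test_mle_matches_numeric_likelihood_max(self, rng):
        """Closed-form MLE equals numeric likelihood maximization to 4
        significant digits."""
        for _ in range(5):
            x = rng.wald(rng.uniform(0.5, 5.0), rng.uniform(1.0, 20.0),
                         size=200)
            mu_hat, lam_hat = invgauss_mle(x)

            def nll(params):
                mu, lam = params
                if mu <= 0 or lam <= 0:
                    return 1e12
                return -np.sum(stats.invgauss.logpdf(x, mu / lam,
                                                     scale=lam))

            res = optimize.minimize(nll, [mu_hat * 1.2, lam_hat * 0.8],
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-10,
                                             "fatol": 1e-10})
            assert res.x[0] == pytest.approx(mu_hat, rel=1e-4)
            assert res.x[1] == pytest.approx(lam_hat, rel=1e-4)


class TestLilliefors:
    def test_normal_data_rarely_rejected(self):
        rng = np.random.default_rng(0)
        n_ok = 0
        for _ in range(100):
            p = lilliefors_normality(rng.standard_normal(1000))
            n_ok += p > 0.05
        assert n_ok >= 90

    def test_exponential_data_rejected(self):
        rng = np.random.default_rng(1)
        p = lilliefors_normality(rng.exponential(1.0, size=1000))
        assert p < 0.01

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="zero"):
            lilliefors_normality(np.full(50, 3.0))

    def test_small_n_errors(self):
        with pytest.raises(ValueError, match="n >= 5"):
            lilliefors_normality([1.0, 2.0, 3.0])

    def test_statistic_matches_statsmodels(self, rng):
        """The KS-with-estimated-parameters statistic agrees with the
        statsmodels implementation (independent oracle)."""
        from statsmodels.stats.diagnostic import lilliefors as sm_lf
        from cellmech.mechstats import _lilliefors_statistic
        for _ in range(5):
            x = rng.normal(3.0, 2.0, size=137)
            d_sm, _ = sm_lf(x, dist="norm", pvalmethod="table")
            assert _lilliefors_statistic(x) == pytest.approx(d_sm,
                                                             rel=1e-9)


class TestRepresentativeSample:
    def test_brute_force_three_subset(self):
        values = [1.0, 2.0, 3.0, 4.0, 100.0]
        sel = select_representative_sample(values, 3)
        med = np.median(values)
        best = min(itertools.combinations(values, 3),
                   key=lambda s: sum(abs(v - med) for v in s))
        assert sorted(sel) == sorted(best) == [2.0, 3.0, 4.0]

    def test_identity_when_n_equals_len(self):
        v = [5.0, 1.0, 3.0]
        assert sorted(select_representative_sample(v, 3)) == sorted(v)

    def test_tie_rule_input_order(self):
        sel = select_representative_sample([7.0, 7.0, 7.0, 7.0], 2)
        assert list(sel) == [7.0, 7.0]

    def test_oversized_request_errors(self):
        with pytest.raises(ValueError):
            select_representative_sample([1.0], 2)


class TestAdhesionEnergy:
    def test_equivalent_radius_values(self):
        assert equivalent_contact_radius(np.pi) == pytest.approx(1.0)
        assert equivalent_contact_radius(100.0) == pytest.approx(5.6419,
                                                                 rel=1e-4)
        # scaling: a(4A) = 2 a(A)
        assert equivalent_contact_radius(4 * 7.3) == pytest.approx(
            2 * equivalent_contact_radius(7.3))
        with pytest.raises(ValueError):
            equivalent_contact_radius(0.0)

    def test_closed_form_value(self):
        # a=10 um, R=8 um, E=1 kPa, nu=0.5 -> ~1.474e-3 J/m^2
        inp = AdhesionEnergyInput(a_m=10e-6, R_m=8e-6, E_Pa=1000.0, nu=0.5)
        assert adhesion_energy(inp) == pytest.approx(1.474e-3, rel=1e-3)

    def test_scaling_laws(self):
        base = AdhesionEnergyInput(a_m=5e-6, R_m=8e-6, E_Pa=1000.0)
        g0 = adhesion_energy(base)
        g_a2 = adhesion_energy(AdhesionEnergyInput(a_m=10e-6, R_m=8e-6,
                                                   E_Pa=1000.0))
        g_R2 = adhesion_energy(AdhesionEnergyInput(a_m=5e-6, R_m=16e-6,
                                                   E_Pa=1000.0))
        assert g_a2 == pytest.approx(8 * g0)       # gamma ~ a^3
        assert g_R2 == pytest.approx(g0 / 4)       # gamma ~ 1/R^2
        # limit a -> 0
        tiny = adhesion_energy(AdhesionEnergyInput(a_m=1e-12, R_m=8e-6,
                                                   E_Pa=1000.0))
        assert tiny < 1e-15

    def test_input_validation(self):
        with pytest.raises(ValueError):
            AdhesionEnergyInput(a_m=-1e-6, R_m=8e-6, E_Pa=1000.0)


class TestCompareGroups:
    def test_mann_whitney_exact_enumeration(self):
        comp = compare_groups({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]},
                              design="mann_whitney")
        assert comp.statistic == 0.0
        # oracle: enumerate all C(6,3) = 20 rank arrangements
        pooled = [1, 2, 3, 4, 5, 6]
        u_obs = 0
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in xs for y in ys if x > y)
            u_min = min(u, 9 - u)
            count += u_min <= min(u_obs, 9 - u_obs)
            total += 1
        assert comp.p_omnibus == pytest.approx(count / total) \
            == pytest.approx(0.1)

    def test_identical_groups_maximal_p(self):
        data = {"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0],
                "c": [2.0, 2.0, 2.0]}
        comp = compare_groups(data, design="kw_dunn")
        assert comp.p_omnibus == 1.0
        assert not comp.pairwise["reject"].any()
        mw = compare_groups({k: data[k] for k in ("a", "b")},
                            design="mann_whitney")
        assert mw.p_omnibus == 1.0

    def test_zero_variance_group_error_names_group(self):
        data = {"ctrl": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]}
        with pytest.raises(ValueError, match="flat"):
            compare_groups(data, design="welch_anova_gh")
        with pytest.raises(ValueError, match="flat"):
            compare_groups(data, design="welch_t")

    def test_dataframe_input_and_matrix_symmetry(self, rng):
        df = pd.DataFrame({
            "group": np.repeat(["a", "b", "c"], 20),
            "value": np.concatenate([rng.normal(0, 1, 20),
                                     rng.normal(0, 1, 20),
                                     rng.normal(3, 1, 20)]),
        })
        comp = compare_groups(df, design="welch_anova_gh")
        m = comp.pairwise_matrix()
        assert np.allclose(m.values, m.values.T)
        assert (comp.pairwise["p_adj"] <= 1.0).all()
        assert comp.p_omnibus < 0.001

    def test_kw_dunn_selective_power(self):
        """3 groups of 50 from N(0,1), N(0,1), N(2,1): only pairs involving
        the shifted group are rejected at alpha=0.01 in >= 95% of 100
        seeded runs."""
        good = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            data = {"g1": rng.normal(0, 1, 50), "g2": rng.normal(0, 1, 50),
                    "g3": rng.normal(2, 1, 50)}
            comp = compare_groups(data, design="kw_dunn", alpha=0.01)
            pw = comp.pairwise.set_index(["group1", "group2"])["reject"]
            correct = (not pw.loc[("g1", "g2")]
                       and pw.loc[("g1", "g3")] and pw.loc[("g2", "g3")])
            good += correct
        assert good >= 95

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            compare_groups({"a": [1, 2], "b": [3, 4]}, design="anova")


def _perm_pairwise_pvals(groups, labels, statistic, n_perm=10_000, seed=0):
    """Two-sample permutation p-values for each pair of groups."""
    rng = np.random.default_rng(seed)
    pvals = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            x, y = groups[g1], groups[g2]
            pooled = np.concatenate([x, y])
            obs = abs(statistic(x, y))
            mat = np.tile(pooled, (n_perm, 1))
            mat = rng.permuted(mat, axis=1)
            px, py = mat[:, :x.size], mat[:, x.size:]
            null = np.abs(statistic(px, py))
            pvals.append((np.sum(null >= obs - 1e-12) + 1) / (n_perm + 1))
    return np.array(pvals)


def _rankdiff_stat(x, y):
    both = np.concatenate([x, y], axis=-1)
    r = stats.rankdata(both, axis=-1)
    nx = x.shape[-1]
    return r[..., :nx].mean(axis=-1) - r[..., nx:].mean(axis=-1)


def _welch_t_stat(x, y):
    vx = x.var(axis=-1, ddof=1)
    vy = y.var(axis=-1, ddof=1)
    return (x.mean(axis=-1) - y.mean(axis=-1)) / np.sqrt(
        vx / x.shape[-1] + vy / y.shape[-1])


class TestPermutationOracle:
    """Dunn and Games-Howell pairwise decisions agree with seeded
    permutation tests on >= 90% of random small datasets."""

    def _datasets(self, n_sets=25):
        rng = np.random.default_rng(99)
        for _ in range(n_sets):
            sizes = rng.integers(5, 11, size=3)
            shift = rng.choice([0.0, 0.0, 2.5])
            yield {
                "g1": rng.normal(0, 1, sizes[0]),
                "g2": rng.normal(0, 1, sizes[1]),
                "g3": rng.normal(shift, 1, sizes[2]),
            }

    def test_dunn_agrees_with_permutation(self):
        from statsmodels.stats.multitest import multipletests
        agree = total = 0
        for k, data in enumerate(self._datasets()):
            labels = list(data)
            comp = compare_groups(data, design="kw_dunn", alpha=0.05)
            dec = comp.pairwise["reject"].to_numpy()
            p_perm = _perm_pairwise_pvals(data, labels, _rankdiff_stat,
                                          seed=k)
            dec_perm = multipletests(p_perm, alpha=0.05,
                                     method="holm")[0]
            agree += int(np.sum(dec == dec_perm))
            total += dec.size
        assert agree / total >= 0.90

    def test_games_howell_agrees_with_permutation(self):
        from statsmodels.stats.multitest import multipletests
        agree = total = 0
        for k, data in enumerate(self._datasets()):
            labels = list(data)
            comp = compare_groups(data, design="welch_anova_gh", alpha=0.05)
            dec = comp.pairwise["reject"].to_numpy()
            p_perm = _perm_pairwise_pvals(data, labels, _welch_t_stat,
                                          seed=1000 + k)
            dec_perm = multipletests(p_perm, alpha=0.05,
                                     method="holm")[0]
            agree += int(np.sum(dec == dec_perm))
            total += dec.size
        assert agree / total >= 0.90
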