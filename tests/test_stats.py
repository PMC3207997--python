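"""Size factors, dispersion, NB exact test and BH correction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

import retex as rx
from retex.stats import fit_dispersion, nb_exact_test

FAMS = list(rx.DEFAULT_FAMILIES)


def _frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, index=FAMS[: arr.shape[0]],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = _frame(np.tile([[10], [20], [5]], (1, 4)))
        np.testing.assert_allclose(rx.estimate_size_factors(df), 1.0)

    def test_doubled_column_gets_doubled_factor(self):
        base = np.array([[10], [20], [5], [40]])
        df = _frame(np.hstack([base, 2 * base]))
        sf = rx.estimate_size_factors(df)
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        df = _frame(rng.integers(1, 500, size=(12, 10)))
        sf = rx.estimate_size_factors(df)
        k = df.to_numpy(float)
        geo = np.exp(np.mean(np.log(k), axis=1))
        expected = np.median(k / geo[:, None], axis=0)
        np.testing.assert_allclose(sf, expected, rtol=1e-12)

    def test_scale_equivariance_of_factor_ratios(self):
        # the overall scale is arbitrary (tied to the geometric mean), so
        # equivariance is a statement about ratios between samples
        rng = np.random.default_rng(1)
        df = _frame(rng.integers(1, 100, size=(8, 5)))
        sf = rx.estimate_size_factors(df)
        scaled = df.copy()
        scaled["s2"] = scaled["s2"] * 3
        sf2 = rx.estimate_size_factors(scaled)
        assert (sf2["s2"] / sf2["s0"]) == pytest.approx(3.0 * sf["s2"] / sf["s0"])
        for c in ("s1", "s3", "s4"):
            assert sf2[c] / sf2["s0"] == pytest.approx(sf[c] / sf["s0"])

    def test_all_zero_rows_rejected_with_hint(self):
        df = _frame([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="pseudocount"):
            rx.estimate_size_factors(df)


class TestDispersion:
    def test_poisson_counts_give_near_shot_noise_variance(self):
        rng = np.random.default_rng(2)
        lam = np.array([50, 100, 200, 400, 800, 1600, 60, 300, 900, 150, 70, 2000], float)
        df = _frame(rng.poisson(lam[:, None], size=(12, 100)))
        sf = pd.Series(1.0, index=df.columns)
        model = fit_dispersion(df, sf)
        for q in lam:
            total_var = q + model(q)
            assert total_var == pytest.approx(q, rel=0.10)

    def test_constant_family_floored_to_shot_noise(self):
        df = _frame(np.tile([[7], [100]], (1, 5)))
        sf = pd.Series(1.0, index=df.columns)
        model = fit_dispersion(df, sf, method="per-family")
        assert model(7.0, family=FAMS[0]) == 0.0  # raw variance floored -> Poisson

    def test_nb_dispersion_recovered_within_factor(self):
        rng = np.random.default_rng(3)
        alpha = 0.1
        lam = np.array([100, 200, 400, 800, 1600, 300, 600, 1200, 150, 2400, 90, 500], float)
        r = 1 / alpha
        df = _frame(rng.negative_binomial(r, r / (r + lam[:, None]), size=(12, 100)))
        sf = pd.Series(1.0, index=df.columns)
        model = fit_dispersion(df, sf, method="per-family")
        est = np.array([model(q, family=f) / q**2 for q, f in zip(lam, FAMS)])
        # median recovered alpha within 50% relative error at 100 samples
        assert abs(np.median(est) - alpha) / alpha < 0.5

    def test_single_sample_condition_rejected(self):
        df = _frame([[5], [10]])
        with pytest.raises(ValueError, match="2 samples"):
            fit_dispersion(df, pd.Series(1.0, index=df.columns))


def _poisson_exact_p(k_a, k_b, mu_a, mu_b):
    """Independent enumeration oracle in the Poisson limit."""
    S = k_a + k_b
    ks = np.arange(S + 1)
    joint = poisson.pmf(ks, mu_a) * poisson.pmf(S - ks, mu_b)
    obs = poisson.pmf(k_a, mu_a) * poisson.pmf(k_b, mu_b)
    return joint[joint <= obs * (1 + 1e-10)].sum() / joint.sum()


class TestExactTest:
    def test_symmetric_equal_counts_give_p_one(self):
        s = np.ones(5)
        p, log10_p = nb_exact_test(40, 40, s, s, v_a=0.5, v_b=0.5)
        assert p == pytest.approx(1.0)
        assert log10_p == pytest.approx(0.0)

    def test_zero_total_returns_one(self):
        assert nb_exact_test(0, 0, np.ones(3), np.ones(3), 0.0, 0.0)[0] == 1.0

    @pytest.mark.parametrize("k_a,k_b,n_a,n_b", [
        (10, 40, 2, 2), (30, 70, 3, 5), (5, 150, 2, 10), (80, 85, 4, 4),
    ])
    def test_poisson_limit_matches_enumeration_oracle(self, k_a, k_b, n_a, n_b):
        s_a, s_b = np.ones(n_a), np.ones(n_b)
        S = k_a + k_b
        q0 = S / (n_a + n_b)
        p, _ = nb_exact_test(k_a, k_b, s_a, s_b, v_a=0.0, v_b=0.0)
        expected = _poisson_exact_p(k_a, k_b, q0 * n_a, q0 * n_b)
        assert p == pytest.approx(expected, rel=1e-6)

    def test_p_decreases_with_planted_shift(self):
        s_a, s_b = np.ones(5), np.ones(5)
        base = 100
        ps = []
        for shift in (1.0, 1.5, 2.0, 3.0):
            k_a = int(base * shift) * 5
            k_b = base * 5
            ps.append(nb_exact_test(k_a, k_b, s_a, s_b, 0.0, 0.0)[0])
        assert ps == sorted(ps, reverse=True)
        assert ps[-1] < ps[0]

    def test_windowed_large_s_agrees_with_full_enumeration(self):
        s_a, s_b = np.ones(4), np.ones(4)
        k_a, k_b = 5200, 4800
        full = nb_exact_test(k_a, k_b, s_a, s_b, 2.0, 2.0)
        windowed = nb_exact_test(k_a, k_b, s_a, s_b, 2.0, 2.0, max_enumeration=2000)
        assert windowed[0] == pytest.approx(full[0], rel=1e-6)

    def test_power_against_twofold_shift(self):
        rng = np.random.default_rng(4)
        n_a, n_b, mu = 10, 100, 100
        hits = 0
        for _ in range(200):
            A = rng.poisson(2 * mu, n_a)
            B = rng.poisson(mu, n_b)
            p, _ = nb_exact_test(int(A.sum()), int(B.sum()),
                                 np.ones(n_a), np.ones(n_b), 0.0, 0.0)
            hits += p < 0.05
        assert hits >= 180  # >= 90% of replicates


def _bh_oracle(p):
    """Direct step-up definition: adj_(i) = min_{j>=i} p_(j) * n / j, capped."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBH:
    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(rx.bh_adjust(p), _bh_oracle(p), rtol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(rx.bh_adjust([0.037]), [0.037])

    def test_uniform_ties_unchanged(self):
        np.testing.assert_allclose(rx.bh_adjust([0.2] * 7), [0.2] * 7)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        p = rng.random(15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(rx.bh_adjust(p)[perm], rx.bh_adjust(p[perm]))

    def test_fixed_points_of_step_up(self):
        # vectors of the form p_(i) = c * i / n are mapped to the constant c
        n, c = 8, 0.4
        p = c * np.arange(1, n + 1) / n
        np.testing.assert_allclose(rx.bh_adjust(p), c)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rx.bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            rx.bh_adjust([-0.1])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(7)
        p = rng.random(30)
        adj = rx.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestRunTable:
    def test_identical_matrices_are_null(self):
        rng = np.random.default_rng(8)
        df = _frame(rng.integers(50, 500, size=(12, 6)))
        res = rx.run_table1(df, df.copy())
        np.testing.assert_allclose(res["fold_change"], 1.0)
        np.testing.assert_allclose(res["p_raw"], 1.0)
        np.testing.assert_allclose(res["p_adj"], 1.0)

    def test_family_mismatch_rejected(self):
        a = _frame(np.ones((3, 2)))
        b = a.iloc[::-1]
        with pytest.raises(ValueError, match="families"):
            rx.run_table1(a, b)

    def test_p_adj_consistent_with_bh_of_p_raw(self):
        rng = np.random.default_rng(9)
        obs = _frame(rng.integers(20, 400, size=(12, 5)), prefix="o")
        sim = _frame(rng.integers(20, 400, size=(12, 8)), prefix="n")
        res = rx.run_table1(obs, sim)
        np.testing.assert_allclose(res["p_adj"], _bh_oracle(res["p_raw"]), rtol=1e-10)
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()

    def test_fold_change_orientation_simulated_over_observed(self):
        # family 0 overexpressed in observed -> fold change below 1
        obs = _frame(np.tile([[400], [100], [100]], (1, 4)), prefix="o")
        sim = _frame(np.tile([[200], [200], [200]], (1, 4)), prefix="n")
        res = rx.run_table1(obs, sim)
        assert res["fold_change"].iloc[0] < 1.0
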