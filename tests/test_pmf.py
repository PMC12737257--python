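import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from sorisk import (PMF, ConcentrationTable, compute_uncertainty,
                    correlation_matrix, factor_number_scan, match_factors)
from sorisk.data import ElementReference, ValidationError
from sorisk.pmf import _multiplicative_fit, _q_value
from sorisk.synthetic import SyntheticSpec, custom_study_spec, generate_mixture


def _table_from(values, elements=None, land_use="farmland"):
    elements = elements or [f"E{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, columns=elements,
                        index=[f"s{i}" for i in range(len(values))])
    return ConcentrationTable(data,
                              pd.Series([land_use] * len(values),
                                        index=data.index))


def _uniform_uncertainty(table, frac=0.1, floor=1e-3):
    return np.maximum(frac * table.data, floor)


class TestComputeUncertainty:
    def test_above_mdl_formula(self, small_table):
        """EF=0.1, x=10, MDL=1 -> sqrt(1 + 0.25) = 1.1180."""
        idx = pd.Index(["Pb", "Cd", "Hg"])
        ref = ElementReference(
            background=pd.Series(1.0, index=idx),
            toxicity=pd.Series(1.0, index=idx),
            mdl=pd.Series(1.0, index=idx),
            error_fraction=pd.Series(0.1, index=idx),
            rfd=pd.DataFrame(index=idx), slope_factor=pd.DataFrame(index=idx))
        table = _table_from(np.array([[10.0, 10.0, 10.0],
                                      [0.5, 1.0, 2.0]]), ["Pb", "Cd", "Hg"])
        u = compute_uncertainty(table, ref)
        assert u.iloc[0, 0] == pytest.approx(1.1180, abs=1e-4)
        # below MDL -> 5/6 * MDL
        assert u.loc["s1", "Pb"] == pytest.approx(5 / 6)
        # boundary: concentration exactly at MDL uses the below-MDL branch
        assert u.loc["s1", "Cd"] == pytest.approx(5 / 6)
        assert u.loc["s1", "Hg"] == pytest.approx(
            np.sqrt((0.1 * 2.0) ** 2 + 0.25))

    def test_below_mdl_scales_with_mdl(self):
        idx = pd.Index(["Pb"])
        ref = ElementReference(
            background=pd.Series(1.0, index=idx),
            toxicity=pd.Series(1.0, index=idx),
            mdl=pd.Series(1.2, index=idx),
            error_fraction=pd.Series(0.1, index=idx),
            rfd=pd.DataFrame(index=idx), slope_factor=pd.DataFrame(index=idx))
        table = _table_from(np.array([[0.5], [0.5]]), ["Pb"])
        u = compute_uncertainty(table, ref)
        np.testing.assert_allclose(u.values, 5.0 / 6.0 * 1.2)


class TestFit:
    def test_zero_noise_two_factor_mixture_recovered_exactly(self):
        # anchor samples make the exact factorization unique up to
        # permutation/scaling, so recovery can be asserted tightly
        rng = np.random.default_rng(0)
        g = rng.uniform(0.2, 2.0, size=(30, 2))
        g[0, 1] = 0.0
        g[1, 0] = 0.0
        f = np.array([[10.0, 1.0, 0.0, 5.0], [0.0, 3.0, 20.0, 1.0]])
        x = g @ f
        table = _table_from(x)
        u = _uniform_uncertainty(table)
        res = PMF(table.data, u, 2).fit(n_starts=10, seed=1, max_iter=20000,
                                        tol=1e-12)
        assert res.q_true < 1e-6
        perm, sims = match_factors(res.profiles, pd.DataFrame(f))
        assert (sims > 0.999).all()

    def test_q_never_increases_along_iterations(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 10, size=(12, 6))
        u = 0.1 * x
        g0 = rng.uniform(0.5, 1.5, (12, 3))
        f0 = x.mean(axis=0) / 3 * rng.uniform(0.5, 1.5, (3, 6))
        _, _, q_hist, _ = _multiplicative_fit(x, 1 / u**2, g0, f0, 2000, 0.0)
        diffs = np.diff(q_hist)
        assert (diffs <= 1e-8 * np.maximum(q_hist[:-1], 1.0)).all()

    def test_four_source_recovery_at_five_percent_noise(self, reference):
        """n=100 synthetic mixture: matched profiles nearly exact."""
        ds = generate_mixture(custom_study_spec(2, n_samples=100))
        u = compute_uncertainty(ds.table, reference)
        res = PMF(ds.table.data, u, 4).fit(n_starts=10, seed=2)
        perm, sims = match_factors(res.profiles, ds.true_profiles)
        assert sims.mean() > 0.95

    def test_rank_one_weighted_fit_matches_direct_oracle(self):
        """3x3, k=1: multiplicative fit reaches the same Q as a direct
        numerical minimisation of the weighted objective."""
        rng = np.random.default_rng(5)
        g_true = rng.uniform(0.5, 2.0, (3, 1))
        f_true = rng.uniform(1.0, 10.0, (1, 3))
        x = g_true @ f_true + rng.normal(0, 0.2, (3, 3))
        x = np.abs(x)
        u = 0.1 * x + 0.05
        res = PMF(pd.DataFrame(x), pd.DataFrame(u), 1).fit(
            n_starts=5, seed=0, max_iter=20000, tol=1e-12)

        def objective(z):
            g = z[:3].reshape(3, 1) ** 2
            f = z[3:].reshape(1, 3) ** 2
            return _q_value(x, u, g, f)

        z0 = np.sqrt(np.concatenate([g_true.ravel(), f_true.ravel()]))
        direct = minimize(objective, z0, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 20000})
        assert res.q_true == pytest.approx(direct.fun, abs=1e-6)

    def test_normalization_leaves_reconstruction_invariant(self):
        ds = generate_mixture(custom_study_spec(4, n_samples=40))
        u = _uniform_uncertainty(ds.table)
        res = PMF(ds.table.data, u, 4).fit(n_starts=5, seed=3)
        # contributions have unit mean per factor; G@F unchanged by the
        # rescaling means Q computed pre/post normalisation agrees
        np.testing.assert_allclose(res.contributions.mean(axis=0), 1.0,
                                   rtol=1e-10)
        assert res.q_true == pytest.approx(res.q_history[-1], rel=1e-10)

    def test_invalid_factor_count_rejected(self, small_table):
        u = _uniform_uncertainty(small_table)
        with pytest.raises(ValidationError):
            PMF(small_table.data, u, 5)


class TestDiagnostics:
    def test_exact_fit_has_unit_r2_and_zero_residuals(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0.2, 2.0, size=(20, 2))
        f = np.array([[10.0, 1.0, 0.5], [0.2, 3.0, 20.0]])
        table = _table_from(g @ f)
        u = _uniform_uncertainty(table)
        res = PMF(table.data, u, 2).fit(n_starts=8, seed=2, max_iter=20000,
                                        tol=1e-13)
        d = res.diagnostics()
        assert all(r > 0.9999 for r in d["r2"].values())
        assert np.abs(res.scaled_residuals.values).max() < 1e-2
        assert d["residuals_within_3"] == 1.0

    def test_well_specified_noise_q_ratio_near_one(self, study_dataset,
                                                   reference):
        u = compute_uncertainty(study_dataset.table, reference)
        res = PMF(study_dataset.table.data, u, 4).fit(n_starts=10, seed=1)
        ratio = res.q_robust / res.q_true
        assert 0.9 <= ratio <= 1.1

    def test_underfactored_model_raises_q_substantially(self, study_dataset,
                                                        reference):
        u = compute_uncertainty(study_dataset.table, reference)
        scan = factor_number_scan(study_dataset.table.data, u, [2, 4],
                                  n_starts=8, seed=0)
        assert scan.loc[2, "q_true"] > 1.2 * scan.loc[4, "q_true"]


class TestSummaries:
    def test_single_factor_owns_everything(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(0.5, 2.0, size=(15, 1))
        f = np.array([[5.0, 1.0, 0.3]])
        table = _table_from(g @ f)
        u = _uniform_uncertainty(table)
        res = PMF(table.data, u, 1).fit(n_starts=3, seed=0)
        np.testing.assert_allclose(res.factor_loading_pct().values, 100.0,
                                   rtol=1e-6)
        assert res.factor_contribution_pct().iloc[0] == pytest.approx(100.0)

    def test_loading_percentages_sum_to_100_per_element(self, study_dataset,
                                                        reference):
        u = compute_uncertainty(study_dataset.table, reference)
        res = PMF(study_dataset.table.data, u, 4).fit(n_starts=5, seed=4)
        np.testing.assert_allclose(res.factor_loading_pct().sum(axis=1), 100.0,
                                   rtol=1e-9)
        assert res.factor_contribution_pct().sum() == pytest.approx(100.0)

    def test_agreement_with_sklearn_nmf_on_noiseless_data(self):
        """Independent cross-check: with uniform weights the weighted
        optimizer should match sklearn's unweighted NMF reconstruction
        error on a noiseless low-rank matrix."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(6)
        g = rng.uniform(0.2, 2.0, size=(25, 3))
        f = rng.uniform(0.0, 10.0, size=(3, 6))
        x = g @ f
        table = _table_from(x)
        u = pd.DataFrame(np.ones_like(x), index=table.data.index,
                         columns=table.data.columns)
        res = PMF(table.data, u, 3).fit(n_starts=10, seed=0, max_iter=20000,
                                        tol=1e-13)
        nmf = sklearn.NMF(n_components=3, init="nndsvda", max_iter=5000,
                          tol=1e-12, random_state=0)
        w = nmf.fit_transform(x)
        err_sklearn = ((x - w @ nmf.components_) ** 2).sum()
        assert res.q_true <= err_sklearn + 1e-6


class TestCorrelation:
    def test_self_correlation_unity_and_antimonotone_minus_one(self):
        n = 10
        data = pd.DataFrame({"A": np.arange(1.0, n + 1),
                             "B": np.arange(n, 0, -1.0),
                             "C": np.full(n, 2.0)},
                            index=[f"s{i}" for i in range(n)])
        table = ConcentrationTable(data, pd.Series(["farmland"] * n,
                                                   index=data.index))
        r, p = correlation_matrix(table)
        assert r.loc["A", "A"] == pytest.approx(1.0)
        assert r.loc["A", "B"] == pytest.approx(-1.0)
        assert np.isnan(r.loc["A", "C"])  # constant column reported missing

    def test_independent_columns_rarely_exceed_half(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 200
        for _ in range(reps):
            a, b = rng.normal(size=24), rng.normal(size=24)
            from scipy.stats import spearmanr
            if abs(spearmanr(a, b).statistic) < 0.5:
                hits += 1
        assert hits / reps > 0.9
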