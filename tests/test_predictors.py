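"""Marker-effect estimators and GEBV accuracy."""

import numpy as np
import pytest

import gsalloc as gs
from gsalloc.errors import ConfigurationError, InvalidInputError


def _random_instance(n, m, seed, sigma=1.0, effect_sd=0.3):
    rng = np.random.default_rng(seed)
    Z = (rng.integers(0, 2, (n, m)) * 2 - 1).astype(float)
    u = rng.normal(0, effect_sd, m)
    y = 1.5 + Z @ u + rng.normal(0, sigma, n)
    return Z, y, u


class TestRRBlup:
    def test_constant_phenotype_degenerate(self):
        Z, _, _ = _random_instance(20, 10, 0)
        fit = gs.fit_rrblup(Z, np.full(20, 7.25))
        assert fit.mu == pytest.approx(7.25)
        assert np.abs(fit.effects).max() == 0.0

    def test_orthonormal_closed_form(self):
        """With orthogonal columns the ridge solution is (z_j.y)/(n + lam)."""
        n, lam = 16, 4.0
        # +-1 Hadamard-style orthogonal design: columns orthogonal, z'z = n
        H = np.array([[1.0]])
        while H.shape[0] < n:
            H = np.block([[H, H], [H, -H]])
        Z = H[:, 1:9]  # drop the constant column; orthogonal to intercept
        rng = np.random.default_rng(1)
        y = Z @ rng.normal(0, 1, 8) + rng.normal(0, 0.5, n)
        fit = gs.fit_rrblup(Z, y, ridge_lambda=lam)
        yc = y - y.mean()
        np.testing.assert_allclose(fit.effects, Z.T @ yc / (n + lam), atol=1e-10)

    def test_matches_dense_mixed_model_equations(self):
        """Fixed-ratio solution equals a direct dense MME solve to 1e-8."""
        Z, y, _ = _random_instance(30, 20, 2)
        lam = 3.7
        fit = gs.fit_rrblup(Z, y, ridge_lambda=lam)
        X = np.ones((30, 1))
        lhs = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(20)]])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        np.testing.assert_allclose(
            np.concatenate([[fit.mu], fit.effects]), sol, atol=1e-8)

    def test_shrinkage_monotone_in_lambda(self):
        Z, y, _ = _random_instance(40, 15, 3)
        norms = [
            np.linalg.norm(gs.fit_rrblup(Z, y, ridge_lambda=lam).effects)
            for lam in (0.1, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_accuracy_invariant_to_affine_phenotype_transform(self):
        Z, y, u = _random_instance(60, 25, 4)
        Zv, _, _ = _random_instance(80, 25, 5)
        a_v = Zv @ u
        g1 = gs.predict(gs.fit_rrblup(Z, y), Zv)
        g2 = gs.predict(gs.fit_rrblup(Z, 3.0 * y + 11.0), Zv)
        assert gs.accuracy(g1, a_v) == pytest.approx(gs.accuracy(g2, a_v), abs=1e-9)

    def test_reml_and_ml_agree_at_moderate_n(self):
        Z, y, _ = _random_instance(150, 40, 6)
        f_reml = gs.fit_rrblup(Z, y, method="REML")
        f_ml = gs.fit_rrblup(Z, y, method="ML")
        r = np.corrcoef(f_reml.effects, f_ml.effects)[0, 1]
        assert r > 0.999


class TestBayesCPi:
    def test_pi_one_gives_empty_model(self):
        Z, y, _ = _random_instance(40, 20, 7)
        cfg = gs.BayesCPiConfig(n_iter=800, burn_in=300, fixed_pi=1.0)
        fit = gs.fit_bayescpi(Z, y, cfg, np.random.default_rng(0))
        assert np.abs(fit.effects).max() == 0.0
        assert fit.mu == pytest.approx(y.mean(), abs=4 * y.std() / np.sqrt(40))
        assert (gs.predict(fit, Z) == 0).all()

    def test_equivalent_to_rrblup_with_fixed_inclusion_and_variances(self):
        """delta fixed to 1 and variances held -> posterior mean is ridge."""
        Z, y, _ = _random_instance(60, 30, 8)
        su2, se2 = 0.4, 2.0
        cfg = gs.BayesCPiConfig(n_iter=6000, burn_in=1000, include_all=True,
                                fixed_sigma_u2=su2, fixed_sigma_e2=se2,
                                fixed_pi=0.0)
        fb = gs.fit_bayescpi(Z, y, cfg, np.random.default_rng(1))
        fr = gs.fit_rrblup(Z, y, ridge_lambda=se2 / su2)
        assert np.corrcoef(fb.effects, fr.effects)[0, 1] > 0.998
        assert np.abs(fb.effects - fr.effects).max() < 0.05

    def test_large_effect_recovered_with_high_inclusion(self):
        """A dominant simulated effect gets posterior inclusion > 0.95."""
        rng = np.random.default_rng(9)
        Z = (rng.integers(0, 2, (80, 50)) * 2 - 1).astype(float)
        y = 4.0 * Z[:, 7] + rng.normal(0, 0.3, 80)
        cfg = gs.BayesCPiConfig(n_iter=6000, burn_in=1000)
        fit = gs.fit_bayescpi(Z, y, cfg, np.random.default_rng(2))
        assert fit.inclusion[7] > 0.95
        assert fit.effects[7] == pytest.approx(4.0, abs=0.2)

    def test_chain_state_stays_valid_and_beats_null(self):
        Z, y, u = _random_instance(70, 30, 10, sigma=0.8)
        cfg = gs.BayesCPiConfig(n_iter=1500, burn_in=500)
        fit = gs.fit_bayescpi(Z, y, cfg, np.random.default_rng(3))
        assert fit.sigma_u2 > 0 and fit.sigma_e2 > 0
        assert (0 <= fit.inclusion).all() and (fit.inclusion <= 1).all()
        yhat = fit.mu + gs.predict(fit, Z)
        assert ((y - yhat) ** 2).sum() < ((y - y.mean()) ** 2).sum()

    def test_nonfinite_phenotypes_rejected(self):
        Z, y, _ = _random_instance(20, 5, 11)
        y[3] = np.nan
        with pytest.raises(InvalidInputError):
            gs.fit_bayescpi(Z, y, gs.BayesCPiConfig(n_iter=20, burn_in=10),
                            np.random.default_rng(4))

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            gs.BayesCPiConfig(n_iter=100, burn_in=100)


def _naive_stepwise(Z, y, alpha):
    """Independent re-implementation of the add/drop rules via statsmodels."""
    import statsmodels.api as sm

    n, m = Z.shape
    included: list[int] = []
    while True:
        changed = False
        best_p, best_j = None, None
        for j in range(m):
            if j in included:
                continue
            X = sm.add_constant(Z[:, included + [j]])
            if n - (len(included) + 1) - 1 < 1:
                continue
            res = sm.OLS(y, X).fit()
            p = res.pvalues[-1]
            if best_p is None or p < best_p - 1e-15:
                best_p, best_j = p, j
        if best_p is not None and best_p <= alpha and len(included) < n - 2:
            included.append(best_j)
            changed = True
            while True:
                X = sm.add_constant(Z[:, included])
                res = sm.OLS(y, X).fit()
                pvals = res.pvalues[1:]
                worst = int(np.argmax(pvals))
                if pvals[worst] > alpha:
                    included.pop(worst)
                else:
                    break
        if not changed:
            break
    return sorted(included)


class TestOlsStepwise:
    def test_perfect_single_signal(self):
        rng = np.random.default_rng(12)
        Z = (rng.integers(0, 2, (12, 3)) * 2 - 1).astype(float)
        y = 5.0 * Z[:, 0]
        fit = gs.fit_ols_stepwise(Z, y, 0.20)
        assert fit.inclusion[0] == 1.0
        assert fit.effects[0] == pytest.approx(5.0, abs=1e-8)
        assert np.abs(fit.effects[1:]).max() < 1e-8 or fit.inclusion[1:].sum() == 0

    def test_duplicate_columns_tie_break_to_lowest_index(self):
        rng = np.random.default_rng(13)
        base = (rng.integers(0, 2, 30) * 2 - 1).astype(float)
        other = (rng.integers(0, 2, 30) * 2 - 1).astype(float)
        Z = np.column_stack([other, base, base.copy()])
        y = 3.0 * base + rng.normal(0, 0.2, 30)
        fit = gs.fit_ols_stepwise(Z, y, 0.20)
        assert fit.inclusion[1] == 1.0 and fit.inclusion[2] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, m = 25, 10
        Z = (rng.integers(0, 2, (n, m)) * 2 - 1).astype(float)
        u = np.zeros(m)
        u[rng.choice(m, 3, replace=False)] = rng.normal(0, 1.0, 3)
        y = Z @ u + rng.normal(0, 1.0, n)
        fit = gs.fit_ols_stepwise(Z, y, 0.20)
        chosen = sorted(np.flatnonzero(fit.inclusion > 0.5))
        assert chosen == _naive_stepwise(Z, y, 0.20)
        if chosen:
            import statsmodels.api as sm

            res = sm.OLS(y, sm.add_constant(Z[:, chosen])).fit()
            np.testing.assert_allclose(fit.effects[chosen], res.params[1:],
                                       atol=1e-8)

    def test_stopping_condition_holds(self):
        """Included markers all significant; no excluded marker would enter."""
        from scipy import stats as sps

        Z, y, _ = _random_instance(50, 20, 14, sigma=2.0)
        alpha = 0.20
        fit = gs.fit_ols_stepwise(Z, y, alpha)
        included = np.flatnonzero(fit.inclusion > 0.5)
        excluded = np.flatnonzero(fit.inclusion < 0.5)
        n = len(y)
        k = included.size

        def partial_p(cols, test_col):
            X = np.column_stack([np.ones(n)] + [Z[:, c] for c in cols])
            rss0 = ((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum()
            X1 = np.column_stack([X, Z[:, test_col]])
            rss1 = ((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2).sum()
            df = n - X1.shape[1]
            f = (rss0 - rss1) / (rss1 / df)
            return sps.f.sf(f, 1, df)

        for j in included:
            others = [c for c in included if c != j]
            assert partial_p(others, j) <= alpha + 1e-12
        if k < n - 2:
            for j in excluded:
                assert partial_p(list(included), j) > alpha - 1e-12

    def test_empty_model_is_valid(self):
        rng = np.random.default_rng(15)
        Z = (rng.integers(0, 2, (30, 5)) * 2 - 1).astype(float)
        y = rng.normal(0, 1, 30)
        fit = gs.fit_ols_stepwise(Z, y, 0.0001)
        assert fit.inclusion.sum() == 0
        assert fit.mu == pytest.approx(y.mean())


class TestPredictAndAccuracy:
    def test_zero_effects_zero_gebv(self):
        fit = gs.ModelFit(1.0, np.zeros(4), np.zeros(4), 0.0, 1.0, "ols")
        assert (gs.predict(fit, np.ones((6, 4))) == 0).all()

    def test_single_marker_identity(self):
        eff = np.zeros(3)
        eff[1] = 1.0
        fit = gs.ModelFit(0.0, eff, eff.copy(), 0.0, 1.0, "ols")
        Z = (np.random.default_rng(16).integers(0, 2, (10, 3)) * 2 - 1).astype(float)
        np.testing.assert_array_equal(gs.predict(fit, Z), Z[:, 1])

    def test_predict_matches_elementwise_oracle(self):
        rng = np.random.default_rng(17)
        eff = rng.normal(0, 1, 8)
        fit = gs.ModelFit(0.3, eff, np.ones(8), 1.0, 1.0, "rrblup")
        Z = rng.integers(-1, 2, (5, 8)).astype(float)
        expected = [sum(Z[i, j] * eff[j] for j in range(8)) for i in range(5)]
        np.testing.assert_allclose(gs.predict(fit, Z), expected, rtol=1e-12)

    def test_dimension_mismatch(self):
        fit = gs.ModelFit(0.0, np.zeros(4), np.zeros(4), 0.0, 1.0, "ols")
        with pytest.raises(InvalidInputError):
            gs.predict(fit, np.ones((5, 3)))

    def test_accuracy_extremes_and_textbook_value(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert gs.accuracy(a, a) == pytest.approx(1.0)
        assert gs.accuracy(-a, a) == pytest.approx(-1.0)
        g = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        num = np.cov(g, a)[0, 1]
        den = g.std(ddof=1) * a.std(ddof=1)
        assert gs.accuracy(g, a) == pytest.approx(num / den)

    def test_zero_variance_returns_nan(self):
        assert np.isnan(gs.accuracy(np.zeros(5), np.arange(5.0)))


class TestModelRanking:
    def test_rrblup_beats_ols_on_polygenic_low_heritability_trait(self, genome):
        """With 100 small QTL and h2plot=0.2 at n=100, shrinkage wins big."""
        import gsalloc.experiments as ex

        res = ex.run_cross_validation(("rrblup", "ols"), n_grid=(100,),
                                      r_grid=(1,), h2plot=0.20,
                                      n_replicates=12, seed=77)
        rr = res.cell(("rrblup", 100, 1)).mean()
        ols = res.cell(("ols", 100, 1)).mean()
        assert rr >= 1.34 * ols
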