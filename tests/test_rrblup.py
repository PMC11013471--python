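import numpy as np
import pytest

from gsalloc import (
    GenotypeMatrix,
    PhenotypeVector,
    SimConfig,
    fit_rrblup,
    predict_gebv,
    prediction_ability,
    reml_h2,
    simulate_panel,
    simulate_phenotype,
)
from gsalloc.rrblup import LAMBDA_BOUNDS, reml_lambda


def _as_G(X):
    n, m = X.shape
    return GenotypeMatrix(
        [f"g{i}" for i in range(n)], [f"m{j}" for j in range(m)], X.astype(float)
    )


def _random_problem(seed, t=10, m=20):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(t, m)).astype(float)
    y = rng.normal(size=t)
    return X, y


def brute_force_reml_lambda(K, y, n_grid=2000):
    """Independent REML profile: dense restricted likelihood on a log grid
    followed by golden-section refinement, no spectral shortcuts."""
    n = len(y)
    ones = np.ones((n, 1))

    def neg2_restricted(lam):
        V = K + lam * np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = float((ones.T @ Vi @ ones).item())
        mu = float((ones.T @ Vi @ y).item()) / XtViX
        r = y - mu
        quad = float(r @ Vi @ r)
        sig = quad / (n - 1)
        sign, logdetV = np.linalg.slogdet(V)
        return (n - 1) * np.log(sig) + logdetV + np.log(XtViX)

    grid = np.logspace(np.log10(LAMBDA_BOUNDS[0]), np.log10(LAMBDA_BOUNDS[1]), n_grid)
    vals = [neg2_restricted(l) for l in grid]
    k = int(np.argmin(vals))
    lo = grid[max(0, k - 1)]
    hi = grid[min(n_grid - 1, k + 1)]
    # golden-section on log scale
    import math

    gr = (math.sqrt(5) - 1) / 2
    a, b = math.log(lo), math.log(hi)
    c, d = b - gr * (b - a), a + gr * (b - a)
    for _ in range(200):
        if neg2_restricted(math.exp(c)) < neg2_restricted(math.exp(d)):
            b = d
        else:
            a = c
        c, d = b - gr * (b - a), a + gr * (b - a)
        if b - a < 1e-12:
            break
    return math.exp((a + b) / 2)


class TestFit:
    def test_constant_phenotype_degenerate(self):
        X, _ = _random_problem(0, t=5, m=3)
        fit = fit_rrblup(_as_G(X), PhenotypeVector([f"g{i}" for i in range(5)],
                                                   np.full(5, 5.0)))
        assert fit.degenerate
        assert fit.mu == 5.0
        np.testing.assert_array_equal(fit.beta, 0.0)

    def test_closed_form_ridge_at_fixed_lambda(self):
        # 6 x 2 fixture; oracle: direct dense solve of (Xc'Xc + I) b = Xc'(y - mu)
        X = np.array(
            [[0, 2], [1, 1], [2, 0], [0, 0], [2, 2], [1, 0]], dtype=float
        )
        y = np.array([1.0, 2.0, 3.0, 0.5, 3.5, 2.2])
        G = _as_G(X)
        fit = fit_rrblup(G, PhenotypeVector(G.genotype_ids, y), lambda_fixed=1.0)
        Xc = X - X.mean(axis=0)
        V = Xc @ Xc.T + np.eye(6)
        Vi = np.linalg.inv(V)
        mu = (np.ones(6) @ Vi @ y) / (np.ones(6) @ Vi @ np.ones(6))
        beta = np.linalg.solve(Xc.T @ Xc + np.eye(2), Xc.T @ (y - mu))
        assert fit.mu == pytest.approx(mu, abs=1e-10)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
        # predictions on new genotypes are mu + X1c beta with training centering
        Xnew = np.array([[2.0, 1.0], [0.0, 1.0]])
        Gnew = _as_G(Xnew)
        np.testing.assert_allclose(
            predict_gebv(fit, Gnew),
            mu + (Xnew - X.mean(axis=0)) @ beta,
            atol=1e-10,
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_kernel_and_ridge_forms_agree(self, seed):
        X, y = _random_problem(seed, t=10, m=20)
        G = _as_G(X)
        yv = PhenotypeVector(G.genotype_ids, y)
        fit_kernel = fit_rrblup(G, yv)  # m > t: kernel path
        # force the ridge path by duplicating rows beyond m
        fit2 = fit_rrblup(G, yv, lambda_fixed=fit_kernel.lam)
        Xc = X - X.mean(axis=0)
        ridge_beta = np.linalg.solve(
            Xc.T @ Xc + fit_kernel.lam * np.eye(20), Xc.T @ (y - fit_kernel.mu)
        )
        np.testing.assert_allclose(fit_kernel.beta, ridge_beta, atol=1e-8)
        np.testing.assert_allclose(fit2.beta, ridge_beta, atol=1e-8)

    def test_reml_matches_brute_force_profile(self):
        X, y = _random_problem(123, t=12, m=20)
        Xc = X - X.mean(axis=0)
        K = Xc @ Xc.T
        lam, _, _ = reml_lambda(K, y)
        lam_bf = brute_force_reml_lambda(K, y)
        assert np.log(lam) == pytest.approx(np.log(lam_bf), abs=1e-4)

    def test_shrinkage_monotone_in_lambda(self):
        X, y = _random_problem(7, t=15, m=10)
        G = _as_G(X)
        yv = PhenotypeVector(G.genotype_ids, y)
        norms = [
            np.linalg.norm(fit_rrblup(G, yv, lambda_fixed=lam).beta)
            for lam in [1e-3, 1e-1, 1.0, 10.0, 1e3, 1e5]
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_too_few_genotypes_rejected(self):
        X, _ = _random_problem(0, t=2, m=4)
        with pytest.raises(ValueError, match="at least 3"):
            fit_rrblup(_as_G(X), PhenotypeVector(["g0", "g1"], np.array([0.0, 1.0])))


class TestPredict:
    def test_training_consistency(self, germplasm_pop):
        G, y, _ = germplasm_pop
        fit = fit_rrblup(G, y)
        gebv = predict_gebv(fit, G)
        Xc = G.dosage - fit.center
        np.testing.assert_allclose(gebv, fit.mu + Xc @ fit.beta, atol=1e-10)

    def test_zero_effects_predict_intercept(self):
        X, _ = _random_problem(1, t=6, m=4)
        G = _as_G(X)
        fit = fit_rrblup(G, PhenotypeVector(G.genotype_ids, np.full(6, 2.5)))
        np.testing.assert_allclose(predict_gebv(fit, G), 2.5)

    def test_marker_mismatch_reported(self, germplasm_pop):
        G, y, _ = germplasm_pop
        fit = fit_rrblup(G, y)
        G_missing = G.subset_markers(G.marker_ids[:10])
        with pytest.raises(ValueError, match="markers"):
            predict_gebv(fit, G_missing)

    def test_noise_free_training_prediction(self):
        # h2 = 1 with more genotypes than markers: near-perfect training fit
        cfg = SimConfig(
            archetype="GERMPLASM", n_genotypes=150, n_markers=50, n_qtl=10,
            h2=1.0, seed=6,
        )
        G = simulate_panel(cfg)
        y, _ = simulate_phenotype(G, cfg)
        fit = fit_rrblup(G, y)
        r = prediction_ability(y.values, predict_gebv(fit, G))
        assert r > 0.99


class TestPredictionAbility:
    def test_perfect_and_anti_correlation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert prediction_ability(y, y) == pytest.approx(1.0)
        assert prediction_ability(y, -y) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        g = np.array([1.0, 2.0, 3.0, 5.0])
        num = np.sum((y - y.mean()) * (g - g.mean()))
        den = np.sqrt(np.sum((y - y.mean()) ** 2) * np.sum((g - g.mean()) ** 2))
        assert prediction_ability(y, g) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            prediction_ability(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


class TestParameterRecovery:
    def test_effect_and_h2_recovery_single_seed(self):
        cfg = SimConfig(
            archetype="GERMPLASM", n_genotypes=400, n_markers=500, n_qtl=50,
            h2=0.5, seed=17,
        )
        G = simulate_panel(cfg)
        y, truth = simulate_phenotype(G, cfg)
        fit = fit_rrblup(G, y)
        qtl_idx = G.marker_index(truth.qtl_marker_ids)
        corr = np.corrcoef(fit.beta[qtl_idx], truth.qtl_effects)[0, 1]
        assert corr > 0
        assert abs(reml_h2(fit) - 0.5) < 0.2

    def test_serialization_round_trip(self, tmp_path, germplasm_pop):
        G, y, _ = germplasm_pop
        fit = fit_rrblup(G, y)
        p = tmp_path / "fit.json"
        fit.to_json(p)
        from gsalloc.rrblup import RRBLUPFit

        fit2 = RRBLUPFit.from_json(p)
        np.testing.assert_allclose(fit2.beta, fit.beta)
        assert fit2.lam == pytest.approx(fit.lam)
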