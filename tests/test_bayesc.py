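"""Weighted BayesC sampler: shrinkage, SNP-BLUP equivalence, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dgvcal import bayesc, simdata
from dgvcal.genotype_qc import GenotypeMatrix


def make_geno(Z, animals=None):
    Z = np.asarray(Z, dtype=float)
    k = Z.shape[1]
    markers = pd.DataFrame(
        {"name": [f"m{j}" for j in range(k)], "chromosome": "1",
         "position": np.arange(1, k + 1), "panel": "sim"}
    )
    ids = animals if animals is not None else np.arange(Z.shape[0])
    return GenotypeMatrix(animal_ids=np.asarray(ids), markers=markers, dosages=Z)


def make_debv(y, w=None):
    return pd.DataFrame(
        {"animal": np.arange(len(y)), "debv": y, "weight": w if w is not None else np.ones(len(y))}
    )


@pytest.fixture(scope="module")
def ridge_case():
    rng = np.random.default_rng(4)
    n, k = 50, 30
    Z = rng.integers(0, 3, size=(n, k)).astype(float)
    beta = np.zeros(k)
    beta[:5] = rng.standard_normal(5)
    y = Z @ beta + rng.standard_normal(n)
    return Z, y


class TestTrain:
    def test_zero_response_shrinks_to_zero(self):
        rng = np.random.default_rng(0)
        Z = rng.integers(0, 3, size=(40, 20)).astype(float)
        cfg = bayesc.BayesCConfig(
            pi=0.9, chain_length=2000, burn_in=500, seed=1,
            prior_scale_genetic=0.5, prior_scale_residual=1.0, estimate_variances=False,
        )
        fit = bayesc.train_bayesc(make_debv(np.zeros(40)), make_geno(Z), cfg)
        assert np.abs(fit.effects).max() < 0.05 * np.sqrt(0.5)

    def test_snp_blup_equivalence_at_pi_zero(self, ridge_case):
        """pi = 0 with fixed variances and equal weights is SNP-BLUP: the
        posterior mean solves the ridge system with an intercept."""
        Z, y = ridge_case
        n, k = Z.shape
        s2u, s2e = 0.5, 1.0
        cfg = bayesc.BayesCConfig(
            pi=0.0, chain_length=20000, burn_in=2000, estimate_variances=False,
            prior_scale_genetic=s2u, prior_scale_residual=s2e, seed=1,
        )
        fit = bayesc.train_bayesc(make_debv(y), make_geno(Z), cfg)
        X = np.hstack([np.ones((n, 1)), Z])
        lhs = X.T @ X
        lhs[1:, 1:] += (s2e / s2u) * np.eye(k)
        sol = np.linalg.solve(lhs, X.T @ y)
        # Monte-Carlo error: batch-mean standard errors are O(1/sqrt(chains));
        # 3 SE at this chain length is comfortably below 0.05
        np.testing.assert_allclose(fit.effects, sol[1:], atol=0.05)
        assert np.corrcoef(fit.effects, sol[1:])[0, 1] > 0.999

    def test_qtl_detection_beats_chance(self):
        rng = np.random.default_rng(10)
        n, k, nq = 400, 500, 10
        p = rng.uniform(0.2, 0.8, size=k)
        Z = rng.binomial(2, p, size=(n, k)).astype(float)
        qtl = rng.choice(k, nq, replace=False)
        beta = np.zeros(k)
        beta[qtl] = rng.standard_normal(nq) * 1.0
        g = Z @ beta
        y = g + rng.standard_normal(n) * g.std()
        cfg = bayesc.BayesCConfig(pi=0.95, chain_length=2000, burn_in=400, seed=2)
        fit = bayesc.train_bayesc(make_debv(y), make_geno(Z), cfg)
        top = np.argsort(fit.inclusion_freq)[-nq:]
        overlap = len(set(top) & set(qtl))
        # hypergeometric: P(overlap >= 3 | random) < 1e-3 at k=500, nq=10
        assert overlap >= 3

    def test_deterministic_under_seed(self, ridge_case):
        Z, y = ridge_case
        cfg = bayesc.BayesCConfig(pi=0.9, chain_length=1000, burn_in=200, seed=7)
        f1 = bayesc.train_bayesc(make_debv(y), make_geno(Z), cfg)
        f2 = bayesc.train_bayesc(make_debv(y), make_geno(Z), cfg)
        np.testing.assert_array_equal(f1.effects, f2.effects)
        assert f1.sigma2_u == f2.sigma2_u

    def test_weight_two_equals_duplicated_record(self, ridge_case):
        """With fixed variances the full conditionals depend on the data only
        through weighted cross-products, so a weight-2 record is exactly two
        weight-1 copies; the sampled chains coincide draw for draw."""
        Z, y = ridge_case
        n = len(y)
        cfg = bayesc.BayesCConfig(
            pi=0.5, chain_length=1500, burn_in=300, seed=3,
            estimate_variances=False, prior_scale_genetic=0.3, prior_scale_residual=1.0,
        )
        w2 = np.ones(n)
        w2[0] = 2.0
        fit_w = bayesc.train_bayesc(make_debv(y, w2), make_geno(Z), cfg)
        y_dup = np.concatenate([y, y[[0]]])
        Z_dup = np.vstack([Z, Z[[0]]])
        fit_d = bayesc.train_bayesc(
            make_debv(y_dup), make_geno(Z_dup), cfg
        )
        np.testing.assert_allclose(fit_w.effects, fit_d.effects, atol=1e-10)

    def test_input_errors(self, ridge_case):
        Z, y = ridge_case
        cfg = bayesc.BayesCConfig(chain_length=100, burn_in=10)
        with pytest.raises(ValueError, match="positive"):
            bayesc.train_bayesc(make_debv(y, np.zeros(len(y))), make_geno(Z), cfg)
        with pytest.raises(ValueError):
            bayesc.BayesCConfig(chain_length=100, burn_in=100).validate()
        Zm = Z.copy()
        Zm[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            bayesc.train_bayesc(make_debv(y), make_geno(Zm), cfg)


class TestInitializePriors:
    def test_scales_near_truth(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            n, k = 300, 200
            p = rng.uniform(0.2, 0.8, size=k)
            Z = rng.binomial(2, p, size=(n, k)).astype(float)
            beta = np.zeros(k)
            qtl = rng.choice(k, 20, replace=False)
            beta[qtl] = rng.standard_normal(20) * 0.3
            g = Z @ beta
            var_g = g.var()
            var_e = var_g * 0.6 / 0.4  # h2 = 0.4
            y = g + rng.standard_normal(n) * np.sqrt(var_e)
            cfg = bayesc.BayesCConfig(pi=0.95, chain_length=1500, burn_in=300, seed=seed)
            primed = bayesc.initialize_priors(make_debv(y), make_geno(Z), cfg)
            het = np.sum(2 * Z.mean(axis=0) / 2 * (1 - Z.mean(axis=0) / 2))
            implied_genvar = primed.prior_scale_genetic * (1 - cfg.pi) * het
            if 0.5 * var_g < implied_genvar < 2 * var_g and 0.5 * var_e < primed.prior_scale_residual < 2 * var_e:
                hits += 1
        assert hits >= 2

    def test_pi_near_one_guarded(self):
        rng = np.random.default_rng(0)
        Z = rng.integers(0, 3, size=(30, 10)).astype(float)
        y = rng.standard_normal(30)
        cfg = bayesc.BayesCConfig(pi=0.999999999, chain_length=200, burn_in=50, seed=0)
        primed = bayesc.initialize_priors(make_debv(y), make_geno(Z), cfg, preliminary_chain=200, preliminary_burn_in=50)
        assert np.isfinite(primed.prior_scale_genetic)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        Z = rng.integers(0, 3, size=(40, 20)).astype(float)
        y = rng.standard_normal(40)
        cfg = bayesc.BayesCConfig(chain_length=300, burn_in=50, seed=5)
        p1 = bayesc.initialize_priors(make_debv(y), make_geno(Z), cfg, 300, 50)
        p2 = bayesc.initialize_priors(make_debv(y), make_geno(Z), cfg, 300, 50)
        assert p1.prior_scale_genetic == p2.prior_scale_genetic

    def test_degenerate_variance_errors(self):
        Z = np.ones((20, 5))
        cfg = bayesc.BayesCConfig(chain_length=200, burn_in=20, seed=0)
        with pytest.raises(ValueError, match="variance"):
            bayesc.initialize_priors(make_debv(np.ones(20)), make_geno(Z), cfg, 200, 20)


class TestPredict:
    def test_zero_effects_zero_dgv(self):
        G = make_geno(np.random.default_rng(0).integers(0, 3, size=(5, 4)).astype(float))
        est = bayesc.MarkerEffectEstimates(
            marker_names=G.marker_names, intercept=1.0, effects=np.zeros(4),
            inclusion_freq=np.zeros(4), sigma2_u=1.0, sigma2_e=1.0,
        )
        assert (bayesc.predict_dgv(G, est)["dgv"] == 0).all()

    def test_single_effect_identity(self):
        Z = np.array([[0.0, 1.0], [2.0, 2.0]])
        G = make_geno(Z)
        est = bayesc.MarkerEffectEstimates(
            marker_names=G.marker_names, intercept=0.0, effects=np.array([0.0, 0.5]),
            inclusion_freq=np.zeros(2), sigma2_u=1.0, sigma2_e=1.0,
        )
        np.testing.assert_allclose(bayesc.predict_dgv(G, est)["dgv"], 0.5 * Z[:, 1])

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(2)
        Z = rng.integers(0, 3, size=(20, 50)).astype(float)
        G = make_geno(Z)
        effects = rng.standard_normal(50)
        est = bayesc.MarkerEffectEstimates(
            marker_names=G.marker_names, intercept=0.3, effects=effects,
            inclusion_freq=np.zeros(50), sigma2_u=1.0, sigma2_e=1.0,
        )
        got = bayesc.predict_dgv(G, est)["dgv"].to_numpy()
        want = np.array([sum(Z[i, j] * effects[j] for j in range(50)) for i in range(20)])
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_marker_mismatch_names_offenders(self):
        G = make_geno(np.zeros((2, 3)))
        est = bayesc.MarkerEffectEstimates(
            marker_names=np.array(["m0", "m1", "other"]), intercept=0.0,
            effects=np.zeros(3), inclusion_freq=np.zeros(3), sigma2_u=1.0, sigma2_e=1.0,
        )
        with pytest.raises(ValueError, match="other"):
            bayesc.predict_dgv(G, est)


def test_predictive_signal_grows_with_training_size():
    """Held-out DGV accuracy increases with training size (within noise)."""
    cfg = simdata.SimulationConfig(
        n_founders=150, n_generations=4, n_markers=300, n_qtl=30,
        offspring_per_mating=2.0, seed=31,
    )
    herd = simdata.simulate_herd(cfg)
    rng = np.random.default_rng(0)
    ids = np.array(herd.genotypes.animal_ids)
    holdout = set(rng.choice(ids, size=150, replace=False))
    train_pool = [a for a in ids if a not in holdout]
    tbv = herd.truth.tbv_series()
    y = pd.Series(
        tbv + rng.standard_normal(len(ids)) * np.sqrt(herd.truth.true_residual_variance),
        index=ids,
    )
    accs = []
    for n_train in (100, 250, len(train_pool)):
        sub = train_pool[:n_train]
        debv = pd.DataFrame({"animal": sub, "debv": y[sub].to_numpy(), "weight": 1.0})
        cfgb = bayesc.BayesCConfig(pi=0.9, chain_length=1500, burn_in=300, seed=5)
        fit = bayesc.train_bayesc(debv, herd.genotypes, cfgb)
        pred = bayesc.predict_dgv(
            herd.genotypes.select_animals(sorted(holdout)), fit
        ).set_index("animal")["dgv"]
        accs.append(np.corrcoef(pred, tbv[pred.index])[0, 1])
    assert accs[0] > 0
    assert accs[-1] > accs[0]
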