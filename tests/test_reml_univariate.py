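import numpy as np
import pytest

from woolgs.grm import GRM, vanraden_grm
from woolgs.reml import UvFit, _uv_loglik, build_fixed_design, fit_uvlmm, predict_gebv
from woolgs.simulate import SimConfig, simulate_population
from scipy.linalg import eigh

from _oracles import direct_reml_loglik, ridge_snp_blup_gebv


@pytest.fixture(scope="module")
def fitted(small_population, small_grm_stable):
    _, geno, pheno, _ = small_population
    col = pheno.trait_columns(pheno.traits[0])[1]
    y = pheno.values[col]
    fit = fit_uvlmm(y, pheno, small_grm_stable)
    return y, pheno, fit


class TestFixedDesign:
    def test_treatment_coding_levels(self, small_population):
        _, _, pheno, _ = small_population
        d = build_fixed_design(pheno.sex, pheno.batch)
        assert d.labels[0] == "intercept"
        assert any(l.startswith("sex[") for l in d.labels)
        assert not d.dropped

    def test_aliased_column_dropped(self):
        sex = np.array(["M", "F"] * 10, dtype=object)
        batch = sex.copy()  # batch identical to sex: aliased
        d = build_fixed_design(sex, batch)
        assert len(d.dropped) == 1
        assert np.linalg.matrix_rank(d.X) == d.X.shape[1]


class TestUnivariateFit:
    def test_h2_is_variance_ratio(self, fitted):
        _, _, fit = fitted
        assert fit.h2 == pytest.approx(fit.sigma2_u / (fit.sigma2_u + fit.sigma2_e))
        assert 0.0 <= fit.h2 <= 1.0
        assert fit.converged

    def test_rotated_loglik_matches_direct_dense(self, small_population, small_grm_stable, rng):
        """Eigen-rotation is an exact reformulation of the dense-V likelihood."""
        _, geno, pheno, _ = small_population
        col = pheno.trait_columns(pheno.traits[0])[2]
        y = pheno.values[col].to_numpy()
        G = small_grm_stable.matrix
        X = build_fixed_design(pheno.sex, pheno.batch).X
        s, U = eigh(G)
        yt, Xt = U.T @ y, U.T @ X
        for _ in range(25):
            s2u = float(10 ** rng.uniform(-2, 1))
            s2e = float(10 ** rng.uniform(-2, 1))
            assert _uv_loglik(s2u, s2e, np.clip(s, 0, None), yt, Xt) == pytest.approx(
                direct_reml_loglik(y, X, G, s2u, s2e), abs=1e-8
            )

    def test_optimum_beats_coarse_grid(self, fitted, small_population, small_grm_stable):
        _, geno, pheno, _ = small_population
        y, _, fit = fitted
        obs = np.isfinite(y.to_numpy())
        G = small_grm_stable.matrix
        X = build_fixed_design(pheno.sex, pheno.batch).X
        best = max(
            direct_reml_loglik(y.to_numpy(), X, G, lam * s2e, s2e)
            for lam in np.logspace(-4, 4, 30)
            for s2e in np.linspace(0.1, 1.5, 15)
        )
        assert fit.loglik_reml >= best - 1e-6

    def test_null_trait_boundary_behaviour(self):
        """Pure-noise traits estimate to (nearly) zero heritability."""
        h2s = []
        for seed in range(8):
            cfg = SimConfig(n_individuals=300, n_markers=2000, n_qtl=100,
                            n_sires=12, n_dams=50, seed=800 + seed)
            geno, pheno, _ = simulate_population(cfg)
            G = vanraden_grm(geno, on_monomorphic="drop")
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(geno.n_individuals)  # no genetic signal
            h2s.append(fit_uvlmm(y, pheno, G).h2)
        assert np.median(h2s) < 0.05

    def test_shift_invariance(self, fitted, small_grm_stable):
        y, pheno, fit = fitted
        shifted = fit_uvlmm(y + 100.0, pheno, small_grm_stable)
        assert shifted.sigma2_u == pytest.approx(fit.sigma2_u, rel=1e-6)
        assert shifted.sigma2_e == pytest.approx(fit.sigma2_e, rel=1e-6)
        np.testing.assert_allclose(shifted.gebv, fit.gebv, atol=1e-8)
        assert shifted.beta_hat[0] == pytest.approx(fit.beta_hat[0] + 100.0, abs=1e-6)
        np.testing.assert_allclose(shifted.beta_hat[1:], fit.beta_hat[1:], atol=1e-6)

    def test_unphenotyped_get_gebvs(self, small_population, small_grm_stable):
        _, geno, pheno, _ = small_population
        col = pheno.trait_columns(pheno.traits[0])[1]
        y = pheno.values[col].to_numpy().copy()
        y[:25] = np.nan
        fit = fit_uvlmm(y, pheno, small_grm_stable)
        assert np.isfinite(fit.gebv).all()
        assert len(fit.gebv) == small_grm_stable.n
        assert len(fit.phenotyped_ids) == np.isfinite(y).sum()

    def test_too_few_records_rejected(self, small_population, small_grm_stable):
        _, geno, pheno, _ = small_population
        y = np.full(small_grm_stable.n, np.nan)
        y[:10] = 1.0
        with pytest.raises(ValueError, match="phenotyped"):
            fit_uvlmm(y, pheno, small_grm_stable)

    def test_se_calibration(self):
        """Reported delta-method SEs track the empirical spread of h2-hat.

        One genotype panel, many phenotype draws at h2 = 0.3; the SD of the
        estimates across replicates should agree with the mean reported SE
        within 30%.
        """
        cfg0 = SimConfig(n_individuals=250, n_markers=2000, n_qtl=100,
                         n_sires=10, n_dams=40, h2=(0.3, 0.3, 0.3), seed=4242)
        geno, _, _ = simulate_population(cfg0)
        G = vanraden_grm(geno, on_monomorphic="drop")
        est, ses = [], []
        from dataclasses import replace

        from woolgs.simulate import simulate_phenotypes

        for rep in range(200):
            cfg = replace(cfg0, seed=5000 + rep)
            pheno, _ = simulate_phenotypes(geno, cfg)
            fit = fit_uvlmm(pheno.values[pheno.trait_columns(cfg.trait)[1]], pheno, G)
            if not fit.boundary:
                est.append(fit.h2)
                ses.append(fit.se_h2)
        ratio = np.std(est, ddof=1) / np.mean(ses)
        assert 0.7 < ratio < 1.3


class TestPrediction:
    def test_predict_gebv_identity_on_fitted_ids(self, fitted, small_grm_stable):
        _, _, fit = fitted
        got = predict_gebv(fit, small_grm_stable, fit.individual_ids)
        np.testing.assert_allclose(got, fit.gebv)

    def test_unknown_id_rejected(self, fitted, small_grm_stable):
        _, _, fit = fitted
        with pytest.raises(KeyError):
            predict_gebv(fit, small_grm_stable, ["nobody"])

    def test_genomically_unrelated_individual_predicts_zero(self, small_population):
        _, geno, pheno, _ = small_population
        base = vanraden_grm(geno, on_monomorphic="drop")
        n = base.n
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = base.matrix
        M[n, n] = 1.0  # unrelated outsider
        ids = np.append(base.individual_ids, "outsider")
        G = GRM(M, ids, base.n_markers_used, base.denom)
        col = pheno.trait_columns(pheno.traits[0])[1]
        y = np.append(pheno.values[col].to_numpy(), np.nan)
        import pandas as pd

        from woolgs.genio import PhenotypeTable

        pheno_plus = PhenotypeTable(
            individual_ids=ids,
            sex=np.append(pheno.sex, "M"),
            batch=np.append(pheno.batch, pheno.batch[0]),
            values=pd.DataFrame({col: y}, index=pd.Index(ids, name="id")),
            time_labels=pheno.time_labels,
        )
        fit = fit_uvlmm(y, pheno_plus, G)
        outsider = predict_gebv(fit, G, ["outsider"])[0]
        assert abs(outsider) < 1e-10

    def test_gblup_equals_snp_blup_ridge(self, small_population):
        """The GRM model and the marker-effects ridge model are the same model."""
        _, geno, pheno, _ = small_population
        G = vanraden_grm(geno, on_monomorphic="drop")  # unstabilized: exact match
        col = pheno.trait_columns(pheno.traits[0])[1]
        y = pheno.values[col].to_numpy().copy()
        y[:20] = np.nan
        fit = fit_uvlmm(y, pheno, G)
        obs = np.isfinite(y)
        X_obs = build_fixed_design(pheno.sex[obs], pheno.batch[obs]).X
        oracle = ridge_snp_blup_gebv(
            geno.dosages, geno.allele_freq, y, X_obs, obs,
            fit.sigma2_u, fit.sigma2_e, G.denom,
        )
        rel = np.max(np.abs(fit.gebv - oracle)) / np.max(np.abs(oracle))
        assert rel < 1e-6
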