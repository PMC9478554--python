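import numpy as np
import pandas as pd
import pytest
from scipy import stats

from woolgs.evaluate import (
    accuracy,
    compare_accuracies,
    correct_phenotypes,
    density_scan,
    make_folds,
    run_cv,
)
from woolgs.genio import PhenotypeTable
from woolgs.grm import stabilize
from woolgs.reml import build_fixed_design, fit_uvlmm

from _oracles import ols_residuals, welch_t_test


def _pheno(ids, sex, batch, columns):
    return PhenotypeTable(
        individual_ids=np.asarray(ids, dtype=object),
        sex=np.asarray(sex, dtype=object),
        batch=np.asarray(batch, dtype=object),
        values=pd.DataFrame(columns, index=pd.Index(ids, name="id")),
    )


class TestCorrectPhenotypes:
    def test_batch_determined_trait_corrects_to_zero(self):
        ids = [f"i{j}" for j in range(8)]
        batch = ["b1"] * 4 + ["b2"] * 4
        y = np.where(np.array(batch) == "b1", 1.0, 3.0)
        pheno = _pheno(ids, ["M", "F"] * 4, batch, {"T_70": y})
        yc = correct_phenotypes(pheno)["T_70"]
        np.testing.assert_allclose(yc, 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_sex(self, rng):
        ids = [f"i{j}" for j in range(200)]
        sex = np.array(["M", "F"] * 100, dtype=object)
        y = (sex == "M") * 0.7 + rng.standard_normal(200)
        pheno = _pheno(ids, sex, ["b1"] * 200, {"T_70": y})
        yc = correct_phenotypes(pheno)["T_70"].to_numpy()
        assert abs(np.corrcoef(yc, (sex == "M").astype(float))[0, 1]) < 1e-10
        assert abs(yc.mean()) < 1e-12

    def test_matches_ols_oracle(self, small_population):
        _, _, pheno, _ = small_population
        col = pheno.values.columns[1]
        yc = correct_phenotypes(pheno)[col].to_numpy()
        X = build_fixed_design(pheno.sex, pheno.batch).X
        expected = ols_residuals(pheno.values[col].to_numpy(), X)
        np.testing.assert_allclose(yc, expected, atol=1e-10)

    def test_missing_rows_stay_missing(self, small_population):
        _, _, pheno, _ = small_population
        col = pheno.values.columns[0]
        vals = pheno.values.copy()
        vals.iloc[:5, 0] = np.nan
        pheno2 = _pheno(pheno.individual_ids, pheno.sex, pheno.batch, vals)
        yc = correct_phenotypes(pheno2)[col]
        assert yc.iloc[:5].isna().all()
        assert yc.iloc[5:].notna().all()


class TestFolds:
    def test_629_in_10_folds(self):
        ids = [f"r{j}" for j in range(629)]
        folds = make_folds(ids, 10, seed=0)
        sizes = sorted(folds.fold_of.value_counts().tolist())
        assert sizes == [62] + [63] * 9

    def test_one_per_fold_when_n_equals_k(self):
        folds = make_folds(list("abcde"), 5, seed=1)
        assert sorted(folds.fold_of.value_counts().tolist()) == [1] * 5

    def test_deterministic(self):
        ids = [f"r{j}" for j in range(101)]
        a = make_folds(ids, 10, seed=5).fold_of
        b = make_folds(ids, 10, seed=5).fold_of
        pd.testing.assert_series_equal(a, b)

    def test_every_individual_once(self):
        ids = [f"r{j}" for j in range(47)]
        folds = make_folds(ids, 7, seed=2)
        assert set(folds.fold_of.index) == set(ids)
        assert folds.fold_of.value_counts().sum() == 47

    def test_bad_fold_counts(self):
        with pytest.raises(ValueError):
            make_folds(list("abc"), 1, seed=0)
        with pytest.raises(ValueError):
            make_folds(list("abc"), 4, seed=0)


class TestAccuracy:
    def test_identity_and_affine(self, rng):
        y = rng.standard_normal(50)
        assert accuracy(y, y) == pytest.approx(1.0)
        assert accuracy(y, -2.0 * y + 5.0) == pytest.approx(-1.0)

    def test_degenerate_inputs_are_missing(self, rng):
        y = rng.standard_normal(10)
        assert np.isnan(accuracy(y, np.zeros(10)))
        assert np.isnan(accuracy(y[:2], y[:2]))

    def test_null_correlation_magnitude(self, rng):
        rs = [
            abs(accuracy(rng.standard_normal(63), rng.standard_normal(63)))
            for _ in range(40)
        ]
        # |r| under independence at n=63 rarely reaches 0.35
        assert np.mean(np.array(rs) < 0.35) >= 0.9


class TestCompareAccuracies:
    def test_identical_groups(self):
        t, p = compare_accuracies([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert (t, p) == (0.0, 1.0)

    def test_large_shift_significant(self, rng):
        b = rng.normal(0.2, 0.03, size=30)
        a = b + 10 * b.std(ddof=1)
        t, p = compare_accuracies(a, b)
        assert p < 1e-6

    def test_matches_textbook_welch(self, rng):
        for _ in range(5):
            a = rng.normal(0, 1, size=rng.integers(5, 40))
            b = rng.normal(0.3, 2, size=rng.integers(5, 40))
            got = compare_accuracies(a, b)
            exp = welch_t_test(a, b)
            assert got[0] == pytest.approx(exp[0], abs=1e-10)
            assert got[1] == pytest.approx(exp[1], abs=1e-10)

    def test_student_variant(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=15)
        t, p = compare_accuracies(a, b, equal_var=True)
        exp = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(exp.statistic)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            compare_accuracies([0.1], [0.2, 0.3])


@pytest.fixture(scope="module")
def folds(small_population):
    _, geno, _, _ = small_population
    return make_folds(geno.individual_ids, n_folds=4, seed=11)


class TestRunCV:
    def test_uvlmm_masking_contract(self, small_population, small_grm, folds):
        _, geno, pheno, _ = small_population
        res = run_cv(pheno, small_grm, "uvLMM", folds)
        assert res.per_fold["masked_in_validation"].all()
        assert len(res.per_fold) == 4 * 3
        assert res.per_fold["accuracy"].abs().max() <= 1.0

    def test_mvlmm_leaves_all_records_out(self, small_population, small_grm, folds):
        _, geno, pheno, _ = small_population
        res = run_cv(pheno, small_grm, "mvLMM", folds)
        assert res.per_fold["masked_in_validation"].all()

    def test_partial_strategies_flag_observed_ages(self, small_population, small_grm, folds):
        _, geno, pheno, _ = small_population
        res = run_cv(pheno, small_grm, "mvLMM3", folds)
        flags = res.per_fold.groupby("time")["masked_in_validation"].all()
        assert not flags.loc[0] and not flags.loc[1] and flags.loc[2]
        res23 = run_cv(pheno, small_grm, "mvLMM23", folds)
        flags23 = res23.per_fold.groupby("time")["masked_in_validation"].all()
        assert not flags23.loc[0] and flags23.loc[1] and flags23.loc[2]

    def test_mean_accuracy_aggregates_converged_folds(self, small_population, small_grm, folds):
        _, geno, pheno, _ = small_population
        res = run_cv(pheno, small_grm, "uvLMM", folds)
        ok = res.per_fold[res.per_fold["converged"]]
        assert res.mean_accuracy(1) == pytest.approx(
            ok[ok["time"] == 1]["accuracy"].mean()
        )

    def test_unknown_model_rejected(self, small_population, small_grm, folds):
        _, geno, pheno, _ = small_population
        with pytest.raises(ValueError):
            run_cv(pheno, small_grm, "blup++", folds)


class TestDensityScan:
    def test_single_full_density_equals_direct_fit(self, small_population, small_grm):
        _, geno, pheno, _ = small_population
        res = density_scan(
            geno, pheno, [geno.n_markers], n_reps=1, base_seed=3, include_cv=False
        )
        col = pheno.values.columns[1]
        direct = fit_uvlmm(pheno.values[col], pheno, stabilize(small_grm))
        got = res.replicates.set_index("column").loc[col, "h2"]
        assert got == pytest.approx(direct.h2, abs=1e-6)
        assert res.grm_correlations.empty

    def test_pairwise_correlation_count(self, small_population):
        _, geno, pheno, _ = small_population
        res = density_scan(
            geno, pheno, [200, 400], n_reps=4, base_seed=1, include_cv=False
        )
        assert len(res.grm_correlations) == 2 * 6  # C(4,2) per density
        assert res.densities == [200, 400]
        assert (res.replicates.groupby("density").size() == 4 * 3).all()

    def test_replicates_deterministic_in_base_seed(self, small_population):
        _, geno, pheno, _ = small_population
        a = density_scan(geno, pheno, [300], n_reps=2, base_seed=9, include_cv=False)
        b = density_scan(geno, pheno, [300], n_reps=2, base_seed=9, include_cv=False)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_density_above_panel_rejected(self, small_population):
        _, geno, pheno, _ = small_population
        with pytest.raises(ValueError):
            density_scan(geno, pheno, [geno.n_markers + 1], n_reps=1)
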