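"""Cross-validation designs, marker-density scans and accuracy comparisons.

Prediction accuracy is the Pearson correlation, inside the validation fold,
between GEBVs and *corrected phenotypes* yc — the phenotype with OLS-estimated
intercept, sex and batch effects removed.  yc is computed once on the full
data so the evaluation target stays fixed across models and densities.

Four model tags are supported in cross-validation:

* ``uvLMM``    — univariate fit per age; validation records of that age masked.
* ``mvLMM``    — trivariate fit; validation individuals lose all three ages.
* ``mvLMM23``  — trivariate fit; validation individuals lose ages 2 and 3.
* ``mvLMM3``   — trivariate fit; validation individuals lose age 3 only.

The GRM always covers the whole population — information flows to masked
individuals through genomic relationships, which is the GBLUP mechanism
being evaluated; no masked *record* ever enters a training fit (each fit
object carries the records it used, and `run_cv` asserts the exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, PhenotypeTable, subsample_markers
from .grm import GRM, grm_correlation, stabilize, vanraden_grm
from .reml import MvFit, build_fixed_design, fit_mvlmm, fit_uvlmm, predict_gebv
from .simulate import mask_records

__all__ = [
    "FoldAssignment",
    "CVResult",
    "DensityScanResult",
    "correct_phenotypes",
    "make_folds",
    "accuracy",
    "run_cv",
    "density_scan",
    "compare_accuracies",
]

MODELS = ("uvLMM", "mvLMM", "mvLMM23", "mvLMM3")
_MASKED_TIMES = {"mvLMM": (0, 1, 2), "mvLMM23": (1, 2), "mvLMM3": (2,)}


@dataclass
class FoldAssignment:
    n_folds: int
    fold_of: pd.Series  # individual id -> fold index
    seed: int

    def validation_ids(self, fold: int) -> np.ndarray:
        return self.fold_of.index[self.fold_of == fold].to_numpy()


@dataclass
class CVResult:
    model: str
    trait: str
    per_fold: pd.DataFrame  # fold, time, accuracy, masked_in_validation, converged
    folds: FoldAssignment
    n_markers: int
    n_failed_folds: int = 0

    def mean_accuracy(self, time_index: int | None = None) -> float | pd.Series:
        ok = self.per_fold[self.per_fold["converged"]]
        means = ok.groupby("time")["accuracy"].mean()
        return means if time_index is None else float(means.loc[time_index])


@dataclass
class DensityScanResult:
    densities: list[int]
    replicates: pd.DataFrame  # density, rep, seed, column, h2, cv_accuracy
    grm_correlations: pd.DataFrame  # density, rep_a, rep_b, correlation
    n_reps: int


def correct_phenotypes(pheno: PhenotypeTable, columns: list[str] | None = None) -> pd.DataFrame:
    """OLS-corrected phenotypes: y minus fitted intercept + sex + batch.

    The linear model is fit per column on *all* individuals with a record,
    and the full fitted value (intercept included) is removed, so each yc
    column is mean-zero and exactly orthogonal to the design.
    """
    cols = columns or list(pheno.values.columns)
    design = build_fixed_design(pheno.sex, pheno.batch)
    X = design.X
    out = {}
    for col in cols:
        y = pheno.values[col].to_numpy(dtype=float)
        obs = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        yc = np.full_like(y, np.nan)
        yc[obs] = y[obs] - X[obs] @ beta
        out[col] = yc
    return pd.DataFrame(out, index=pd.Index(pheno.individual_ids, name="id"))


def make_folds(ids, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Random folds with sizes differing by at most one."""
    ids = np.asarray(ids, dtype=object)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > ids.size:
        raise ValueError("more folds than individuals")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ids.size)
    fold = np.empty(ids.size, dtype=int)
    fold[order] = np.arange(ids.size) % n_folds
    return FoldAssignment(n_folds=n_folds, fold_of=pd.Series(fold, index=pd.Index(ids, name="id")), seed=seed)


def accuracy(yc, gebv) -> float:
    """Pearson correlation between aligned yc and GEBV; NaN if degenerate."""
    yc = np.asarray(yc, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    ok = np.isfinite(yc) & np.isfinite(gebv)
    if ok.sum() < 3:
        return float("nan")
    a, b = yc[ok], gebv[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def run_cv(
    pheno: PhenotypeTable,
    grm: GRM,
    model: str,
    folds: FoldAssignment,
    trait: str | None = None,
    yc: pd.DataFrame | None = None,
    stabilize_eps: float = 1e-6,
    **fit_kwargs,
) -> CVResult:
    """Cross-validated genomic prediction under one model tag.

    Returns per-fold accuracies per age; for the partial leave-out models the
    accuracy of an age whose validation records stayed observed is reported
    too, flagged ``masked_in_validation=False``.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    trait = trait or pheno.traits[0]
    cols = pheno.trait_columns(trait)
    if yc is None:
        yc = correct_phenotypes(pheno, cols)
    G = stabilize(grm, stabilize_eps)
    rows = []
    n_failed = 0
    for fold in range(folds.n_folds):
        val_ids = folds.validation_ids(fold)
        val_idx = grm.index_of(val_ids)
        if model == "uvLMM":
            for t, col in enumerate(cols):
                masked = mask_records(pheno, val_ids, [col])
                y = masked.values[col]
                fit = fit_uvlmm(y, masked, G, **fit_kwargs)
                assert not set(val_ids) & set(fit.phenotyped_ids), "masked record leaked into training"
                acc = accuracy(yc[col].loc[val_ids], predict_gebv(fit, G, val_ids))
                rows.append((fold, t, acc, True, fit.converged))
                if not fit.converged:
                    n_failed += 1
        else:
            mask_t = _MASKED_TIMES[model]
            masked = mask_records(pheno, val_ids, [cols[t] for t in mask_t])
            Y = masked.values[cols]
            start = None
            if model != "mvLMM":
                # warm start from the leave-all-out fit of the same fold:
                # trained on training individuals only, so no masked record
                # influences it, and it sits near the final optimum
                all_out = mask_records(pheno, val_ids, cols)
                pre = fit_mvlmm(all_out.values[cols], all_out, G, **fit_kwargs)
                start = (pre.Sigma_u, pre.Sigma_e)
            fit = fit_mvlmm(Y, masked, G, start=start, **fit_kwargs)
            observed = set(fit.observed_records)
            for t in mask_t:
                assert not any((vid, t) in observed for vid in val_ids), "masked record leaked into training"
            gebv = predict_gebv(fit, G, val_ids)
            for t, col in enumerate(cols):
                acc = accuracy(yc[col].loc[val_ids], gebv[:, t])
                rows.append((fold, t, acc, t in mask_t, fit.converged))
            if not fit.converged:
                n_failed += 1
    per_fold = pd.DataFrame(rows, columns=["fold", "time", "accuracy", "masked_in_validation", "converged"])
    return CVResult(
        model=model,
        trait=trait,
        per_fold=per_fold,
        folds=folds,
        n_markers=grm.n_markers_used,
        n_failed_folds=n_failed,
    )


def _replicate_seed(base_seed: int, density_index: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(density_index, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def density_scan(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    densities: list[int],
    n_reps: int = 30,
    base_seed: int = 0,
    trait: str | None = None,
    include_cv: bool = True,
    n_folds: int = 10,
    **fit_kwargs,
) -> DensityScanResult:
    """Marker-density experiment: subsample, build GRM, estimate, cross-validate.

    For every density d and replicate r a fresh random marker subset is drawn
    (seed derived deterministically from ``base_seed``), a VanRaden GRM is
    built, per-age heritabilities are estimated with the univariate model,
    optionally a univariate CV accuracy is computed, and all pairwise GRM
    correlations among the replicates of the density are recorded.
    """
    densities = sorted(int(d) for d in densities)
    if densities[-1] > geno.n_markers:
        raise ValueError("largest density exceeds marker count")
    trait = trait or pheno.traits[0]
    cols = pheno.trait_columns(trait)
    yc = correct_phenotypes(pheno, cols)
    folds = make_folds(geno.individual_ids, n_folds=n_folds, seed=base_seed) if include_cv else None
    rep_rows, corr_rows = [], []
    for di, d in enumerate(densities):
        grms = []
        for r in range(n_reps):
            seed = _replicate_seed(base_seed, di, r)
            sub = subsample_markers(geno, d, seed)
            grm = vanraden_grm(sub, on_monomorphic="drop")
            grms.append(grm)
            Gs = stabilize(grm)
            accs = None
            if include_cv:
                cv = run_cv(pheno, grm, "uvLMM", folds, trait=trait, yc=yc, **fit_kwargs)
                accs = cv.mean_accuracy()
            for t, col in enumerate(cols):
                try:
                    fit = fit_uvlmm(pheno.values[col], pheno, Gs, **fit_kwargs)
                    h2 = fit.h2
                except Exception:
                    h2 = float("nan")
                acc = float(accs.loc[t]) if accs is not None else float("nan")
                rep_rows.append((d, r, seed, col, h2, acc))
        for a in range(n_reps):
            for b in range(a + 1, n_reps):
                corr_rows.append((d, a, b, grm_correlation(grms[a], grms[b])))
    return DensityScanResult(
        densities=densities,
        replicates=pd.DataFrame(
            rep_rows, columns=["density", "rep", "seed", "column", "h2", "cv_accuracy"]
        ),
        grm_correlations=pd.DataFrame(
            corr_rows, columns=["density", "rep_a", "rep_b", "correlation"]
        ),
        n_reps=n_reps,
    )


def compare_accuracies(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test between replicate accuracy groups (Welch by default).

    Degenerate case: both groups constant with equal means -> (0.0, 1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
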