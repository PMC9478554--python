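"""Synthetic populations for genomic-prediction experiments.

The generator emulates the data structure of a mid-size rabbit breeding
population: several hundred genotyped individuals of two sexes in a few
management batches, LD-structured biallelic SNPs, and one trait recorded at
three ages (70, 140 and 210 days) treated as three correlated traits.

Genotypes: founder haplotypes are first-order Markov chains along each
chromosome whose adjacent-marker correlation is ``ld_rho``; the study
population is then bred as one offspring generation from ``n_sires`` sires
and ``n_dams`` dams (parents drawn uniformly per offspring, mimicking
mixed-semen insemination without recorded pedigree), each gamete a
recombined copy of the parent's two haplotypes.  The resulting half- and
full-sib families give the genomic relationship matrix the eigenvalue
spread that real farm populations have — without it, variance components
are barely identifiable at a few hundred individuals and masked
individuals would be genomically unrelated to every training animal.
Setting ``n_sires=None`` produces unrelated individuals instead.

Phenotypes: a set of pleiotropic QTL gets effect vectors drawn from a
trivariate normal with the target genetic correlation, breeding values are
the QTL dosage scores, and genetic and residual parts are rescaled on the
realized sample so the *realized* variance ratio equals the target
heritability exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, PhenotypeTable

__all__ = ["SimConfig", "TrueValues", "simulate_genotypes", "simulate_phenotypes", "simulate_population", "mask_records"]


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults mirror the study design this toolkit is built around: 629
    individuals (298 males / 331 females), three measurement ages, target
    heritabilities (0.05, 0.30, 0.30) spanning the low-to-high range typical
    of wool traits, and a 0.8 genetic correlation between ages.
    """

    n_individuals: int = 629
    n_markers: int = 10_000
    n_chromosomes: int = 10
    ld_rho: float = 0.9
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_qtl: int = 200
    n_sires: int | None = 25
    n_dams: int = 100
    n_generations: int = 5
    crossovers_per_chrom: float = 1.0
    h2: tuple[float, float, float] = (0.05, 0.30, 0.30)
    genetic_corr: np.ndarray = field(default_factory=lambda: np.array(
        [[1.0, 0.8, 0.8], [0.8, 1.0, 0.8], [0.8, 0.8, 1.0]]))
    residual_corr: np.ndarray | None = None
    sex_effect: float = 0.5
    batch_effects: tuple[float, ...] = (0.0, 0.3, 0.6)
    male_fraction: float = 298 / 629
    trait: str = "WSW"
    time_labels: tuple[int, int, int] = (70, 140, 210)
    seed: int = 0

    def __post_init__(self) -> None:
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not all(0.0 < h < 1.0 for h in self.h2):
            raise ValueError("each h2 must lie in the open interval (0, 1)")
        C = self.genetic_corr
        if C.shape != (3, 3) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("genetic_corr must be symmetric 3x3 with unit diagonal")
        if np.linalg.eigvalsh(C)[0] <= 0:
            raise ValueError("genetic_corr must be positive definite")
        if self.residual_corr is not None:
            R = np.asarray(self.residual_corr, dtype=float)
            if np.linalg.eigvalsh(R)[0] <= 0:
                raise ValueError("residual_corr must be positive definite")
            self.residual_corr = R
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_sires is not None and (self.n_sires < 1 or self.n_dams < 1):
            raise ValueError("n_sires and n_dams must be positive")

    @property
    def n_batches(self) -> int:
        return len(self.batch_effects)


@dataclass
class TrueValues:
    """Ground truth kept aside for parameter-recovery checks."""

    true_breeding_values: np.ndarray  # n x 3
    qtl_ids: np.ndarray
    qtl_effects: np.ndarray  # n_qtl x 3
    realized_h2: np.ndarray  # length 3

    def to_frame(self, individual_ids, time_labels=(70, 140, 210)) -> pd.DataFrame:
        return pd.DataFrame(
            self.true_breeding_values,
            index=pd.Index(individual_ids, name="id"),
            columns=[f"tbv_{t}" for t in time_labels],
        )


def _markov_haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray, rho: float) -> np.ndarray:
    """Binary haplotypes with adjacent-marker correlation rho at the given freqs.

    For target correlation rho between adjacent Bernoulli markers with
    frequencies (p1, p2) the conditional success probabilities are
    p2 + rho*sqrt(p2 q2 / (p1 q1)) * (x1 - p1); they are clipped into [0,1],
    which slightly attenuates realized LD at extreme frequency jumps.
    """
    m = freqs.size
    H = np.empty((n_hap, m), dtype=np.int8)
    u = rng.random((n_hap, m))
    H[:, 0] = u[:, 0] < freqs[0]
    for k in range(1, m):
        p_prev, p_k = freqs[k - 1], freqs[k]
        slope = rho * np.sqrt(p_k * (1 - p_k) / (p_prev * (1 - p_prev)))
        cond = np.clip(p_k + slope * (H[:, k - 1] - p_prev), 0.0, 1.0)
        H[:, k] = u[:, k] < cond
    return H


def _meiosis(rng: np.random.Generator, parent_h1: np.ndarray, parent_h2: np.ndarray,
             expected_crossovers: float) -> np.ndarray:
    """One gamete per row: switch between the parent's two haplotypes along
    the chromosome with on average ``expected_crossovers`` switch points."""
    n, mc = parent_h1.shape
    s = expected_crossovers / max(mc - 1, 1)
    flips = np.empty((n, mc), dtype=bool)
    flips[:, 0] = rng.random(n) < 0.5
    flips[:, 1:] = rng.random((n, mc - 1)) < s
    use_h2 = np.logical_xor.accumulate(flips, axis=1)
    return np.where(use_h2, parent_h2, parent_h1)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """LD- and family-structured biallelic dosages, deterministic under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_markers
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    related = cfg.n_sires is not None
    if related:
        n_pool = cfg.n_sires + cfg.n_dams
        # pedigree: a closed pool bred for n_generations, then the study cohort
        pool_parents = [
            (rng.integers(0, cfg.n_sires, size=n_pool),
             cfg.n_sires + rng.integers(0, cfg.n_dams, size=n_pool))
            for _ in range(max(cfg.n_generations - 1, 0))
        ]
        sire_of = rng.integers(0, cfg.n_sires, size=n)
        dam_of = cfg.n_sires + rng.integers(0, cfg.n_dams, size=n)
    dosage = np.empty((n, m), dtype=float)
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    start = 0
    for c, mc in enumerate(per_chrom):
        if mc == 0:
            continue
        block = slice(start, start + mc)
        if related:
            f1 = _markov_haplotypes(rng, n_pool, freqs[block], cfg.ld_rho)
            f2 = _markov_haplotypes(rng, n_pool, freqs[block], cfg.ld_rho)
            for s_of, d_of in pool_parents:
                f1, f2 = (
                    _meiosis(rng, f1[s_of], f2[s_of], cfg.crossovers_per_chrom),
                    _meiosis(rng, f1[d_of], f2[d_of], cfg.crossovers_per_chrom),
                )
            gam_s = _meiosis(rng, f1[sire_of], f2[sire_of], cfg.crossovers_per_chrom)
            gam_d = _meiosis(rng, f1[dam_of], f2[dam_of], cfg.crossovers_per_chrom)
            dosage[:, block] = gam_s + gam_d
        else:
            h1 = _markov_haplotypes(rng, n, freqs[block], cfg.ld_rho)
            h2 = _markov_haplotypes(rng, n, freqs[block], cfg.ld_rho)
            dosage[:, block] = h1 + h2
        chrom[block] = c + 1
        pos[block] = np.arange(1, mc + 1) * 1000  # 1 kb spacing
        start += mc
    ids = np.array([f"ind{i:04d}" for i in range(1, n + 1)], dtype=object)
    mids = np.array([f"snp{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    return GenotypeMatrix(dosages=dosage, individual_ids=ids, marker_ids=mids, chrom=chrom, pos=pos)


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig) -> tuple[PhenotypeTable, TrueValues]:
    """Three-age phenotypes y = mean + sex + batch + u + e on given genotypes.

    Breeding values come from ``cfg.n_qtl`` pleiotropic QTL whose 3-vector
    effects are drawn N(0, genetic_corr); u and e are rescaled per age so
    that realized var(u)/(var(u)+var(e)) equals ``cfg.h2`` exactly and the
    phenotypic variance (after fixed effects) is 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7_919)))
    n = g.n_individuals
    if cfg.n_qtl > g.n_markers:
        raise ValueError("n_qtl exceeds available markers")
    qtl_idx = np.sort(rng.choice(g.n_markers, size=cfg.n_qtl, replace=False))
    L = np.linalg.cholesky(cfg.genetic_corr)
    beta = rng.standard_normal((cfg.n_qtl, 3)) @ L.T
    Wq = g.dosages[:, qtl_idx] - 2.0 * g.allele_freq[qtl_idx]
    Wq = np.where(np.isnan(Wq), 0.0, Wq)
    u = Wq @ beta
    u -= u.mean(axis=0)
    if cfg.residual_corr is not None:
        Le = np.linalg.cholesky(cfg.residual_corr)
        e = rng.standard_normal((n, 3)) @ Le.T
    else:
        e = rng.standard_normal((n, 3))
    e -= e.mean(axis=0)
    h2 = np.asarray(cfg.h2)
    su = u.std(axis=0, ddof=1)
    se = e.std(axis=0, ddof=1)
    u_scale = np.sqrt(h2) / su
    e_scale = np.sqrt(1.0 - h2) / se
    u = u * u_scale
    e = e * e_scale
    beta_scaled = beta * u_scale

    n_male = int(round(cfg.male_fraction * n))
    sex = np.array(["F"] * n, dtype=object)
    sex[rng.permutation(n)[:n_male]] = "M"
    batch = np.array([f"b{i % cfg.n_batches + 1}" for i in range(n)], dtype=object)
    batch_eff = dict(zip(sorted(set(batch)), cfg.batch_effects))
    fixed = (sex == "M") * cfg.sex_effect + np.array([batch_eff[b] for b in batch])
    y = fixed[:, None] + u + e

    cols = [f"{cfg.trait}_{t}" for t in cfg.time_labels]
    values = pd.DataFrame(y, index=pd.Index(g.individual_ids, name="id"), columns=cols)
    pheno = PhenotypeTable(
        individual_ids=g.individual_ids,
        sex=sex,
        batch=batch,
        values=values,
        time_labels=cfg.time_labels,
    )
    realized = u.var(axis=0, ddof=1) / (u.var(axis=0, ddof=1) + e.var(axis=0, ddof=1))
    truth = TrueValues(
        true_breeding_values=u,
        qtl_ids=g.marker_ids[qtl_idx],
        qtl_effects=beta_scaled,
        realized_h2=realized,
    )
    return pheno, truth


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, TrueValues]:
    """Convenience wrapper: genotypes then phenotypes under one config."""
    g = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(g, cfg)
    return g, pheno, truth


def mask_records(pheno: PhenotypeTable, ids, columns) -> PhenotypeTable:
    """Copy of ``pheno`` with the given (individual, column) records set missing.

    Never touches any other cell — the masking used by the cross-validation
    leave-out strategies.
    """
    values = pheno.values.copy()
    values.loc[list(ids), list(columns)] = np.nan
    return PhenotypeTable(
        individual_ids=pheno.individual_ids,
        sex=pheno.sex,
        batch=pheno.batch,
        values=values,
        time_labels=pheno.time_labels,
    )
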