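"""Genotype / phenotype I/O, marker quality control and marker subsampling.

Genotypes are kept as allele *dosages* — real numbers in [0, 2] counting
copies of the alternate allele — because the data this toolkit targets come
from low-coverage sequencing followed by imputation, where the natural
genotype representation is a posterior mean dosage rather than a hard call.
Missing entries are NaN and are kept distinct from 0 until they are
explicitly mean-imputed (which :func:`woolgs.grm.vanraden_grm` does just
before building a relationship matrix, never before QC).

Supported on-disk formats: PLINK bed/bim/fam (SNP-major), VCF (DS field
preferred, GT fallback) and a plain "matrix-csv" dialect (header row of
marker ids, first column the individual id).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "QCThresholds",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "qc_filter",
    "hwe_exact_test",
    "subsample_markers",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed in the named dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violate a structural invariant."""


def _compute_allele_freq(dosages: np.ndarray) -> np.ndarray:
    """In-sample alternate-allele frequency per marker, ignoring missing."""
    n_obs = np.sum(~np.isnan(dosages), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(dosages, axis=0) / (2.0 * n_obs)
    return np.where(n_obs > 0, freq, np.nan)


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with marker metadata.

    ``allele_freq`` is always the in-sample alternate-allele frequency of the
    current matrix; it is recomputed on construction, so any slicing helper
    that returns a new :class:`GenotypeMatrix` automatically refreshes it.
    """

    dosages: np.ndarray
    individual_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        n, m = self.dosages.shape if self.dosages.ndim == 2 else (0, 0)
        if self.dosages.ndim != 2 or n == 0 or m == 0:
            raise ValidationError("genotype matrix must be non-empty and 2-D")
        if len(self.individual_ids) != n:
            raise ValidationError("individual_ids length does not match matrix")
        if not (len(self.marker_ids) == len(self.chrom) == len(self.pos) == m):
            raise ValidationError("marker metadata length does not match matrix")
        for name, ids in (("individual", self.individual_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicated {name} ids")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosages must lie in [0, 2]")
        self.allele_freq = _compute_allele_freq(self.dosages)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given marker indices (order kept)."""
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            individual_ids=self.individual_ids,
            marker_ids=self.marker_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
        )


@dataclass
class PhenotypeTable:
    """Per-individual sex, batch and trait values at several ages.

    ``values`` is a DataFrame indexed by individual id whose columns are
    ``f"{trait}_{time}"`` (e.g. ``WSW_140``); NaN marks a missing record.
    """

    individual_ids: np.ndarray
    sex: np.ndarray
    batch: np.ndarray
    values: pd.DataFrame
    time_labels: tuple[int, ...] = (70, 140, 210)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("duplicated individual ids in phenotypes")
        n = len(self.individual_ids)
        if not (len(self.sex) == len(self.batch) == len(self.values) == n):
            raise ValidationError("phenotype component lengths disagree")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and not np.all(np.isfinite(vals[~np.isnan(vals)])):
            raise ValidationError("non-finite phenotype value")

    @property
    def traits(self) -> list[str]:
        seen: list[str] = []
        for col in self.values.columns:
            base = col.rsplit("_", 1)[0]
            if base not in seen:
                seen.append(base)
        return seen

    def trait_columns(self, trait: str) -> list[str]:
        return [f"{trait}_{t}" for t in self.time_labels]

    def trait_matrix(self, trait: str) -> np.ndarray:
        """n x n_times array for one trait, NaN where missing."""
        return self.values[self.trait_columns(trait)].to_numpy(dtype=float)


@dataclass
class QCThresholds:
    """Marker filters: strict inequalities, matching common PLINK usage."""

    maf_min: float = 0.05
    missing_rate_max: float = 0.10
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_rate_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from ``plink-bed``, ``vcf`` or ``matrix-csv``.

    When ``format`` is omitted it is inferred from the file suffix
    (``.bed`` / ``.vcf`` / anything else -> matrix-csv).
    """
    path = Path(path)
    if format is None:
        format = {".bed": "plink-bed", ".vcf": "vcf"}.get(path.suffix, "matrix-csv")
    if format == "matrix-csv":
        return _read_matrix_csv(path)
    if format == "plink-bed":
        return _read_plink_bed(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".bed": "plink-bed", ".vcf": "vcf"}.get(path.suffix, "matrix-csv")
    if format == "matrix-csv":
        _write_matrix_csv(g, path)
    elif format == "plink-bed":
        _write_plink_bed(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_matrix_csv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no marker columns")
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        individual_ids=df.index.astype(str).to_numpy(),
        marker_ids=df.columns.astype(str).to_numpy(),
        chrom=np.ones(df.shape[1], dtype=int),
        pos=np.arange(1, df.shape[1] + 1),
    )


def _write_matrix_csv(g: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(g.dosages, index=g.individual_ids, columns=g.marker_ids)
    df.index.name = "id"
    df.to_csv(path)


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major


def _read_plink_bed(path: Path) -> GenotypeMatrix:
    stem = path.with_suffix("")
    fam = pd.read_csv(stem.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(stem.with_suffix(".bim"), sep=r"\s+", header=None)
    ids = fam[1].astype(str).to_numpy()
    n, m = len(fam), len(bim)
    raw = path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeParseError(f"{path}: bad bed magic bytes (not SNP-major bed)")
    bytes_per_marker = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_marker * m:
        raise GenotypeParseError(f"{path}: bed payload size mismatch")
    codes = np.unpackbits(body.reshape(m, bytes_per_marker)[:, :, None], axis=2, bitorder="little")
    codes = codes.reshape(m, -1)[:, : 2 * n].reshape(m, n, 2)
    two_bit = codes[:, :, 0] + 2 * codes[:, :, 1]
    # 00 -> 2 copies of A1 (dosage of A2 = 0 if A1 is alt? PLINK counts A1);
    # here A1 is taken as the alternate allele so 00 = dosage 2, 11 = 0.
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dos = lut[two_bit].T  # n x m
    return GenotypeMatrix(
        dosages=dos,
        individual_ids=ids,
        marker_ids=bim[1].astype(str).to_numpy(),
        chrom=bim[0].to_numpy(),
        pos=bim[3].to_numpy(),
    )


def _write_plink_bed(g: GenotypeMatrix, path: Path) -> None:
    """Hard calls only: dosages are rounded to {0,1,2}; NaN stays missing."""
    stem = path.with_suffix("")
    n, m = g.dosages.shape
    fam = pd.DataFrame({0: g.individual_ids, 1: g.individual_ids, 2: 0, 3: 0, 4: 0, 5: -9})
    fam.to_csv(stem.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {0: g.chrom, 1: g.marker_ids, 2: 0.0, 3: g.pos, 4: "A", 5: "G"}
    )
    bim.to_csv(stem.with_suffix(".bim"), sep="\t", header=False, index=False)
    hard = np.round(g.dosages)
    code = np.full((m, n), 1, dtype=np.uint8)  # 01 = missing
    hardT = hard.T
    code[hardT == 2] = 0
    code[hardT == 1] = 2
    code[hardT == 0] = 3
    bits = np.zeros((m, ((n + 3) // 4) * 4, 2), dtype=np.uint8)
    bits[:, :n, 0] = code & 1
    bits[:, :n, 1] = code >> 1
    packed = np.packbits(bits.reshape(m, -1, 8), axis=-1, bitorder="little")
    with open(path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.asarray(vcf.samples, dtype=object)
    marker_ids, chroms, poss, cols = [], [], [], []
    for i, var in enumerate(vcf):
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            col = np.choose(gt.astype(int), [0.0, 1.0, np.nan, 2.0])
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        cols.append(col)
    if not cols:
        raise ValidationError(f"{path}: VCF contains no variant records")
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        individual_ids=ids,
        marker_ids=np.asarray(marker_ids, dtype=object),
        chrom=np.asarray(chroms),
        pos=np.asarray(poss, dtype=int),
    )


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    """Plain-text VCF with GT (rounded) and DS (the dosage itself)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(pd.Series(g.chrom).astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.individual_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for k in range(g.n_markers):
            fields = [str(g.chrom[k]), str(g.pos[k]), str(g.marker_ids[k]), "G", "A", ".", "PASS", ".", "GT:DS"]
            for d in g.dosages[:, k]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[int(round(d))]}:{d:.6g}")
            fh.write("\t".join(fields) + "\n")


def read_phenotypes(path: str | Path, time_labels: tuple[int, ...] = (70, 140, 210)) -> PhenotypeTable:
    """CSV with columns ``id, sex, batch`` then ``trait_time`` columns."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "batch": str})
    for col in ("id", "sex", "batch"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    value_cols = [c for c in df.columns if c not in ("id", "sex", "batch")]
    values = df[value_cols].astype(float)
    values.index = pd.Index(df["id"], name="id")
    return PhenotypeTable(
        individual_ids=df["id"].to_numpy(),
        sex=df["sex"].to_numpy(),
        batch=df["batch"].to_numpy(),
        values=values,
        time_labels=time_labels,
    )


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    out = pd.DataFrame({"id": p.individual_ids, "sex": p.sex, "batch": p.batch})
    out = pd.concat([out.reset_index(drop=True), p.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts that are no more probable than the observed one
    (the standard exact test of Wigginton, Cutler & Abecasis).  Returns a
    p-value in (0, 1].
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_A = 2 * n_AA + n_Aa
    # possible heterozygote counts share the parity of n_A
    h_max = min(n_A, 2 * n - n_A)
    hs = np.arange(h_max % 2, h_max + 1, 2)
    # log P(h) up to a constant: n! 2^h / (nAA! h! naa!)
    logp = hs * np.log(2.0) - gammaln((n_A - hs) / 2 + 1) - gammaln(hs + 1) - gammaln((2 * n - n_A - hs) / 2 + 1)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix | None, pd.DataFrame]:
    """Apply MAF, missing-rate and HWE filters; return (filtered, report).

    All comparisons are strict: a marker is kept iff MAF > ``maf_min``,
    missing fraction < ``missing_rate_max`` and exact HWE p > ``hwe_p_min``.
    The HWE test needs hard genotype calls, so dosages are rounded to the
    nearest integer for that test only.  If every marker fails, the filtered
    matrix is returned as None alongside the full report.
    """
    t = thresholds or QCThresholds()
    n = g.n_individuals
    miss = np.isnan(g.dosages).sum(axis=0) / n
    maf = np.minimum(g.allele_freq, 1.0 - g.allele_freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    hard = np.round(g.dosages)
    hwe_p = np.empty(g.n_markers)
    for k in range(g.n_markers):
        col = hard[:, k]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[k] = 0.0
            continue
        hwe_p[k] = hwe_exact_test(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
    pass_maf = maf > t.maf_min
    pass_miss = miss < t.missing_rate_max
    pass_hwe = hwe_p > t.hwe_p_min
    keep = pass_maf & pass_miss & pass_hwe
    fail_reason = np.where(
        ~pass_maf, "maf", np.where(~pass_miss, "missing_rate", np.where(~pass_hwe, "hwe", ""))
    )
    report = pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "maf": maf,
            "missing_rate": miss,
            "hwe_p": hwe_p,
            "passed": keep,
            "fail_reason": fail_reason,
        }
    )
    if not keep.any():
        import warnings

        warnings.warn("QC removed every marker", stacklevel=2)
        return None, report
    return g.take_markers(np.flatnonzero(keep)), report


def subsample_markers(g: GenotypeMatrix, k: int, seed: int) -> GenotypeMatrix:
    """Uniform without-replacement marker subsample, source order preserved."""
    if not 1 <= k <= g.n_markers:
        raise ValueError(f"k={k} outside [1, {g.n_markers}]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(g.n_markers, size=k, replace=False))
    return g.take_markers(idx)
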