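"""SNP quality control and the genomic relationship matrix.

Genotypes are stored as counts of one allele in {0, 1, 2} with NaN for
missing calls. QC removes unmapped/non-autosomal markers, then markers
failing call-rate, Hardy-Weinberg and minor-allele-frequency filters, then
samples with poor call rates. The genomic relationship matrix follows the
VanRaden form G = WW' / 2*sum(p(1-p)) with W the frequency-centred
genotypes; frequencies are always recomputed from the genotyped population
at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "Grm",
    "QcReport",
    "snp_qc",
    "allele_frequencies",
    "hwe_chi2_pvalues",
    "build_grm",
    "read_raw",
    "read_ped",
    "read_tsv_genotypes",
]

_AUTOSOME_MAX = 29  # Bos taurus


@dataclass
class GenotypeMatrix:
    """Animals x SNPs genotype matrix with a marker map."""

    animal_ids: pd.Index
    snp_ids: pd.Index
    chromosome: np.ndarray
    position: np.ndarray
    values: np.ndarray  # float, {0,1,2,nan}

    def __post_init__(self) -> None:
        self.animal_ids = pd.Index(self.animal_ids)
        self.snp_ids = pd.Index(self.snp_ids)
        self.chromosome = np.asarray(self.chromosome)
        self.position = np.asarray(self.position)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.animal_ids) != n or len(self.snp_ids) != m:
            raise ValueError("ID lengths do not match matrix dimensions")
        if len(self.chromosome) != m or len(self.position) != m:
            raise ValueError("map length does not match number of SNPs")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotypes must be in {0, 1, 2} or missing")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def is_autosomal(self) -> np.ndarray:
        out = np.zeros(self.n_snps, dtype=bool)
        for i, (c, pos) in enumerate(zip(self.chromosome, self.position)):
            try:
                ci = int(c)
            except (TypeError, ValueError):
                continue
            out[i] = 1 <= ci <= _AUTOSOME_MAX and pos > 0
        return out

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = np.ones(self.n_animals, bool) if animal_mask is None else np.asarray(animal_mask)
        sm = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(
            self.animal_ids[am], self.snp_ids[sm],
            self.chromosome[sm], self.position[sm],
            self.values[np.ix_(am, sm)],
        )

    def write_raw(self, path) -> None:
        """PLINK .raw-style TSV: FID, IID then one 0/1/2 column per SNP."""
        df = pd.DataFrame(self.values, columns=self.snp_ids)
        df.insert(0, "IID", self.animal_ids)
        df.insert(0, "FID", self.animal_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    def write_map(self, path) -> None:
        pd.DataFrame(
            {"chromosome": self.chromosome, "snp": self.snp_ids,
             "cm": 0, "position": self.position}
        ).to_csv(path, sep="\t", index=False, header=False)


@dataclass
class QcReport:
    n_snps_in: int = 0
    n_non_autosomal: int = 0
    n_fail_call_rate: int = 0
    n_fail_hwe: int = 0
    n_fail_maf: int = 0
    n_snps_out: int = 0
    n_animals_in: int = 0
    n_fail_sample_call_rate: int = 0
    n_animals_out: int = 0


@dataclass
class Grm:
    """VanRaden genomic relationship matrix."""

    animal_ids: pd.Index
    matrix: np.ndarray
    denominator: float

    def __post_init__(self) -> None:
        self.animal_ids = pd.Index(self.animal_ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if self.denominator <= 0:
            raise ValueError("GRM denominator must be positive")
        self._eig_cache: dict = {}

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def stabilized(self, blend: float = 0.01) -> np.ndarray:
        """Blend toward the identity, G* = (1-blend) G + blend I, for inversion/MCMC."""
        return (1.0 - blend) * self.matrix + blend * np.eye(self.n)

    def eigendecomposition(self, blend: float = 0.01):
        """Cached eigendecomposition of the stabilized matrix (d, U)."""
        key = round(blend, 12)
        if key not in self._eig_cache:
            d, u = np.linalg.eigh(self.stabilized(blend))
            self._eig_cache[key] = (np.clip(d, 1e-12, None), u)
        return self._eig_cache[key]

    def subset(self, ids) -> "Grm":
        idx = self.animal_ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            missing = pd.Index(ids)[idx < 0]
            raise KeyError(f"animals not in GRM: {list(missing)}")
        return Grm(pd.Index(ids), self.matrix[np.ix_(idx, idx)], self.denominator)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.animal_ids, columns=self.animal_ids).to_csv(
            path, sep="\t"
        )


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker allele frequency p_n = mean(genotype)/2 over non-missing calls."""
    n_called = np.isfinite(g.values).sum(axis=0)
    if (n_called == 0).any():
        bad = g.snp_ids[n_called == 0]
        raise ValueError(f"SNP(s) with no non-missing calls: {list(bad)}")
    return np.nanmean(g.values, axis=0) / 2.0


def hwe_chi2_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """One-df chi-square test of Hardy-Weinberg proportions per SNP.

    Observed genotype counts are compared with expectations at the observed
    allele frequency; no continuity correction. Monomorphic SNPs get p = 1
    (they trivially fit HW and are removed by the MAF filter instead).
    """
    vals = g.values
    called = np.isfinite(vals)
    n = called.sum(axis=0).astype(float)
    n0 = ((vals == 0) & called).sum(axis=0)
    n1 = ((vals == 1) & called).sum(axis=0)
    n2 = ((vals == 2) & called).sum(axis=0)
    p = (2 * n2 + n1) / (2 * np.maximum(n, 1))
    q = 1 - p
    exp0, exp1, exp2 = n * q**2, n * 2 * p * q, n * p**2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (
            (n0 - exp0) ** 2 / exp0
            + (n1 - exp1) ** 2 / exp1
            + (n2 - exp2) ** 2 / exp2
        )
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[~np.isfinite(chi2)] = 1.0
    return pvals


def snp_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-4,
    maf_min: float = 0.05,
    sample_call_rate_min: float = 0.90,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs (map, call rate, HWE, MAF) then samples (call rate)."""
    for name, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min),
                    ("sample_call_rate_min", sample_call_rate_min)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    report = QcReport(n_snps_in=g.n_snps, n_animals_in=g.n_animals)

    keep = g.is_autosomal()
    report.n_non_autosomal = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    called = np.isfinite(g.values)
    call_rate = called.mean(axis=0)
    cr_ok = call_rate >= call_rate_min
    report.n_fail_call_rate = int((~cr_ok).sum())
    g = g.subset(snp_mask=cr_ok)

    hwe_ok = hwe_chi2_pvalues(g) >= hwe_p_min
    report.n_fail_hwe = int((~hwe_ok).sum())
    g = g.subset(snp_mask=hwe_ok)

    p = allele_frequencies(g)
    maf = np.minimum(p, 1 - p)
    maf_ok = maf >= maf_min
    report.n_fail_maf = int((~maf_ok).sum())
    g = g.subset(snp_mask=maf_ok)
    report.n_snps_out = g.n_snps
    if g.n_snps == 0:
        raise ValueError("no SNPs survive QC")

    sample_cr = np.isfinite(g.values).mean(axis=1)
    s_ok = sample_cr >= sample_call_rate_min
    report.n_fail_sample_call_rate = int((~s_ok).sum())
    g = g.subset(animal_mask=s_ok)
    report.n_animals_out = g.n_animals
    if g.n_animals == 0:
        raise ValueError("no animals survive QC")
    return g, report


def build_grm(g: GenotypeMatrix) -> Grm:
    """VanRaden GRM: G = WW' / 2*sum(p(1-p)), W = genotypes - 2p, mean-imputed."""
    p = allele_frequencies(g)
    den = float(2.0 * np.sum(p * (1 - p)))
    if den <= 0:
        raise ValueError("all SNPs monomorphic; GRM denominator is zero")
    w = g.values - 2 * p
    w = np.where(np.isfinite(w), w, 0.0)  # missing -> 2p (centred to 0)
    grm = w @ w.T / den
    grm = 0.5 * (grm + grm.T)
    return Grm(g.animal_ids, grm, den)


def read_raw(path) -> GenotypeMatrix:
    """Read a PLINK .raw-style table (FID/IID [+PAT/MAT/SEX/PHENOTYPE] + SNP columns)."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    snps = [c for c in df.columns if c not in meta]
    ids = df["IID"].astype(str) if "IID" in df.columns else df.iloc[:, 0].astype(str)
    values = df[snps].to_numpy(dtype=float)
    m = len(snps)
    return GenotypeMatrix(
        pd.Index(ids), pd.Index(snps),
        np.array([(i % _AUTOSOME_MAX) + 1 for i in range(m)]),
        np.arange(1, m + 1), values,
    )


def read_ped(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK .ped/.map (allele pairs recoded to minor-allele counts).

    Missing calls are '0' alleles. The count allele at each marker is the
    minor allele observed in the file.
    """
    m = pd.read_csv(map_path, sep=r"\s+", header=None,
                    names=["chromosome", "snp", "cm", "position"])
    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    ids = ped.iloc[:, 1]
    alleles = ped.iloc[:, 6:].to_numpy()
    n, n_cols = alleles.shape
    if n_cols != 2 * len(m):
        raise ValueError(".ped allele columns do not match the .map marker count")
    values = np.full((n, len(m)), np.nan)
    for j in range(len(m)):
        a1 = alleles[:, 2 * j]
        a2 = alleles[:, 2 * j + 1]
        called = (a1 != "0") & (a2 != "0")
        obs = np.concatenate([a1[called], a2[called]])
        if obs.size == 0:
            continue
        uniq, counts = np.unique(obs, return_counts=True)
        minor = uniq[np.argmin(counts)] if len(uniq) > 1 else uniq[0]
        values[called, j] = (a1[called] == minor).astype(float) + (
            a2[called] == minor
        ).astype(float)
    return GenotypeMatrix(pd.Index(ids.astype(str)), pd.Index(m["snp"].astype(str)),
                          m["chromosome"].to_numpy(), m["position"].to_numpy(), values)


def read_tsv_genotypes(genotype_path, map_path=None) -> GenotypeMatrix:
    """Plain TSV dialect: first column animal ID, remaining columns SNP dosages.

    An optional map TSV (columns: chromosome, snp, cm, position — headerless,
    PLINK .map layout) attaches marker coordinates; otherwise SNPs are placed
    on autosomes cyclically.
    """
    df = pd.read_csv(genotype_path, sep="\t", index_col=0)
    snps = pd.Index(df.columns)
    if map_path is not None:
        m = pd.read_csv(map_path, sep="\t", header=None,
                        names=["chromosome", "snp", "cm", "position"])
        m = m.set_index("snp").reindex(snps)
        chrom = m["chromosome"].to_numpy()
        pos = m["position"].fillna(0).to_numpy()
    else:
        chrom = np.array([(i % _AUTOSOME_MAX) + 1 for i in range(len(snps))])
        pos = np.arange(1, len(snps) + 1)
    return GenotypeMatrix(pd.Index(df.index.astype(str)), snps, chrom, pos,
                          df.to_numpy(dtype=float))
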