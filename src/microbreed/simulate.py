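"""Synthetic herds with known genetic architecture and microbiome compositions.

The generator emulates the study conditions of a host-genomic analysis of
rumen microbiome traits and methane (CH4, g/kg dry-matter intake): SNP
genotypes in Hardy-Weinberg proportions with MAF >= 0.05, a cross-classified
experiment x breed x diet fixed-effect design, multi-trait breeding values
drawn from GRM (x) G0 with user-specified heritabilities and host-genomic
correlations, and logistic-normal-multinomial microbiome count tables with
per-sample sequencing-depth variation and (for coverage-based uncultured
genome features) zero inflation.

Trait 1 is always CH4. Defaults mirror the study scale: 359 animals,
h2_CH4 = 0.33 with genomic variance 3.9 (g/kg DMI)^2, a second microbial
trait with h2 = 0.33 and host-genomic correlation -0.8 with CH4, five
experiments, four breeds, two diets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compositional import AbundanceTable
from .genomics import GenotypeMatrix, Grm, build_grm

__all__ = ["SimConfig", "GroundTruth", "TraitDesign", "simulate_genotypes",
           "simulate_traits", "simulate_microbiome_counts", "default_covariances",
           "covariances_from_h2_rg", "write_simulation"]


def covariances_from_h2_rg(
    h2: np.ndarray, rg: np.ndarray, phenotypic_var: np.ndarray | None = None,
    re_corr: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (G0, R0) from per-trait heritabilities and a genetic correlation matrix.

    Residual correlations default to zero; phenotypic variances default to 1.
    """
    h2 = np.asarray(h2, dtype=float)
    rg = np.asarray(rg, dtype=float)
    t = len(h2)
    if phenotypic_var is None:
        phenotypic_var = np.ones(t)
    sg = np.sqrt(h2 * phenotypic_var)
    se = np.sqrt((1 - h2) * phenotypic_var)
    g0 = rg * np.outer(sg, sg)
    if re_corr is None:
        re_corr = np.eye(t)
    r0 = np.asarray(re_corr, dtype=float) * np.outer(se, se)
    return g0, r0


def default_covariances() -> tuple[np.ndarray, np.ndarray]:
    """CH4 (h2 = 0.33, var_g = 3.9 (g/kg DMI)^2) plus one microbial trait (h2 = 0.33,
    r_g = -0.8, unit phenotypic variance on the log-ratio scale)."""
    return covariances_from_h2_rg(
        h2=np.array([0.33, 0.33]),
        rg=np.array([[1.0, -0.8], [-0.8, 1.0]]),
        phenotypic_var=np.array([3.9 / 0.33, 1.0]),
    )


@dataclass
class SimConfig:
    n_animals: int = 359
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 2
    G0_true: np.ndarray | None = None
    R0_true: np.ndarray | None = None
    # cross-classified design: {factor: (n_levels, effect scale per trait)}
    n_experiments: int = 5
    n_breeds: int = 4
    n_diets: int = 2
    fixed_effect_scale: float = 1.0
    trait_means: np.ndarray | None = None  # CH4 mean 19.7 g/kg DMI by default
    depth_range: tuple[float, float] = (1e5, 1e6)
    zero_inflation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")
        if self.G0_true is None or self.R0_true is None:
            if self.n_traits == 2:
                g0, r0 = default_covariances()
            else:
                g0, r0 = covariances_from_h2_rg(
                    np.full(self.n_traits, 0.33), np.eye(self.n_traits)
                )
            self.G0_true = g0 if self.G0_true is None else self.G0_true
            self.R0_true = r0 if self.R0_true is None else self.R0_true
        self.G0_true = np.asarray(self.G0_true, dtype=float)
        self.R0_true = np.asarray(self.R0_true, dtype=float)
        for name, m in (("G0_true", self.G0_true), ("R0_true", self.R0_true)):
            if m.shape != (self.n_traits, self.n_traits):
                raise ValueError(f"{name} must be {self.n_traits}x{self.n_traits}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
        if self.trait_means is None:
            means = np.zeros(self.n_traits)
            means[0] = 19.7  # g CH4 / kg DMI
            self.trait_means = means
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        d_lo, d_hi = self.depth_range
        if d_lo <= 0 or d_hi < d_lo:
            raise ValueError("depth_range must be positive and ordered")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")

    @property
    def h2_true(self) -> np.ndarray:
        dg = np.diag(self.G0_true)
        return dg / (dg + np.diag(self.R0_true))

    @property
    def rg_true(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.G0_true))
        with np.errstate(divide="ignore", invalid="ignore"):
            rg = self.G0_true / np.outer(sd, sd)
        np.fill_diagonal(rg, 1.0)
        return rg


@dataclass
class GroundTruth:
    breeding_values: pd.DataFrame  # animals x traits
    fixed_effects: pd.DataFrame    # combined level x traits
    h2_true: np.ndarray
    rg_true: np.ndarray

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("[h2_true]\n")
            for j, v in enumerate(self.h2_true):
                fh.write(f"trait_{j}\t{v:.6f}\n")
            fh.write("[rg_true]\n")
            t = len(self.h2_true)
            for a in range(t):
                for b in range(a + 1, t):
                    fh.write(f"trait_{a}:trait_{b}\t{self.rg_true[a, b]:.6f}\n")


@dataclass
class TraitDesign:
    """Phenotypes plus the combined experiment x breed x diet fixed factor."""

    phenotypes: pd.DataFrame   # animals x traits, NaN allowed
    fixed_factor: pd.Series    # combined level per animal
    design: pd.DataFrame       # experiment / breed / diet columns

    @property
    def animal_ids(self) -> pd.Index:
        return self.phenotypes.index

    def design_matrix(self) -> np.ndarray:
        """Full-rank dummy design for the combined factor (first level as reference,
        plus intercept)."""
        return design_matrix_from_factor(self.fixed_factor)


def design_matrix_from_factor(factor: pd.Series) -> np.ndarray:
    """Intercept + treatment-coded dummies; levels with < 2 records are merged
    into the reference level."""
    counts = factor.value_counts()
    rare = counts[counts < 2].index
    f = factor.where(~factor.isin(rare), other="__merged__")
    levels = sorted(f.unique())
    x = np.ones((len(f), len(levels)))
    for k, lev in enumerate(levels[1:], start=1):
        x[:, k] = (f == lev).to_numpy(dtype=float)
    return x


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Independent SNPs in Hardy-Weinberg proportions, frequencies ~ U(maf_range)."""
    if config.n_animals < 2 or config.n_snps < 1:
        raise ValueError("need n_animals >= 2 and n_snps >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p = rng.uniform(*config.maf_range, size=config.n_snps)
    geno = rng.binomial(2, p, size=(config.n_animals, config.n_snps)).astype(float)
    chrom = (np.arange(config.n_snps) % 29) + 1
    pos = np.arange(config.n_snps) // 29 + 1
    ids = pd.Index([f"animal_{i:04d}" for i in range(config.n_animals)])
    snps = pd.Index([f"snp_{i:05d}" for i in range(config.n_snps)])
    return GenotypeMatrix(ids, snps, chrom, pos * 1000, geno)


def _psd_factor(matrix: np.ndarray) -> np.ndarray:
    """Factor L with L L' = matrix, tolerant of tiny negative eigenvalues."""
    d, u = np.linalg.eigh(matrix)
    return u * np.sqrt(np.clip(d, 0.0, None))


def simulate_traits(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    grm: Grm | None = None,
) -> tuple[TraitDesign, GroundTruth]:
    """Draw breeding values g ~ N(0, GRM (x) G0), residuals e ~ N(0, I (x) R0),
    assign the cross-classified design and return y = mean + Xb + g + e."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n, t = genotypes.n_animals, config.n_traits
    grm = build_grm(genotypes) if grm is None else grm

    lg = _psd_factor(grm.matrix)
    lg0 = _psd_factor(config.G0_true)
    g = lg @ rng.standard_normal((n, t)) @ lg0.T
    e = rng.standard_normal((n, t)) @ _psd_factor(config.R0_true).T

    exp_lab = rng.integers(config.n_experiments, size=n)
    breed = rng.integers(config.n_breeds, size=n)
    diet = rng.integers(config.n_diets, size=n)
    design = pd.DataFrame(
        {"experiment": [f"E{v}" for v in exp_lab],
         "breed": [f"B{v}" for v in breed],
         "diet": [f"D{v}" for v in diet]},
        index=genotypes.animal_ids,
    )
    combined = design["experiment"] + ":" + design["breed"] + ":" + design["diet"]
    combined.name = "fixed_level"

    levels = sorted(combined.unique())
    sd_p = np.sqrt(np.diag(config.G0_true) + np.diag(config.R0_true))
    effects = rng.standard_normal((len(levels), t)) * config.fixed_effect_scale * sd_p
    eff_df = pd.DataFrame(effects, index=pd.Index(levels, name="fixed_level"),
                          columns=[f"trait_{j}" for j in range(t)])
    xb = eff_df.loc[combined].to_numpy()

    y = config.trait_means + xb + g + e
    pheno = pd.DataFrame(y, index=genotypes.animal_ids,
                         columns=[f"trait_{j}" for j in range(t)])
    pheno = pheno.rename(columns={"trait_0": "CH4"})
    bv = pd.DataFrame(g, index=genotypes.animal_ids, columns=pheno.columns)
    truth = GroundTruth(bv, eff_df, config.h2_true, config.rg_true)
    return TraitDesign(pheno, combined, design), truth


def simulate_microbiome_counts(
    latent_alr: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    mode: str = "genus",
    sample_ids=None,
    feature_ids=None,
) -> AbundanceTable:
    """Logistic-normal-multinomial counts from latent ALR coordinates.

    Per sample the J proportions are the inverse-ALR of the latent row (the
    reference part is appended last); a sequencing depth is drawn log-uniform
    from ``depth_range``; counts are multinomial at that depth. In ``rug``
    mode the table is returned as continuous coverages with entries below 1x
    zeroed and independent Bernoulli(zero_inflation) dropout applied.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    latent = np.asarray(latent_alr, dtype=float)
    if latent.ndim != 2 or not np.all(np.isfinite(latent)):
        raise ValueError("latent_alr must be a finite 2-D array")
    if mode not in ("genus", "gene", "rug"):
        raise ValueError("mode must be 'genus', 'gene' or 'rug'")
    n, jm1 = latent.shape
    expo = np.exp(np.column_stack([latent, np.zeros(n)]))
    props = expo / expo.sum(axis=1, keepdims=True)

    lo, hi = config.depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if sample_ids is None:
        sample_ids = [f"animal_{i:04d}" for i in range(n)]
    if feature_ids is None:
        feature_ids = [f"feature_{j:04d}" for j in range(jm1)] + ["reference"]

    if mode == "rug":
        cov = props * depths[:, None]
        cov[cov < 1.0] = 0.0
        drop = rng.random(cov.shape) < config.zero_inflation
        cov[drop] = 0.0
        data = cov
        fclass = "RUG"
    else:
        depths_int = np.round(depths).astype(np.int64)
        data = np.empty((n, jm1 + 1), dtype=np.int64)
        for i in range(n):
            data[i] = rng.multinomial(depths_int[i], props[i])
        fclass = "genus" if mode == "genus" else "gene"
    df = pd.DataFrame(data, index=pd.Index(sample_ids), columns=pd.Index(feature_ids))
    return AbundanceTable(df.astype(float), fclass)


def write_simulation(outdir, genotypes: GenotypeMatrix, traits: TraitDesign,
                     truth: GroundTruth, tables: dict[str, AbundanceTable] | None = None
                     ) -> None:
    """Write genotypes (.raw-style TSV + map), trait/design table, ground truth,
    and any abundance tables under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes.write_raw(out / "genotypes.raw.tsv")
    genotypes.write_map(out / "genotypes.map")
    full = traits.phenotypes.join(traits.design).join(traits.fixed_factor)
    full.to_csv(out / "traits.tsv", sep="\t")
    truth.write(out / "ground_truth.txt")
    truth.breeding_values.to_csv(out / "true_breeding_values.tsv", sep="\t")
    for name, table in (tables or {}).items():
        table.to_tsv(out / f"abundance_{name}.tsv")
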