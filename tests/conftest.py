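import numpy as np
import pandas as pd
import pytest

from microbreed.genomics import build_grm
from microbreed.simulate import SimConfig, covariances_from_h2_rg, simulate_genotypes, \
    simulate_traits


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_herd():
    """120 animals, 400 SNPs, CH4 (h2=0.4) + one microbial trait, r_g=-0.8."""
    g0, r0 = covariances_from_h2_rg([0.4, 0.4], np.array([[1, -0.8], [-0.8, 1]]))
    cfg = SimConfig(n_animals=120, n_snps=400, n_traits=2, G0_true=g0, R0_true=r0,
                    seed=42, fixed_effect_scale=0.5)
    master = np.random.default_rng(42)
    geno = simulate_genotypes(cfg, master)
    grm = build_grm(geno)
    traits, truth = simulate_traits(geno, cfg, master, grm=grm)
    return dict(config=cfg, genotypes=geno, grm=grm, traits=traits, truth=truth)


def simulate_univariate_herd(seed, n=500, m=1000, h2=0.33, phen_var=1.0,
                             fixed_effect_scale=0.3):
    """One replicate of the univariate study conditions; returns (y, factor, grm, h2)."""
    g0 = np.array([[h2 * phen_var]])
    r0 = np.array([[(1 - h2) * phen_var]])
    cfg = SimConfig(n_animals=n, n_snps=m, n_traits=1, G0_true=g0, R0_true=r0,
                    trait_means=np.array([0.0]), seed=seed,
                    fixed_effect_scale=fixed_effect_scale)
    rng_ = np.random.default_rng(seed)
    geno = simulate_genotypes(cfg, rng_)
    grm = build_grm(geno)
    traits, truth = simulate_traits(geno, cfg, rng_, grm=grm)
    return traits.phenotypes.iloc[:, 0], traits.fixed_factor, grm, truth


def simulate_bivariate_herd(seed, n=500, m=1000, h2=(0.3, 0.3), rg=-0.8):
    g0, r0 = covariances_from_h2_rg(list(h2), np.array([[1, rg], [rg, 1]]))
    cfg = SimConfig(n_animals=n, n_snps=m, n_traits=2, G0_true=g0, R0_true=r0,
                    trait_means=np.zeros(2), seed=seed, fixed_effect_scale=0.3)
    rng_ = np.random.default_rng(seed)
    geno = simulate_genotypes(cfg, rng_)
    grm = build_grm(geno)
    traits, truth = simulate_traits(geno, cfg, rng_, grm=grm)
    return traits.phenotypes, traits.fixed_factor, grm, truth
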