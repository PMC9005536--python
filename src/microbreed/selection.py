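"""Selection theory downstream of the genomic-parameter estimates.

Covers the correlated response of CH4 to selection on a microbial trait
(R = i * h * r_g * sigma_gCH4), assembly of the multi-trait (co)variance
matrix from pairwise bivariate fits with eigenvalue bending, the three
genomic-prediction scenarios (CH4 records only / microbial genes only with
CH4 treated as missing / both), Eq.-style per-animal accuracies, truncation
response-to-selection distributions, and the rule-based breeding-panel
filter.

Sign convention: the breeding goal is CH4 *reduction*, so truncation selects
the animals with the lowest CH4 GEBVs and responses are reported as positive
reductions (mean of all animals minus mean of the selected group); formatted
outputs also carry the signed g/kg DMI change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import McmcFit, ModelSpec, fit_multitrait, fit_univariate, genomic_accuracy, summarize
from .genomics import Grm

__all__ = [
    "selection_intensity", "correlated_response", "CovarianceEstimate",
    "assemble_covariance", "bend_matrix", "SelectionResult", "predict_scenarios",
    "accuracy", "response_to_selection", "select_breeding_panel",
]


def selection_intensity(p: float) -> float:
    """Selection intensity i = phi(z_p)/p for truncation of the best fraction p.

    Infinite-population formula: z_p is the upper-tail standard-normal
    truncation point. Selecting everyone (p = 1) gives 0.
    """
    if not 0 < p <= 1:
        raise ValueError("selected fraction must be in (0, 1]")
    if p == 1:
        return 0.0
    z = stats.norm.ppf(1 - p)
    return float(stats.norm.pdf(z) / p)


def correlated_response(
    i: float,
    h_samples: np.ndarray,
    rg_samples: np.ndarray,
    sigma_g_ch4: np.ndarray | float,
    ch4_mean: float | None = None,
) -> dict:
    """Posterior distribution of the correlated CH4 response to selection on trait j.

    Per draw, R = i * h_j * r_g * sigma_gCH4 with h_j the square root of the
    trait's heritability draw. Returns median, sd, P0, the draws, and the
    response as a percent of the CH4 mean when one is supplied.
    """
    h = np.asarray(h_samples, dtype=float)
    rg = np.asarray(rg_samples, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("h draws must lie in [0, 1]")
    if np.any(np.abs(rg) > 1 + 1e-9):
        raise ValueError("r_g draws must lie in [-1, 1]")
    sig = np.asarray(sigma_g_ch4, dtype=float)
    if h.shape != rg.shape or (sig.ndim and sig.shape != h.shape):
        raise ValueError("sample vectors must have matching lengths")
    r = i * h * rg * sig
    out = {
        "samples": r,
        "median": float(np.median(r)),
        "sd": float(r.std(ddof=1)) if r.size > 1 else 0.0,
        "p0": max(float((r > 0).mean()), float((r < 0).mean())),
    }
    if ch4_mean is not None:
        out["percent_of_mean"] = 100.0 * out["median"] / ch4_mean
    return out


@dataclass
class CovarianceEstimate:
    """Multi-trait G0/R0 assembled from pairwise bivariate posteriors."""

    trait_names: list
    G0: np.ndarray
    R0: np.ndarray
    bending_log: dict = field(default_factory=dict)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


def assemble_covariance(
    pairwise_fits: dict[tuple[str, str], McmcFit],
    trait_names: list[str],
    ch4_trait: str | None = None,
) -> CovarianceEstimate:
    """Assemble t x t G0/R0 from all t(t-1)/2 bivariate fits.

    Off-diagonals are the posterior medians of the pairwise covariances.
    Each trait's diagonal is the mean of its per-fit posterior-median
    variances; for the focal CH4 trait this is exactly the mean across all
    its bivariate models.
    """
    t = len(trait_names)
    ch4_trait = ch4_trait or trait_names[0]
    lut: dict[tuple[str, str], tuple[McmcFit, int, int]] = {}
    for (a, b), fit in pairwise_fits.items():
        lut[(a, b)] = (fit, 0, 1)
        lut[(b, a)] = (fit, 1, 0)
    missing = [
        (a, b)
        for i, a in enumerate(trait_names)
        for b in trait_names[i + 1:]
        if (a, b) not in lut
    ]
    if missing:
        raise ValueError(f"missing bivariate fit(s) for pair(s): {missing}")

    g0 = np.zeros((t, t))
    r0 = np.zeros((t, t))
    diag_g = {name: [] for name in trait_names}
    diag_r = {name: [] for name in trait_names}
    for i, a in enumerate(trait_names):
        for j, b in enumerate(trait_names):
            if i >= j:
                continue
            fit, ia, ib = lut[(a, b)]
            g0[i, j] = g0[j, i] = float(np.median(fit.samples["G0"][:, ia, ib]))
            r0[i, j] = r0[j, i] = float(np.median(fit.samples["R0"][:, ia, ib]))
            diag_g[a].append(float(np.median(fit.samples["G0"][:, ia, ia])))
            diag_g[b].append(float(np.median(fit.samples["G0"][:, ib, ib])))
            diag_r[a].append(float(np.median(fit.samples["R0"][:, ia, ia])))
            diag_r[b].append(float(np.median(fit.samples["R0"][:, ib, ib])))
    for i, name in enumerate(trait_names):
        g0[i, i] = float(np.mean(diag_g[name]))
        r0[i, i] = float(np.mean(diag_r[name]))
    return CovarianceEstimate(list(trait_names), g0, r0)


def bend_matrix(m: np.ndarray, tolerance: float = 0.001) -> tuple[np.ndarray, dict]:
    """Bend a symmetric matrix to positive definiteness by eigenvalue flooring.

    Eigenvalues below ``tolerance`` are raised to it and the matrix is
    reconstructed; the log records eigenvalues before/after and the maximum
    absolute element change. PSD inputs above tolerance come back unchanged.
    """
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("bend_matrix requires a symmetric input")
    vals, vecs = np.linalg.eigh(m)
    if vals.min() >= tolerance:
        return m.copy(), {
            "bent": False, "eigenvalues_before": vals, "eigenvalues_after": vals,
            "max_element_change": 0.0,
        }
    floored = np.maximum(vals, tolerance)
    bent = (vecs * floored) @ vecs.T
    bent = 0.5 * (bent + bent.T)
    return bent, {
        "bent": True, "eigenvalues_before": vals, "eigenvalues_after": floored,
        "max_element_change": float(np.abs(bent - m).max()),
    }


@dataclass
class SelectionResult:
    scenario: int
    trait_names: list
    gebv_mean: pd.Series       # CH4 genomic value per animal
    gebv_sd: pd.Series
    accuracies: pd.Series
    gebv_samples: np.ndarray   # (k, n) thinned CH4 GEBV draws
    intensity: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


def predict_scenarios(
    phenotypes: pd.DataFrame,
    fixed_factor,
    grm: Grm,
    cov: CovarianceEstimate,
    scenario: int,
    spec: ModelSpec,
    ch4_trait: str | None = None,
) -> SelectionResult:
    """Multi-trait GBLUP prediction of CH4 genomic values with fixed (co)variances.

    Scenario 1 uses the measured CH4 records only (univariate, CH4 variances
    from ``cov``); scenario 2 sets every CH4 record missing and predicts from
    the microbial traits through the genetic covariances; scenario 3 uses
    all records. ``cov`` should already be bent.
    """
    if scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")
    ch4_trait = ch4_trait or cov.trait_names[0]
    ch4_idx = cov.trait_names.index(ch4_trait)
    y = phenotypes[cov.trait_names].copy()
    sigma2_ch4 = float(cov.G0[ch4_idx, ch4_idx])

    if scenario == 1:
        fit = fit_univariate(
            y[ch4_trait], spec, grm, fixed_factor=fixed_factor,
            fixed_variances=(sigma2_ch4, float(cov.R0[ch4_idx, ch4_idx])),
        )
        gebv_mean = fit.gebv_mean[:, 0]
        gebv_sd = fit.gebv_sd[:, 0]
        g_draws = fit.samples["g"][:, :, 0]
        ids = fit.animal_ids
    else:
        if scenario == 2:
            off = np.delete(cov.G0[ch4_idx], ch4_idx)
            if np.allclose(off, 0.0):
                warnings.warn("scenario 2 with zero genetic covariance between CH4 "
                              "and every indicator trait: no information flows")
            y[ch4_trait] = np.nan
        fit = fit_multitrait(
            y, spec, grm, fixed_factor=fixed_factor,
            fixed_components=(cov.G0, cov.R0),
        )
        gebv_mean = fit.gebv_mean[:, ch4_idx]
        gebv_sd = fit.gebv_sd[:, ch4_idx]
        g_draws = fit.samples["g"][:, :, ch4_idx]
        ids = fit.animal_ids

    grm_sub = grm.subset(ids)
    acc, _ = genomic_accuracy(gebv_sd, np.diag(grm_sub.matrix), sigma2_ch4)
    return SelectionResult(
        scenario=scenario,
        trait_names=list(cov.trait_names),
        gebv_mean=pd.Series(gebv_mean, index=ids, name="gebv_ch4"),
        gebv_sd=pd.Series(gebv_sd, index=ids, name="gebv_sd"),
        accuracies=pd.Series(acc, index=ids, name="accuracy"),
        gebv_samples=g_draws,
    )


def accuracy(gebv_sd_i, g_rm_ii, sigma2_ch4) -> np.ndarray:
    """Per-animal accuracy sqrt(1 - sd_i^2/(g_ii sigma2)); see genomic_accuracy."""
    acc, _ = genomic_accuracy(np.atleast_1d(gebv_sd_i), np.atleast_1d(g_rm_ii),
                              sigma2_ch4)
    return acc


def response_to_selection(
    result: SelectionResult, fractions=(0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)
) -> dict[float, np.ndarray]:
    """Posterior truncation-response distributions per selected fraction.

    Per MCMC draw and fraction p, the floor(p*n) animals with the lowest CH4
    GEBV are selected (ties broken by stable animal order) and the response
    is mean(all) - mean(selected): a positive value is a reduction in
    emissions.
    """
    g = result.gebv_samples
    k, n = g.shape
    out = {}
    for p in fractions:
        n_sel = int(np.floor(p * n))
        if n_sel < 1:
            raise ValueError(f"fraction {p} selects no animals out of {n}")
        order = np.argsort(g, axis=1, kind="stable")
        sel = np.take_along_axis(g, order[:, :n_sel], axis=1)
        out[p] = g.mean(axis=1) - sel.mean(axis=1)
    return out


def response_summary_table(responses: dict[float, np.ndarray]) -> pd.DataFrame:
    rows = []
    for p, samples in sorted(responses.items()):
        s = summarize(samples) if len(samples) >= 100 else None
        rows.append({
            "fraction": p,
            "intensity": selection_intensity(p),
            "reduction_median": float(np.median(samples)),
            "reduction_sd": float(np.std(samples, ddof=1)),
            "signed_change_median": -float(np.median(samples)),
            "p0": s.p0 if s else np.nan,
        })
    return pd.DataFrame(rows)


def select_breeding_panel(
    candidates: pd.DataFrame,
    min_ra: float = 1e-4,
    p0_min: float = 0.95,
    require_full_occupancy: bool = True,
    cap: int | None = 30,
) -> pd.DataFrame:
    """Filter microbial traits for the multi-trait breeding panel.

    Expects columns: ``occupancy_all`` (bool), ``mean_ra`` (fraction),
    ``h2_significant`` (bool; the DIC <= -20 and corrected-BF > 3 gate),
    ``p0`` (sign confidence of r_gCH4), ``rg_median`` and ``h2_median``.
    Qualifying traits are those passing every gate; when more qualify than
    ``cap``, the strongest |r_gCH4| (then higher h2) are kept.
    """
    required = {"mean_ra", "h2_significant", "p0", "rg_median", "h2_median"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table lacks columns: {sorted(missing)}")
    mask = (
        candidates["mean_ra"] >= min_ra
    ) & candidates["h2_significant"].astype(bool) & (candidates["p0"] >= p0_min)
    if require_full_occupancy and "occupancy_all" in candidates.columns:
        mask &= candidates["occupancy_all"].astype(bool)
    panel = candidates[mask].copy()
    panel["abs_rg"] = panel["rg_median"].abs()
    panel = panel.sort_values(["abs_rg", "h2_median"], ascending=False)
    if cap is not None and len(panel) > cap:
        panel = panel.iloc[:cap]
    return panel.drop(columns=["abs_rg"])
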