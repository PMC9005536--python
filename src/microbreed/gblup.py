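"""Bayesian GBLUP animal models via Gibbs sampling.

Univariate model per trait:

    y = Xb + Zg + e,   g | G_RM, sg2 ~ N(0, G_RM sg2),   e ~ N(0, I se2)

and the bivariate/multi-trait extension with g ~ N(0, G_RM (x) G0),
e ~ N(0, I (x) R0). Fixed effects get a flat prior; variance components get
flat (constant) improper priors, giving full conditionals sg2 ~ S/chi2_(n-2)
and G0 ~ IW(S, n-t-1). (The sharper nu = 0 scale-prior limit places an
improper spike on singular covariance matrices, which in multi-trait models
creates an absorbing boundary at genetic correlations of +/-1; the flat
limit avoids it.)

The sampler works in the eigenbasis of the stabilized relationship matrix
G* = 0.99 G_RM + 0.01 I: with one record per animal the conditional
precision of the transformed genomic effects is diagonal (univariate) or
block-diagonal in t x t animal blocks (multi-trait), so a sweep costs O(n)
resp. O(n t^3) instead of a dense n x n solve. Missing records in
multi-trait models are handled by data augmentation: each sweep the missing
phenotypes are drawn from their residual conditional given the animal's
observed traits.

Besides the thinned draws, the sampler accumulates the Rao-Blackwellized
posterior mean of the genomic effects (the average of their full-conditional
means), which has far smaller Monte-Carlo error than the average of draws
and is what ``gebv_mean`` reports.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve

from .genomics import Grm
from .simulate import design_matrix_from_factor

__all__ = [
    "ModelSpec", "McmcFit", "PosteriorSummary",
    "fit_univariate", "fit_bivariate", "fit_multitrait",
    "summarize", "hpd_interval", "geweke_z", "mcse_timeseries",
    "dic", "bayes_factor", "heritability_from_samples", "rg_samples",
    "deregress_gebv", "group_genomic_variance",
]


@dataclass(frozen=True)
class ModelSpec:
    """MCMC settings and priors for a GBLUP fit.

    Defaults are desk-scale (100k iterations / 20k burn-in / thin 100);
    ``ModelSpec.production_settings()`` restores the heavyweight 1M/200k/100
    schedule used for production runs.
    """

    n_iter: int = 100_000
    burn_in: int = 20_000
    thin: int = 100
    seed: int = 0
    blend: float = 0.01
    prior_df: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def production_settings(cls, seed: int = 0) -> "ModelSpec":
        return cls(n_iter=1_000_000, burn_in=200_000, thin=100, seed=seed)

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSummary:
    median: float
    hpd_low: float
    hpd_high: float
    p0: float
    n_samples: int
    extra: dict = field(default_factory=dict)


@dataclass
class McmcFit:
    trait_names: list
    animal_ids: pd.Index
    samples: dict                 # 'sg2'/'se2' (k,) or 'G0'/'R0' (k,t,t); 'b'; 'g'
    gebv_mean: np.ndarray         # (n, t) Rao-Blackwellized posterior mean
    gebv_sd: np.ndarray           # (n, t) posterior sd of draws
    deviance: np.ndarray          # (k,) observed-data conditional deviance
    deviance_at_mean: float
    spec: ModelSpec
    data_hash: str
    has_genomic: bool = True
    loglik_integrated: np.ndarray | None = None  # (k,) g-integrated likelihood
    theta_draws: np.ndarray | None = None        # (k, d) for Laplace-Metropolis
    psd_projections: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.deviance)


# ---------------------------------------------------------------------------
# helpers

def _hash_data(*arrays) -> str:
    h = hashlib.sha1()
    for a in arrays:
        h.update(np.ascontiguousarray(np.nan_to_num(np.asarray(a, float), nan=-9e9)))
    return h.hexdigest()


def _resolve_design(x, fixed_factor, n: int) -> np.ndarray:
    if x is not None:
        x = np.asarray(x, dtype=float)
    elif fixed_factor is not None:
        x = design_matrix_from_factor(pd.Series(fixed_factor))
    else:
        x = np.ones((n, 1))
    if x.shape[0] != n:
        raise ValueError("design matrix rows must match phenotype length")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed-effect design is rank-deficient after reduction")
    return x


def _draw_invchi2(rng, df: float, scale_sum: float) -> float:
    return scale_sum / rng.chisquare(df)


def _draw_invwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    # tiny relative ridge keeps early sweeps (near-zero effects) full rank
    t = scale.shape[0]
    ridge = 1e-10 * max(float(np.trace(scale)) / t, 1e-30)
    return stats.invwishart.rvs(df=df, scale=scale + ridge * np.eye(t),
                                random_state=rng)


def _project_psd(m: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    d, u = np.linalg.eigh(m)
    return (u * np.clip(d, floor, None)) @ u.T


def _ensure_pd(m: np.ndarray) -> tuple[np.ndarray, int]:
    """Return a positive-definite version of ``m`` and whether projection was needed."""
    try:
        np.linalg.cholesky(m)
        return m, 0
    except np.linalg.LinAlgError:
        return _project_psd(m, 1e-10), 1


# ---------------------------------------------------------------------------
# univariate Gibbs

def fit_univariate(
    y,
    spec: ModelSpec,
    grm: Grm | None = None,
    fixed_factor=None,
    x=None,
    include_genomic: bool = True,
    fixed_variances: tuple[float, float] | None = None,
) -> McmcFit:
    """Gibbs sampler for the univariate animal model.

    ``y`` is a pandas Series indexed by animal ID (NaN records are dropped
    together with their GRM rows) or a plain vector aligned to the GRM.
    With ``include_genomic=False`` the reduced model without g is fitted
    (used for DIC/Bayes-factor comparisons). ``fixed_variances=(sg2, se2)``
    freezes the variance components (location parameters only).
    """
    if isinstance(y, pd.Series):
        y = y.dropna()
        ids = y.index
        yv = y.to_numpy(dtype=float)
        if grm is not None:
            grm = grm.subset(ids)
        if fixed_factor is not None:
            fixed_factor = pd.Series(fixed_factor).loc[ids]
    else:
        yv = np.asarray(y, dtype=float)
        ids = grm.animal_ids if grm is not None else pd.Index(range(len(yv)))
        if np.isnan(yv).any():
            raise ValueError("NaN phenotypes require a pandas Series input")
    n = len(yv)
    x = _resolve_design(x, fixed_factor, n)
    p = x.shape[1]
    rng = np.random.default_rng(spec.seed)
    vy = float(np.var(yv)) or 1.0

    if include_genomic:
        if grm is None:
            raise ValueError("a GRM is required for the genomic model")
        d, u = grm.eigendecomposition(spec.blend)
    else:
        d, u = np.ones(n), np.eye(n)

    yt = u.T @ yv
    xt = u.T @ x
    xtx = xt.T @ xt
    lxx = np.linalg.cholesky(xtx)

    if fixed_variances is not None:
        sg2, se2 = map(float, fixed_variances)
    else:
        sg2, se2 = 0.5 * vy, 0.5 * vy
    a = np.zeros(n)
    b = np.linalg.lstsq(xt, yt, rcond=None)[0]

    k = spec.n_samples
    out_sg2 = np.empty(k)
    out_se2 = np.empty(k)
    out_b = np.empty((k, p))
    out_a = np.empty((k, n))
    out_dev = np.empty(k)
    out_ll = np.empty(k)
    rb_acc = np.zeros(n)
    rb_n = 0
    kept = 0
    const = n * np.log(2 * np.pi)

    # with frozen variances, draw b from its g-marginalized conditional
    # (y ~ N(Xb, diag(sg2 d + se2)) in the eigenbasis) followed by a | b:
    # a blocked draw from p(b, a | y) with no b <-> a autocorrelation
    collapsed_b = fixed_variances is not None and include_genomic
    if collapsed_b:
        v_marg = sg2 * d + se2
        pb = (xt / v_marg[:, None]).T @ xt
        lpb = np.linalg.cholesky(pb)
        b_marg_mean = np.linalg.solve(pb, xt.T @ (yt / v_marg))

    for it in range(spec.n_iter):
        if collapsed_b:
            b = b_marg_mean + np.linalg.solve(lpb.T, rng.standard_normal(p))
        else:
            # fixed effects: b ~ N((X'X)^-1 X'(y - a), se2 (X'X)^-1)
            bhat = np.linalg.solve(xtx, xt.T @ (yt - a))
            z = rng.standard_normal(p)
            b = bhat + np.sqrt(se2) * np.linalg.solve(lxx.T, z)

        resid_f = yt - xt @ b
        if include_genomic:
            prec = 1.0 / se2 + 1.0 / (d * sg2)
            var_a = 1.0 / prec
            mean_a = var_a * resid_f / se2
            a = mean_a + np.sqrt(var_a) * rng.standard_normal(n)
            if it >= spec.burn_in:
                rb_acc += mean_a
                rb_n += 1
        resid = resid_f - a
        sse = float(resid @ resid)

        if fixed_variances is None:
            if include_genomic:
                sg2 = _draw_invchi2(rng, n - 2 + spec.prior_df, float(a @ (a / d)))
            se2 = _draw_invchi2(rng, n - 2 + spec.prior_df, sse)
        if not np.isfinite(se2) or (include_genomic and not np.isfinite(sg2)):
            raise FloatingPointError(f"divergent draw at iteration {it}")

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and kept < k:
            out_sg2[kept] = sg2 if include_genomic else 0.0
            out_se2[kept] = se2
            out_b[kept] = b
            out_a[kept] = a
            out_dev[kept] = const + n * np.log(se2) + sse / se2
            v = sg2 * d + se2 if include_genomic else np.full(n, se2)
            out_ll[kept] = -0.5 * (const + np.log(v).sum() + np.sum(resid_f**2 / v))
            kept += 1

    g_samples = out_a @ u.T  # (k, n)
    if collapsed_b:
        # the conditional mean of a is linear in b, so the posterior mean is
        # its value at b's exact marginal mean (full Rao-Blackwellization)
        var_a = 1.0 / (1.0 / se2 + 1.0 / (d * sg2))
        a_post = var_a * (yt - xt @ b_marg_mean) / se2
        gebv_mean = (u @ a_post)[:, None]
    elif include_genomic and rb_n:
        gebv_mean = (u @ (rb_acc / rb_n))[:, None]
    else:
        gebv_mean = np.zeros((n, 1))
    gebv_sd = g_samples.std(axis=0, ddof=1)[:, None]

    b_mean = out_b.mean(axis=0)
    g_mean = gebv_mean[:, 0]
    se2_mean = out_se2.mean()
    resid_mean = yv - x @ b_mean - (g_mean if include_genomic else 0.0)
    dev_at_mean = const + n * np.log(se2_mean) + float(resid_mean @ resid_mean) / se2_mean

    samples = {"se2": out_se2, "b": out_b, "g": g_samples[:, :, None]}
    if include_genomic:
        samples["sg2"] = out_sg2
    if include_genomic:
        theta = np.column_stack([out_b, np.log(out_sg2), np.log(out_se2)])
    else:
        theta = np.column_stack([out_b, np.log(out_se2)])

    return McmcFit(
        trait_names=[getattr(y, "name", None) or "trait_0"],
        animal_ids=pd.Index(ids),
        samples=samples,
        gebv_mean=gebv_mean,
        gebv_sd=gebv_sd,
        deviance=out_dev,
        deviance_at_mean=dev_at_mean,
        spec=spec,
        data_hash=_hash_data(yv, x),
        has_genomic=include_genomic,
        loglik_integrated=out_ll,
        theta_draws=theta,
    )


# ---------------------------------------------------------------------------
# multi-trait Gibbs (bivariate and the 31-trait selection scenarios)

def fit_multitrait(
    y: pd.DataFrame,
    spec: ModelSpec,
    grm: Grm,
    fixed_factor=None,
    x=None,
    fixed_components: tuple[np.ndarray, np.ndarray] | None = None,
) -> McmcFit:
    """Gibbs sampler for the multi-trait animal model with per-trait missing records.

    ``y`` is animals x traits with NaN for missing records; the GRM is
    subset/aligned to the phenotype index. ``fixed_components=(G0, R0)``
    freezes the (co)variance matrices (used for the selection scenarios);
    otherwise G0 and R0 get inverse-Wishart full conditionals.
    """
    y = y.copy()
    ids = y.index
    grm = grm.subset(ids)
    yv = y.to_numpy(dtype=float)
    n, t = yv.shape
    if t < 2:
        raise ValueError("use fit_univariate for a single trait")
    if np.isnan(yv).all(axis=1).all():
        raise ValueError("no observed records")
    if fixed_factor is not None:
        fixed_factor = pd.Series(fixed_factor).loc[ids]
    x = _resolve_design(x, fixed_factor, n)
    p = x.shape[1]
    rng = np.random.default_rng(spec.seed)

    d, u = grm.eigendecomposition(spec.blend)
    xt_ = u.T @ x
    xtx = xt_.T @ xt_
    lxx = np.linalg.cholesky(xtx)

    missing = np.isnan(yv)
    has_missing = bool(missing.any())
    col_mean = np.array([c[np.isfinite(c)].mean() if np.isfinite(c).any() else 0.0
                         for c in yv.T])
    y_aug = np.where(missing, col_mean, yv)

    # group animals by missing pattern for the augmentation step
    patterns = []
    if has_missing:
        keys = [tuple(row) for row in missing]
        for key in sorted(set(keys)):
            if not any(key):
                continue
            rows = np.array([i for i, kk in enumerate(keys) if kk == key])
            m_idx = np.array([j for j, miss in enumerate(key) if miss])
            o_idx = np.array([j for j, miss in enumerate(key) if not miss])
            patterns.append((rows, o_idx, m_idx))
    obs_patterns = []  # for the observed-data deviance
    keys = [tuple(row) for row in missing]
    for key in sorted(set(keys)):
        o_idx = np.array([j for j, miss in enumerate(key) if not miss])
        if len(o_idx) == 0:
            continue
        rows = np.array([i for i, kk in enumerate(keys) if kk == key])
        obs_patterns.append((rows, o_idx))

    nv = np.array([c[np.isfinite(c)].var() if np.isfinite(c).sum() > 1 else 1.0
                   for c in yv.T])
    nv = np.where(nv > 0, nv, 1.0)
    if fixed_components is not None:
        g0 = np.asarray(fixed_components[0], dtype=float).copy()
        r0 = np.asarray(fixed_components[1], dtype=float).copy()
    else:
        g0 = np.diag(nv / 2)
        r0 = np.diag(nv / 2)

    bmat = np.zeros((p, t))
    a = np.zeros((n, t))
    yt = u.T @ y_aug

    k = spec.n_samples
    out_g0 = np.empty((k, t, t))
    out_r0 = np.empty((k, t, t))
    out_b = np.empty((k, p, t))
    out_a = np.empty((k, n, t))
    rb_acc = np.zeros((n, t))
    rb_n = 0
    kept = 0
    psd_projections = 0

    # with frozen (co)variances, draw B from its g-marginalized conditional
    # (per eigen-row i, y_i ~ N(B'x_i, d_i G0 + R0)), then a | B: a blocked
    # draw of the location parameters with no B <-> a autocorrelation
    collapsed_b = fixed_components is not None
    # when every animal shares one missing pattern (e.g. CH4 set missing for
    # all records), the observed-data residual precision is the same padded
    # matrix for every animal, so the eigenbasis stays separable and no
    # augmentation is needed: the observed traits drive a directly and the
    # unobserved trait's genomic effect is predicted through G0
    uniform_missing = False
    if collapsed_b and has_missing:
        uniform_missing = bool((missing == missing[0]).all() and (~missing[0]).any())
    if collapsed_b:
        if uniform_missing:
            obs_cols = np.where(~missing[0])[0]
            t_obs = len(obs_cols)
            yt = u.T @ np.where(missing, 0.0, yv)  # missing coords never enter
            q_res = np.zeros((t, t))
            q_res[np.ix_(obs_cols, obs_cols)] = np.linalg.inv(
                r0[np.ix_(obs_cols, obs_cols)])
            r0_oo = r0[np.ix_(obs_cols, obs_cols)]
            g0_oo = g0[np.ix_(obs_cols, obs_cols)]
            v_marg = d[:, None, None] * g0_oo[None] + r0_oo[None]
            v_inv = np.linalg.inv(v_marg)
            pb = np.einsum("ia,ib,ijk->ajbk", xt_, xt_, v_inv).reshape(
                p * t_obs, p * t_obs)
            lpb = np.linalg.cholesky(pb)
            w = np.einsum("ijk,ik->ij", v_inv, yt[:, obs_cols])
            theta_mean_const = cho_solve((lpb, True), (xt_.T @ w).reshape(p * t_obs))
        else:
            v_marg = d[:, None, None] * g0[None] + r0[None]
            v_inv = np.linalg.inv(v_marg)
            pb = np.einsum("ia,ib,ijk->ajbk", xt_, xt_, v_inv).reshape(p * t, p * t)
            lpb = np.linalg.cholesky(pb)
            if not has_missing:
                w = np.einsum("ijk,ik->ij", v_inv, yt)
                theta_mean_const = cho_solve((lpb, True), (xt_.T @ w).reshape(p * t))
        # genomic-block precision is loop-invariant with frozen components
        g0i_c = np.linalg.inv(g0)
        r0i_c = q_res if uniform_missing else np.linalg.inv(r0)
        l_r0_c = np.linalg.cholesky(r0)
        prec_c = r0i_c[None, :, :] + g0i_c[None, :, :] / d[:, None, None]
        prec_inv_c = np.linalg.inv(prec_c)
        lpT_inv_c = np.linalg.inv(np.transpose(np.linalg.cholesky(prec_c), (0, 2, 1)))

    for it in range(spec.n_iter):
        if collapsed_b:
            g0i, r0i, l_r0 = g0i_c, r0i_c, l_r0_c
        else:
            g0i = np.linalg.inv(g0)
            r0i = np.linalg.inv(r0)
            l_r0 = np.linalg.cholesky(r0)

        if has_missing and not uniform_missing:
            mu = x @ bmat + u @ a
            for rows, o_idx, m_idx in patterns:
                mu_m = mu[np.ix_(rows, m_idx)]
                if len(o_idx) == 0:
                    cov = r0[np.ix_(m_idx, m_idx)]
                    ls = np.linalg.cholesky(cov)
                    y_aug[np.ix_(rows, m_idx)] = (
                        mu_m + rng.standard_normal((len(rows), len(m_idx))) @ ls.T
                    )
                else:
                    r_oo = r0[np.ix_(o_idx, o_idx)]
                    w = np.linalg.solve(r_oo, r0[np.ix_(o_idx, m_idx)]).T
                    resid_o = y_aug[np.ix_(rows, o_idx)] - mu[np.ix_(rows, o_idx)]
                    cond_mean = mu_m + resid_o @ w.T
                    cond_cov = r0[np.ix_(m_idx, m_idx)] - w @ r0[np.ix_(o_idx, m_idx)]
                    ls = np.linalg.cholesky(_project_psd(cond_cov))
                    y_aug[np.ix_(rows, m_idx)] = (
                        cond_mean + rng.standard_normal((len(rows), len(m_idx))) @ ls.T
                    )
            yt = u.T @ y_aug

        if collapsed_b:
            if uniform_missing:
                theta = theta_mean_const + np.linalg.solve(
                    lpb.T, rng.standard_normal(p * t_obs))
                bmat = np.zeros((p, t))
                bmat[:, obs_cols] = theta.reshape(p, t_obs)
            else:
                if has_missing:
                    w = np.einsum("ijk,ik->ij", v_inv, yt)
                    theta_mean = cho_solve((lpb, True), (xt_.T @ w).reshape(p * t))
                else:
                    theta_mean = theta_mean_const
                theta = theta_mean + np.linalg.solve(lpb.T,
                                                     rng.standard_normal(p * t))
                bmat = theta.reshape(p, t)
        else:
            # fixed effects: B_hat is OLS (same X for all traits); cov kron(R0, (X'X)^-1)
            bhat = np.linalg.solve(xtx, xt_.T @ (yt - a))
            z = rng.standard_normal((p, t))
            bmat = bhat + np.linalg.solve(lxx.T, z) @ l_r0.T

        # genomic effects: per-animal t x t blocks, precision R0^-1 + G0^-1 / d_i
        e_f = yt - xt_ @ bmat
        rhs = e_f @ r0i.T
        z = rng.standard_normal((n, t))
        if collapsed_b:
            mean_a = np.einsum("ijk,ik->ij", prec_inv_c, rhs)
            a = mean_a + np.einsum("ijk,ik->ij", lpT_inv_c, z)
        else:
            prec = r0i[None, :, :] + g0i[None, :, :] / d[:, None, None]
            mean_a = np.linalg.solve(prec, rhs[:, :, None])[:, :, 0]
            lp = np.linalg.cholesky(prec)
            a = mean_a + np.linalg.solve(np.transpose(lp, (0, 2, 1)), z[:, :, None])[:, :, 0]
        if it >= spec.burn_in:
            rb_acc += mean_a
            rb_n += 1

        if fixed_components is None:
            s_g = (a / d[:, None]).T @ a
            g0 = _draw_invwishart(rng, n - t - 1 + spec.prior_df, s_g)
            g0, flag = _ensure_pd(g0)
            psd_projections += flag
            e_res = e_f - a
            r0 = _draw_invwishart(rng, n - t - 1 + spec.prior_df, e_res.T @ e_res)
            r0, flag = _ensure_pd(r0)
            psd_projections += flag
        if not np.all(np.isfinite(g0)) or not np.all(np.isfinite(r0)):
            raise FloatingPointError(f"divergent draw at iteration {it}")

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and kept < k:
            out_g0[kept] = g0
            out_r0[kept] = r0
            out_b[kept] = bmat
            out_a[kept] = a
            kept += 1

    if collapsed_b and (not has_missing or uniform_missing):
        # exact posterior mean: a's conditional mean is linear in B, and B's
        # marginal posterior mean is available in closed form
        if uniform_missing:
            b_post = np.zeros((p, t))
            b_post[:, obs_cols] = theta_mean_const.reshape(p, t_obs)
        else:
            b_post = theta_mean_const.reshape(p, t)
        e_post = yt - xt_ @ b_post
        a_post = np.einsum("ijk,ik->ij", prec_inv_c, e_post @ r0i_c.T)
        rb_acc = a_post * rb_n  # overrides the draw-based accumulation below

    # back-transform genomic effects and evaluate the observed-data deviance
    g_samples = np.einsum("ij,kjt->kit", u, out_a)
    out_dev = np.empty(k)
    for s in range(k):
        mu = x @ out_b[s] + g_samples[s]
        out_dev[s] = _obs_deviance(yv, mu, out_r0[s], obs_patterns)
    gebv_mean = u @ (rb_acc / rb_n)
    gebv_sd = g_samples.std(axis=0, ddof=1)

    mu_mean = x @ out_b.mean(axis=0) + gebv_mean
    dev_at_mean = _obs_deviance(yv, mu_mean, out_r0.mean(axis=0), obs_patterns)

    return McmcFit(
        trait_names=list(y.columns),
        animal_ids=pd.Index(ids),
        samples={"G0": out_g0, "R0": out_r0, "b": out_b, "g": g_samples},
        gebv_mean=gebv_mean,
        gebv_sd=gebv_sd,
        deviance=out_dev,
        deviance_at_mean=dev_at_mean,
        spec=spec,
        data_hash=_hash_data(yv, x),
        psd_projections=psd_projections,
    )


def _obs_deviance(yv, mu, r0, obs_patterns) -> float:
    total = 0.0
    for rows, o_idx in obs_patterns:
        sub = r0[np.ix_(o_idx, o_idx)]
        resid = yv[np.ix_(rows, o_idx)] - mu[np.ix_(rows, o_idx)]
        sign, logdet = np.linalg.slogdet(sub)
        quad = np.einsum("ij,ij->", resid @ np.linalg.inv(sub), resid)
        total += len(rows) * (len(o_idx) * np.log(2 * np.pi) + logdet) + quad
    return float(total)


def fit_bivariate(
    y2: pd.DataFrame, spec: ModelSpec, grm: Grm, fixed_factor=None, x=None,
    fixed_components=None,
) -> McmcFit:
    """Bivariate GBLUP (trait pair, typically CH4 + one microbial trait)."""
    if y2.shape[1] != 2:
        raise ValueError("fit_bivariate expects exactly 2 trait columns")
    return fit_multitrait(y2, spec, grm, fixed_factor=fixed_factor, x=x,
                          fixed_components=fixed_components)


def rg_samples(fit: McmcFit, i: int = 0, j: int = 1) -> np.ndarray:
    """Posterior draws of the genomic correlation G0[i,j]/sqrt(G0[i,i] G0[j,j])."""
    g0 = fit.samples["G0"]
    return g0[:, i, j] / np.sqrt(g0[:, i, i] * g0[:, j, j])


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics

def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    m = max(int(np.ceil(prob * n)), 2)
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[: n - m + 1]
    lo = int(np.argmin(widths))
    return float(s[lo]), float(s[lo + m - 1])


def summarize(samples: np.ndarray, prob: float = 0.95) -> PosteriorSummary:
    """Median, HPD interval and P0 (probability of sign agreement with the median)."""
    s = np.asarray(samples, dtype=float)
    if len(s) < 100:
        raise ValueError("need at least 100 retained samples")
    lo, hi = hpd_interval(s, prob)
    p0 = max(float((s > 0).mean()), float((s < 0).mean()))
    return PosteriorSummary(float(np.median(s)), lo, hi, p0, len(s))


def _spectral_s0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Bartlett-windowed autocovariances."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    lag_max = min(n - 1, max(int(round(n ** (1 / 3))), 1))
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    w = 1.0 - np.arange(1, lag_max + 1) / (lag_max + 1)
    return float(acov[0] + 2.0 * np.sum(w * acov[1: lag_max + 1]))


def geweke_z(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence Z: compares the means of the first ``first`` and last
    ``last`` fractions of the chain using spectral variance estimates."""
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise ValueError("chain must have at least 100 samples")
    if np.ptp(x) == 0:
        warnings.warn("constant chain: Geweke Z undefined")
        return float("nan")
    a = x[: int(first * len(x))]
    b = x[-int(last * len(x)):]
    va = _spectral_s0(a) / len(a)
    vb = _spectral_s0(b) / len(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def mcse_timeseries(chain, n_batches: int | None = None) -> tuple[float, float]:
    """Batch-means Monte-Carlo standard error and the sd/MCSE ratio.

    Returns (mcse, ratio); a posterior is considered well resolved when the
    ratio is at least 10. Constant chains give (0, nan) with a warning.
    """
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise ValueError("chain must have at least 100 samples")
    sd = float(x.std(ddof=1))
    if sd == 0:
        warnings.warn("constant chain: MCSE ratio undefined")
        return 0.0, float("nan")
    k = n_batches or int(np.floor(np.sqrt(len(x))))
    m = len(x) // k
    means = x[: k * m].reshape(k, m).mean(axis=1)
    mcse = float(means.std(ddof=1) / np.sqrt(k))
    return mcse, sd / mcse if mcse > 0 else float("inf")


def convergence_report(fit: McmcFit) -> pd.DataFrame:
    """Geweke Z and MCSE ratio for every scalar variance-component chain."""
    rows = []
    chains = {}
    if "sg2" in fit.samples:
        chains["sg2"] = fit.samples["sg2"]
    if "se2" in fit.samples:
        chains["se2"] = fit.samples["se2"]
    if "G0" in fit.samples:
        t = fit.samples["G0"].shape[1]
        for i_ in range(t):
            for j_ in range(i_, t):
                chains[f"G0[{i_},{j_}]"] = fit.samples["G0"][:, i_, j_]
                chains[f"R0[{i_},{j_}]"] = fit.samples["R0"][:, i_, j_]
    for name, c in chains.items():
        mcse, ratio = mcse_timeseries(c)
        rows.append({"parameter": name, "geweke_z": geweke_z(c),
                     "mcse": mcse, "sd_to_mcse": ratio})
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# model comparison

def dic(fit_full: McmcFit, fit_reduced: McmcFit) -> tuple[float, float, float]:
    """DIC = mean deviance + pD for both fits and their difference (full - reduced).

    A difference of -20 or lower is the evidence threshold for the genomic
    effect used throughout the package.
    """
    if fit_full.data_hash != fit_reduced.data_hash:
        raise ValueError("fits were not run on identical data")
    dics = []
    for fit in (fit_full, fit_reduced):
        dbar = float(fit.deviance.mean())
        pd_ = dbar - fit.deviance_at_mean
        dics.append(dbar + pd_)
    return dics[0], dics[1], dics[0] - dics[1]


def _laplace_metropolis_logml(fit: McmcFit) -> float:
    """Laplace-Metropolis marginal likelihood from thinned posterior draws.

    Parameters are (b, log variance components); with the package's improper
    scale priors the posterior kernel in this parameterisation is the
    g-integrated likelihood itself.
    """
    if fit.theta_draws is None or fit.loglik_integrated is None:
        raise ValueError("fit lacks stored likelihood evaluations")
    theta = fit.theta_draws
    dpar = theta.shape[1]
    cov = np.cov(theta, rowvar=False)
    cov = np.atleast_2d(cov)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        warnings.warn("degenerate posterior covariance; falling back to diagonal")
        logdet = float(np.log(np.clip(np.var(theta, axis=0), 1e-300, None)).sum())
    lmax = float(fit.loglik_integrated.max())
    return 0.5 * dpar * np.log(2 * np.pi) + 0.5 * logdet + lmax


def bayes_factor(fit_full: McmcFit, fit_reduced: McmcFit, n_tests: int = 2473
                 ) -> tuple[float, float]:
    """Bayes factor full/reduced via Laplace-Metropolis, with the prior-odds
    multiple-testing correction bf_corrected = bf_raw / n_tests."""
    if fit_full.data_hash != fit_reduced.data_hash:
        raise ValueError("fits were not run on identical data")
    log_bf = _laplace_metropolis_logml(fit_full) - _laplace_metropolis_logml(fit_reduced)
    bf_raw = float(np.exp(np.clip(log_bf, -700, 700)))
    return bf_raw, bf_raw / n_tests


# ---------------------------------------------------------------------------
# derived genetic parameters

H2_BANDS = ((0.20, "lowly heritable"), (0.40, "moderately heritable"),
            (np.inf, "highly heritable"))


def classify_h2(h2: float) -> str:
    """Heritability bands: <0.20 low, 0.20-0.40 moderate, >0.40 high."""
    if h2 < 0.20:
        return "lowly heritable"
    if h2 <= 0.40:
        return "moderately heritable"
    return "highly heritable"


def h2_samples(fit: McmcFit, trait: int = 0) -> np.ndarray:
    if "sg2" in fit.samples:
        sg2 = fit.samples["sg2"]
        se2 = fit.samples["se2"]
    else:
        sg2 = fit.samples["G0"][:, trait, trait]
        se2 = fit.samples["R0"][:, trait, trait]
    return sg2 / (sg2 + se2)


def heritability_from_samples(fit: McmcFit, trait: int = 0) -> PosteriorSummary:
    """Per-draw h2 = sg2/(sg2+se2), summarized, with the heritability band."""
    h2 = h2_samples(fit, trait)
    summ = summarize(h2)
    summ.extra["classification"] = classify_h2(summ.median)
    return summ


def genomic_accuracy(gebv_sd: np.ndarray, grm_diag: np.ndarray, sigma2: float
                     ) -> tuple[np.ndarray, int]:
    """Per-animal accuracy sqrt(1 - sd_i^2 / (g_ii sigma2)), clipped at 0."""
    ratio = np.asarray(gebv_sd, float) ** 2 / (np.asarray(grm_diag, float) * sigma2)
    n_clipped = int((ratio > 1).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} animal(s) with sd^2 above the genomic variance; "
                      "accuracy clipped to 0")
    return np.sqrt(np.clip(1.0 - ratio, 0.0, None)), n_clipped


def deregress_gebv(
    fit: McmcFit, grm: Grm, trait: int = 0, min_reliability: float = 0.01,
    sigma2_g: float | None = None,
) -> tuple[pd.Series, list]:
    """Deregressed GEBVs, dGEBV_i = GEBV_i / reliability_i.

    Reliability is the squared Eq.-accuracy of each animal's GEBV; animals
    below ``min_reliability`` are excluded (returned separately) rather than
    blown up by the deregression.
    """
    grm = grm.subset(fit.animal_ids)
    if sigma2_g is None:
        if "sg2" in fit.samples:
            sigma2_g = float(np.median(fit.samples["sg2"]))
        else:
            sigma2_g = float(np.median(fit.samples["G0"][:, trait, trait]))
    acc, _ = genomic_accuracy(fit.gebv_sd[:, trait], np.diag(grm.matrix), sigma2_g)
    rel = acc**2
    ok = rel >= min_reliability
    excluded = list(fit.animal_ids[~ok])
    dg = pd.Series(np.where(ok, fit.gebv_mean[:, trait] / np.where(ok, rel, 1.0), np.nan),
                   index=fit.animal_ids, name="dGEBV")
    return dg[ok], excluded


def group_genomic_variance(fit: McmcFit, groups: pd.Series, trait: int = 0
                           ) -> dict[str, np.ndarray]:
    """Per-group posterior distributions of the within-group variance of the
    sampled genomic effects (the Sorensen-style variance partition)."""
    groups = pd.Series(groups).loc[fit.animal_ids]
    g = fit.samples["g"][:, :, trait]  # (k, n)
    out = {}
    for level, idx in groups.groupby(groups).groups.items():
        pos = fit.animal_ids.get_indexer(idx)
        if len(pos) < 2:
            warnings.warn(f"group {level!r} has < 2 animals; excluded")
            continue
        out[str(level)] = g[:, pos].var(axis=1, ddof=1)
    return out


def group_overlap_summary(dists: dict[str, np.ndarray], prob: float = 0.95
                          ) -> pd.DataFrame:
    """Pairwise overlap of HPD intervals across group posterior distributions."""
    names = list(dists)
    intervals = {k: hpd_interval(v, prob) for k, v in dists.items()}
    rows = []
    for i_, a in enumerate(names):
        for b in names[i_ + 1:]:
            lo = max(intervals[a][0], intervals[b][0])
            hi = min(intervals[a][1], intervals[b][1])
            rows.append({"group_a": a, "group_b": b, "overlaps": hi > lo})
    return pd.DataFrame(rows)
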