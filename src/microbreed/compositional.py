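"""Compositional treatment of metagenomic abundance tables.

Raw microbial abundances (read counts for genera and KEGG-orthologue genes,
assembly coverages for uncultured genomes) are compositional: only relative
information is meaningful, and correlations computed on raw proportions are
spurious. This module turns raw tables into analysis-ready traits via

* closure to relative abundances,
* core-feature filtering on occupancy and mean relative abundance,
* Bayesian-multiplicative (GBM) replacement of count zeros,
* additive (ALR) and centred (CLR) log-ratio transforms,
* diagnostics for choosing an ALR reference part (occupancy, mean RA,
  log-ratio variance, Procrustes agreement with the full log-ratio geometry).

All relative-abundance thresholds in this package are fractions (0.001 % is
passed as 1e-5); the CLI converts percent notation at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "TransformedTable",
    "relative_abundance",
    "filter_core",
    "gbm_zero_replace",
    "alr_transform",
    "clr_transform",
    "inverse_alr",
    "reference_diagnostics",
    "procrustes_correlation",
]

FEATURE_CLASSES = ("genus", "RUG", "gene")


@dataclass
class AbundanceTable:
    """Sample x feature non-negative abundance matrix.

    ``data`` holds samples as rows and features as columns (counts,
    coverages or relative abundances). ``feature_class`` labels the kind of
    feature; ``process_label`` optionally maps gene features to the
    biological process they belong to (CH4 metabolism, other metabolism,
    genetic information, communication & host interaction, uncharacterized).
    """

    data: pd.DataFrame
    feature_class: str = "genus"
    process_label: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"feature_class must be one of {FEATURE_CLASSES}")
        if not self.data.index.is_unique:
            raise ValueError("sample IDs must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("feature IDs must be unique")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("abundances must be finite and non-negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass
class TransformedTable:
    """Log-ratio transformed table (samples x J-1 for ALR, samples x J for CLR)."""

    data: pd.DataFrame
    transform_kind: str
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.transform_kind not in ("ALR", "CLR"):
            raise ValueError("transform_kind must be 'ALR' or 'CLR'")
        if self.transform_kind == "ALR" and self.reference_id is None:
            raise ValueError("ALR table requires a reference_id")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# transform_kind: {self.transform_kind}\n")
            if self.reference_id is not None:
                fh.write(f"# reference_id: {self.reference_id}\n")
            self.data.to_csv(fh, sep="\t")


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to relative abundances (rows sum to 1)."""
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return AbundanceTable(
        table.data.div(totals, axis=0), table.feature_class, table.process_label
    )


def filter_core(
    table: AbundanceTable,
    min_mean_ra: float = 1e-5,
    require_all_samples: bool = True,
    min_occupancy: int | None = None,
    presence_threshold: float = 0.0,
) -> AbundanceTable:
    """Retain core features by occupancy and mean relative abundance.

    A feature is "present" in a sample when its raw value is positive
    (``presence_threshold`` <= 0, the count/RA case) or at least
    ``presence_threshold`` (e.g. 1 for coverage-based features, mirroring a
    1x coverage cut-off). Occupancy is enforced either in every sample
    (``require_all_samples``) or in at least ``min_occupancy`` samples. The
    mean-RA criterion is evaluated on the closed table.
    """
    if min_mean_ra < 0 or min_mean_ra > 1:
        raise ValueError("min_mean_ra must be a fraction in [0, 1]")
    raw = table.data.to_numpy(dtype=float)
    present = raw > 0 if presence_threshold <= 0 else raw >= presence_threshold
    occupancy = present.sum(axis=0)
    n = table.data.shape[0]
    if require_all_samples:
        occ_ok = occupancy == n
    elif min_occupancy is not None:
        occ_ok = occupancy >= min_occupancy
    else:
        occ_ok = np.ones(table.data.shape[1], dtype=bool)
    ra = relative_abundance(table).values
    ra_ok = ra.mean(axis=0) > min_mean_ra
    keep = occ_ok & ra_ok
    if not keep.any():
        warnings.warn("no features pass the core filter; returning empty table")
    kept = table.data.loc[:, table.data.columns[keep]]
    retained_ra = float(ra[:, keep].sum(axis=1).mean()) if keep.any() else 0.0
    labels = None
    if table.process_label is not None:
        labels = table.process_label.loc[kept.columns]
    out = AbundanceTable(kept, table.feature_class, labels)
    out.retained_cumulative_ra = retained_ra
    return out


def gbm_zero_replace(table: AbundanceTable, strength: float | None = None) -> AbundanceTable:
    """Replace count/coverage zeros by Bayesian-multiplicative posterior estimates.

    Each sample's counts are modelled as multinomial with a Dirichlet prior
    alpha_j = s_i * t_j, where t is the across-sample geometric-mean
    composition (computed from non-zero entries) and the per-sample prior
    strength s_i defaults to sqrt of the sample total. A zero entry is
    replaced by its posterior expectation on the count scale,
    ``n_i * t_j * s_i / (n_i + s_i)``, and the non-zero entries of the
    sample are multiplicatively rescaled so the sample total is preserved
    and all ratios among originally non-zero parts are unchanged.
    """
    x = table.values.copy()
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        bad = table.sample_ids[totals <= 0]
        raise ValueError(f"sample(s) with all zeros cannot be imputed: {list(bad)}")
    if not (x == 0).any():
        return table

    # geometric-mean composition over samples, per feature from its non-zero entries
    props = x / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(props > 0, np.log(props), np.nan)
    gm = np.exp(np.nanmean(logp, axis=0))
    gm = np.where(np.isnan(gm), np.nanmin(gm) if np.isfinite(np.nanmin(gm)) else 1.0, gm)
    t = gm / gm.sum()

    out = x.copy()
    for i in range(x.shape[0]):
        zeros = x[i] == 0
        if not zeros.any():
            continue
        s_i = float(strength) if strength is not None else np.sqrt(totals[i])
        repl = totals[i] * t[zeros] * s_i / (totals[i] + s_i)
        # guard: a replacement may never exceed the smallest observed count share
        cap = 0.65 * x[i][~zeros].min()
        repl = np.minimum(repl, cap)
        out[i, zeros] = repl
        scale = (totals[i] - repl.sum()) / totals[i]
        out[i, ~zeros] = x[i, ~zeros] * scale
    result = pd.DataFrame(out, index=table.sample_ids, columns=table.feature_ids)
    return AbundanceTable(result, table.feature_class, table.process_label)


def _require_positive(values: np.ndarray, what: str) -> None:
    if np.any(values <= 0):
        raise ValueError(
            f"{what} requires strictly positive values; run gbm_zero_replace first"
        )


def alr_transform(table: AbundanceTable, reference_id: str) -> TransformedTable:
    """Additive log-ratio transform, ln(x_j / x_ref) for each non-reference part."""
    if reference_id not in table.feature_ids:
        raise KeyError(f"reference feature {reference_id!r} not in table")
    ref = table.data[reference_id].to_numpy(dtype=float)
    bad = table.sample_ids[ref <= 0]
    if len(bad):
        raise ValueError(
            f"reference {reference_id!r} is zero/absent in sample(s): {list(bad)}"
        )
    _require_positive(table.values, "ALR")
    others = table.data.drop(columns=[reference_id])
    out = np.log(others.to_numpy(dtype=float)) - np.log(ref)[:, None]
    return TransformedTable(
        pd.DataFrame(out, index=table.sample_ids, columns=others.columns),
        "ALR",
        reference_id,
    )


def clr_transform(table: AbundanceTable) -> TransformedTable:
    """Centred log-ratio transform, ln(x_j) minus the sample's mean log value."""
    _require_positive(table.values, "CLR")
    logs = np.log(table.values)
    out = logs - logs.mean(axis=1, keepdims=True)
    return TransformedTable(
        pd.DataFrame(out, index=table.sample_ids, columns=table.feature_ids), "CLR"
    )


def inverse_alr(transformed: TransformedTable) -> pd.DataFrame:
    """Map ALR coordinates back to relative abundances (reference appended last)."""
    if transformed.transform_kind != "ALR":
        raise ValueError("inverse_alr expects an ALR table")
    expo = np.exp(transformed.data.to_numpy(dtype=float))
    full = np.column_stack([expo, np.ones(expo.shape[0])])
    full /= full.sum(axis=1, keepdims=True)
    cols = list(transformed.data.columns) + [transformed.reference_id]
    return pd.DataFrame(full, index=transformed.data.index, columns=cols)


def procrustes_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Procrustes correlation between two sample configurations.

    Both configurations are column-centred; the narrower one is padded with
    zero columns; orthogonal rotation and isotropic scaling are permitted.
    The statistic is trace-norm based: sum of singular values of X'Y divided
    by the product of Frobenius norms, 1 for identical geometries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("configurations must have the same number of samples")
    k = max(x.shape[1], y.shape[1])
    x = np.pad(x, ((0, 0), (0, k - x.shape[1])))
    y = np.pad(y, ((0, 0), (0, k - y.shape[1])))
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("degenerate (constant) configuration")
    sv = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(sv.sum() / (nx * ny))


def _pcoa_coordinates(dist: np.ndarray, n_axes: int | None = None) -> np.ndarray:
    """Principal coordinates of a distance matrix (classical MDS)."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return coords


def reference_diagnostics(
    table: AbundanceTable, candidate_ids=None
) -> pd.DataFrame:
    """Score candidate ALR reference parts.

    For each candidate: occupancy (samples where the part is non-zero), mean
    relative abundance, log-ratio variance (mean over the other parts j of
    var_s ln(x_j/x_cand)), its quartile rank among all candidates (1 = lowest
    variance quartile), and the Procrustes correlation between the sample
    configuration in the full pairwise-log-ratio geometry (principal
    coordinates) and in the candidate's ALR geometry.

    Occupancy is evaluated on the raw table; when zeros are present the
    geometry is computed on a zero-replaced copy, and candidates absent from
    any sample are disqualified rather than scored.
    """
    raw = table.values
    if (raw == 0).any():
        table = gbm_zero_replace(table)
    ra = relative_abundance(table)
    logs = np.log(table.values)
    n, j = logs.shape
    if candidate_ids is None:
        candidate_ids = list(table.feature_ids)

    # full pairwise log-ratio geometry == sqrt(J) * CLR geometry
    clr = logs - logs.mean(axis=1, keepdims=True)
    diff = clr[:, None, :] - clr[None, :, :]
    full_dist = np.sqrt(j) * np.sqrt((diff**2).sum(axis=2))
    full_coords = _pcoa_coordinates(full_dist)

    # log-ratio variance of every part against every candidate, via CLR variances:
    # var ln(x_a/x_b) = var(clr_a) + var(clr_b) - 2 cov(clr_a, clr_b)
    cov = np.cov(clr, rowvar=False)
    v = np.diag(cov)
    lrv_matrix = v[:, None] + v[None, :] - 2 * cov  # [a, b] = var ln(x_a/x_b)
    all_ids = list(table.feature_ids)
    mean_lrv_all = pd.Series(
        (lrv_matrix.sum(axis=0) - np.diag(lrv_matrix)) / max(j - 1, 1), index=all_ids
    )
    quartile_edges = mean_lrv_all.quantile([0.25, 0.5, 0.75]).to_numpy()

    rows = []
    for cand in candidate_ids:
        col = raw[:, table.feature_ids.get_loc(cand)]
        occupancy = int((col > 0).sum())
        if occupancy < n:
            rows.append(
                dict(candidate=cand, occupancy=occupancy, mean_ra=np.nan,
                     logratio_variance=np.nan, variance_quartile=np.nan,
                     procrustes_r=np.nan, qualified=False,
                     reason="absent from at least one sample")
            )
            continue
        mean_ra = float(ra.data[cand].mean())
        lrv = float(mean_lrv_all[cand])
        quartile = int(np.searchsorted(quartile_edges, lrv, side="right")) + 1
        alr = alr_transform(table, cand)
        pr = procrustes_correlation(full_coords, alr.data.to_numpy())
        rows.append(
            dict(candidate=cand, occupancy=occupancy, mean_ra=mean_ra,
                 logratio_variance=lrv, variance_quartile=quartile,
                 procrustes_r=pr, qualified=True, reason="")
        )
    return pd.DataFrame(rows).set_index("candidate")
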