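"""Pre-clustering/association transforms with an enforced transform ledger.

Order contract: ``log`` must precede everything else; batch adjustment must
precede contamination-score residualization; standardization is terminal for
association scans. Each operation returns a new :class:`AbundanceMatrix`
with the ledger extended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "IPSVector",
    "log_transform",
    "median_normalize",
    "batch_adjust_eb",
    "compute_ips",
    "residualize",
    "standardize_per_protein",
]

_TRANSFORMS = ("log", "median_norm", "batch_adjust", "ips_regressed", "standardized")


@dataclass
class AbundanceMatrix:
    """Samples x aptamers matrix plus the ordered ledger of applied transforms."""

    data: pd.DataFrame
    ledger: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate aptamer ids: {dup}")
        unknown = [t for t in self.ledger if t not in _TRANSFORMS]
        if unknown:
            raise ValueError(f"unknown ledger entries: {unknown}")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def aptamer_ids(self) -> pd.Index:
        return self.data.columns

    def _with(self, values: np.ndarray, step: str) -> "AbundanceMatrix":
        out = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return AbundanceMatrix(out, self.ledger + [step])

    def require(self, *steps: str) -> None:
        for step in steps:
            if step not in self.ledger:
                raise ValueError(f"transform {step!r} must be applied first")

    def forbid(self, *steps: str) -> None:
        for step in steps:
            if step in self.ledger:
                raise ValueError(f"transform {step!r} already applied")


@dataclass
class IPSVector:
    """Per-sample intracellular protein score (log scale)."""

    scores: pd.Series
    aptamer_ids: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("IPS contains non-finite values")


def log_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Element-wise natural log of strictly positive abundances."""
    matrix.forbid("log")
    vals = matrix.values
    bad = np.argwhere(~(vals > 0))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-positive value at sample {matrix.sample_ids[i]!r}, "
            f"aptamer {matrix.aptamer_ids[j]!r}: {vals[i, j]}"
        )
    return matrix._with(np.log(vals), "log")


def median_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Equalize per-sample medians: subtract each sample's median, add back
    the median of the per-sample medians."""
    matrix.require("log")
    if matrix.data.empty:
        raise ValueError("empty matrix")
    vals = matrix.values
    row_med = np.median(vals, axis=1)
    grand = np.median(row_med)
    return matrix._with(vals - row_med[:, None] + grand, "median_norm")


def _eb_iterate(
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    n_batch: int,
    z_batch: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative posterior-mode solution for one batch's location/scale
    parameters under normal / inverse-gamma moment-matched priors."""
    g_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1)
    v = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    if s2 <= 0:  # degenerate spread: no shrinkage possible on scale
        a_prior, b_prior = 2.0, v
    else:
        a_prior = (2 * s2 + v**2) / s2
        b_prior = (v * s2 + v**3) / s2
    g_star = gamma_hat.copy()
    d_star = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n_batch * t2 * gamma_hat + d_star * g_bar) / (n_batch * t2 + d_star)
        ss = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * ss + b_prior) / (n_batch / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_star).max(initial=0.0),
            np.abs(d_new - d_star).max(initial=0.0),
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


def batch_adjust_eb(matrix: AbundanceMatrix, batch_labels) -> AbundanceMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per aptamer: standardize against the pooled (batch-size-weighted) mean
    and pooled within-batch variance, estimate per-batch location and scale,
    shrink both toward cross-aptamer priors (normal / inverse-gamma,
    moments-matched), remove them and restore the original scale. The grand
    mean of every aptamer is preserved exactly by a final recentring.
    """
    matrix.require("log")
    matrix.forbid("ips_regressed", "standardized")
    batch = pd.Series(np.asarray(batch_labels), index=matrix.sample_ids)
    levels = batch.unique()
    if len(levels) == 1:
        warnings.warn("single batch: adjustment is a no-op", stacklevel=2)
        return matrix._with(matrix.values.copy(), "batch_adjust")
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with <2 samples: {small.index.tolist()}")

    vals = matrix.values.astype(float)
    n, p = vals.shape
    masks = {lv: (batch == lv).to_numpy() for lv in levels}
    batch_means = {lv: vals[m].mean(axis=0) for lv, m in masks.items()}
    alpha = sum(masks[lv].sum() / n * batch_means[lv] for lv in levels)
    pooled_var = (
        sum(((vals[masks[lv]] - batch_means[lv][None, :]) ** 2).sum(axis=0) for lv in levels)
        / n
    )
    pooled_sd = np.sqrt(pooled_var)
    if (pooled_sd <= 0).any():
        j = int(np.flatnonzero(pooled_sd <= 0)[0])
        raise ValueError(f"aptamer {matrix.aptamer_ids[j]!r} constant within batches")

    z = (vals - alpha[None, :]) / pooled_sd[None, :]
    adjusted = np.empty_like(z)
    for lv in levels:
        m = masks[lv]
        zb = z[m]
        gamma_hat = zb.mean(axis=0)
        delta_hat = zb.var(axis=0, ddof=1)
        g_star, d_star = _eb_iterate(gamma_hat, delta_hat, m.sum(), zb)
        adjusted[m] = (zb - g_star[None, :]) / np.sqrt(d_star)[None, :]
    out = adjusted * pooled_sd[None, :] + alpha[None, :]
    out += vals.mean(axis=0)[None, :] - out.mean(axis=0)[None, :]
    return matrix._with(out, "batch_adjust")


def compute_ips(matrix: AbundanceMatrix, annotation: pd.DataFrame) -> IPSVector:
    """Intracellular protein score: mean of per-aptamer-standardized log
    abundances over intracellular-flagged aptamers.

    Constant intracellular aptamers are dropped with a warning; an error is
    raised only if every intracellular aptamer is constant.
    """
    matrix.require("log")
    intra = annotation.loc[annotation["intracellular"].astype(bool), "aptamer_id"]
    intra = [a for a in intra if a in matrix.data.columns]
    if not intra:
        raise ValueError("no intracellular aptamers present in the matrix")
    sub = matrix.data[intra]
    sds = sub.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        if len(constant) == len(intra):
            raise ValueError("all intracellular aptamers are constant")
        warnings.warn(
            f"dropping {len(constant)} constant intracellular aptamers", stacklevel=2
        )
        sub = sub.drop(columns=constant)
        sds = sds.drop(constant)
    z = (sub - sub.mean()) / sds
    scores = z.mean(axis=1)
    scores.name = "ips"
    return IPSVector(scores, list(sub.columns))


def residualize(matrix: AbundanceMatrix, covariate) -> AbundanceMatrix:
    """Replace each aptamer by residuals of least squares on
    intercept + covariate. Idempotent; residuals are exactly uncorrelated
    with the covariate."""
    matrix.require("log")
    cov = np.asarray(covariate, dtype=float).ravel()
    if len(cov) != len(matrix.data):
        raise ValueError("covariate length must equal sample count")
    if not np.isfinite(cov).all():
        raise ValueError("covariate must be finite")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant")
    vals = matrix.values.astype(float)
    cov_c = cov - cov.mean()
    beta = cov_c @ (vals - vals.mean(axis=0)[None, :]) / (cov_c @ cov_c)
    resid = vals - vals.mean(axis=0)[None, :] - np.outer(cov_c, beta)
    step = "ips_regressed"
    ledger = matrix.ledger + ([step] if step not in matrix.ledger else [])
    out = pd.DataFrame(resid, index=matrix.data.index, columns=matrix.data.columns)
    return AbundanceMatrix(out, ledger)


def standardize_per_protein(matrix: AbundanceMatrix, grouping=None) -> AbundanceMatrix:
    """Within each group (or globally), center each aptamer and divide by
    its sample SD (denominator n-1)."""
    matrix.require("log")
    vals = matrix.values.astype(float)
    if grouping is None:
        groups = np.zeros(len(vals), dtype=int)
    else:
        groups = np.asarray(grouping)
        if len(groups) != len(vals):
            raise ValueError("grouping length must equal sample count")
    out = np.empty_like(vals)
    for g in np.unique(groups):
        m = groups == g
        sub = vals[m]
        sd = sub.std(axis=0, ddof=1)
        const = np.flatnonzero(sd == 0)
        if len(const):
            names = [matrix.aptamer_ids[j] for j in const]
            raise ValueError(f"constant aptamers within group {g!r}: {names}")
        out[m] = (sub - sub.mean(axis=0)[None, :]) / sd[None, :]
    step = "standardized"
    ledger = matrix.ledger + ([step] if step not in matrix.ledger else [])
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return AbundanceMatrix(df, ledger)
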