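"""ComBat empirical-Bayes batch-effect harmonization.

Parametric ComBat for lesion feature tables acquired at multiple centers:
each feature is standardized against its pooled mean/variance, per-batch
location (gamma) and scale (delta^2) effects are estimated, shrunk toward a
normal / inverse-gamma prior whose hyperparameters come from the spread of
the per-feature estimates (method of moments), and the data are adjusted

    x* = sigma_pooled * (z - gamma*) / delta* + alpha_hat (+ covariate fit).

The (gamma*, delta*^2) pair is solved jointly by fixed-point iteration to a
relative tolerance of 1e-6.  Zero-variance features pass through unchanged
with a warning flag.  An optional outcome covariate can be protected; by
default none is (but note that fitting on all lesions before a train/test
split leaks test information — the modeling protocol fits on the training
split only unless explicitly told otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import feature_columns


@dataclass
class CombatModel:
    feature_names: list[str]
    batch_levels: list[str]
    alpha_hat: np.ndarray          # (n_features,) grand mean
    beta_hat: np.ndarray           # (n_cov, n_features) covariate coefficients
    var_pooled: np.ndarray         # (n_features,)
    gamma_star: np.ndarray         # (n_batches, n_features) EB locations
    delta_star_sq: np.ndarray      # (n_batches, n_features) EB scales
    constant_features: list[str] = field(default_factory=list)
    n_iterations: list[int] = field(default_factory=list)
    max_delta: float = 0.0
    covariate_col: str | None = None

    def digest(self) -> bytes:
        """Byte-exact fingerprint of the fitted parameters (leakage tests)."""
        parts = [",".join(self.feature_names).encode(), ",".join(self.batch_levels).encode()]
        for arr in (self.alpha_hat, self.beta_hat, self.var_pooled, self.gamma_star, self.delta_star_sq):
            parts.append(np.ascontiguousarray(arr).tobytes())
        return b"|".join(parts)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _it_solve(sdat: np.ndarray, g_hat, d_hat, g_bar, t2, a, b, tol=1e-6, max_iter=500):
    """Joint EB fixed-point update for one batch (all features at once)."""
    n = sdat.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    it = 0
    while change > tol and it < max_iter:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        it += 1
    return g_old, d_old, it


def combat_fit(
    table: pd.DataFrame,
    batch_col: str = "center_id",
    covariate_col: str | None = None,
    features: list[str] | None = None,
) -> CombatModel:
    """Fit parametric ComBat location/scale parameters on a feature table."""
    feats = features if features is not None else feature_columns(table)
    batches = table[batch_col].astype(str)
    levels = sorted(batches.unique())
    if len(levels) < 2:
        raise ValueError("ComBat needs at least 2 batches")
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every batch needs >= 2 samples, got {counts.to_dict()}")

    X = table[feats].to_numpy(dtype=float)  # (n_samples, n_features)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    n, p = X.shape

    variances = X.var(axis=0)
    const = variances <= 1e-30
    constant_features = [f for f, c in zip(feats, const) if c]
    if constant_features:
        warnings.warn(
            f"zero-variance feature(s) passed through unchanged: {constant_features}"
        )
    work = X[:, ~const]

    batch_idx = [np.flatnonzero((batches == lv).to_numpy()) for lv in levels]
    n_b = np.array([len(ix) for ix in batch_idx], dtype=float)

    # covariate design (outcome protection), centered batch-wise via OLS
    if covariate_col is not None:
        cov = pd.get_dummies(table[covariate_col], drop_first=True).to_numpy(dtype=float)
    else:
        cov = np.empty((n, 0))
    design = np.column_stack(
        [np.isin(np.arange(n), ix).astype(float) for ix in batch_idx] + [cov]
    )
    B_hat, *_ = np.linalg.lstsq(design, work, rcond=None)
    gamma_hat_ols = B_hat[: len(levels)]            # per-batch means
    beta_hat = B_hat[len(levels):]

    alpha_hat = (n_b / n) @ gamma_hat_ols           # weighted grand mean
    fitted = design @ B_hat
    var_pooled = ((work - fitted) ** 2).mean(axis=0)
    var_pooled = np.maximum(var_pooled, 1e-30)

    stand = (work - alpha_hat[None, :] - cov @ beta_hat) / np.sqrt(var_pooled)[None, :]

    gamma_star = np.zeros((len(levels), stand.shape[1]))
    delta_star_sq = np.ones_like(gamma_star)
    iterations: list[int] = []
    max_delta = 0.0
    for bi, ix in enumerate(batch_idx):
        sdat = stand[ix]
        g_hat = sdat.mean(axis=0)
        d_hat = sdat.var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        if s2 <= 0 or t2 <= 0:
            # too few features to estimate priors: no shrinkage
            g_star, d_star, it = g_hat, np.maximum(d_hat, 1e-12), 0
        else:
            a = (2.0 * s2 + m**2) / s2
            b = (m * s2 + m**3) / s2
            g_star, d_star, it = _it_solve(sdat, g_hat, d_hat, g_bar, t2, a, b)
        gamma_star[bi] = g_star
        delta_star_sq[bi] = np.maximum(d_star, 1e-12)
        iterations.append(it)
        max_delta = max(max_delta, float(np.max(np.abs(g_star - g_hat))))

    # re-embed constant features with neutral parameters
    def expand(arr, fill):
        full = np.full(arr.shape[:-1] + (p,), fill, dtype=float)
        full[..., ~const] = arr
        return full

    model = CombatModel(
        feature_names=list(feats),
        batch_levels=list(levels),
        alpha_hat=expand(alpha_hat, 0.0),
        beta_hat=expand(beta_hat, 0.0) if beta_hat.size else np.zeros((cov.shape[1], p)),
        var_pooled=expand(var_pooled, 1.0),
        gamma_star=expand(gamma_star, 0.0),
        delta_star_sq=expand(delta_star_sq, 1.0),
        constant_features=constant_features,
        n_iterations=iterations,
        max_delta=max_delta,
        covariate_col=covariate_col,
    )
    # constant features: make adjustment the identity (alpha = value itself)
    if constant_features:
        const_ix = np.array([feats.index(f) for f in constant_features])
        model.alpha_hat[const_ix] = X[:, const_ix].mean(axis=0)
    return model


def combat_apply(model: CombatModel, table: pd.DataFrame, batch_col: str = "center_id") -> pd.DataFrame:
    """Adjust a feature table with fitted ComBat parameters.

    Rows keep their order; metadata columns are untouched.  Batch labels not
    seen at fit time are a hard error.
    """
    batches = table[batch_col].astype(str)
    unseen = sorted(set(batches) - set(model.batch_levels))
    if unseen:
        raise ValueError(f"batch label(s) not in fitted model: {unseen}")
    X = table[model.feature_names].to_numpy(dtype=float)
    if model.covariate_col is not None:
        cov = pd.get_dummies(table[model.covariate_col], drop_first=True).to_numpy(dtype=float)
    else:
        cov = np.empty((len(table), 0))
    cov_term = cov @ model.beta_hat if model.beta_hat.size else 0.0

    sd = np.sqrt(model.var_pooled)[None, :]
    z = (X - model.alpha_hat[None, :] - cov_term) / sd
    out = np.empty_like(X)
    for bi, lv in enumerate(model.batch_levels):
        ix = np.flatnonzero((batches == lv).to_numpy())
        if ix.size == 0:
            continue
        adj = (z[ix] - model.gamma_star[bi][None, :]) / np.sqrt(model.delta_star_sq[bi])[None, :]
        out[ix] = adj * sd + model.alpha_hat[None, :] + (cov_term[ix] if np.ndim(cov_term) else 0.0)
    const_ix = [model.feature_names.index(f) for f in model.constant_features]
    if const_ix:
        out[:, const_ix] = X[:, const_ix]

    result = table.copy()
    result[model.feature_names] = out
    return result


def combat_harmonize(
    table: pd.DataFrame,
    batch_col: str = "center_id",
    covariate_col: str | None = None,
) -> pd.DataFrame:
    """Fit-and-apply convenience wrapper (single-table use)."""
    model = combat_fit(table, batch_col=batch_col, covariate_col=covariate_col)
    return combat_apply(model, table, batch_col=batch_col)
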