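"""Univariate statistics: Spearman tiers, ROC/AUC with DeLong variance,
paired DeLong AUC comparison, and Benjamini-Hochberg FDR.

AUC is the Mann-Whitney pair statistic (ties count one half); its variance
and the covariance between two correlated AUCs come from DeLong's placement
values.  The four-arm univariate screen (static/DTP x with/without ComBat)
reports per-feature AUC/p/q and counts features whose AUC significantly
improved, decreased or did not change across arms, with BH q < 0.05 as the
significance rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import feature_columns

SPEARMAN_TIERS = (("low", 0.0, 0.5), ("moderate", 0.5, 0.7), ("high", 0.7, np.inf))


# ---------------------------------------------------------------- Spearman

@dataclass
class CorrelationReport:
    """Paired static-vs-DTP Spearman correlations with tier assignment.

    Tiers partition the features by |rho|: low < 0.5 <= moderate < 0.7 <= high
    (boundaries are assigned upward, matching the published cutpoints which
    overlap at exactly 0.5 / 0.7).
    """

    table: pd.DataFrame  # feature, rho, p, tier

    def tier_counts(self) -> dict[str, int]:
        return self.table["tier"].value_counts().to_dict()

    def features_in_tier(self, tier: str) -> list[str]:
        return self.table.loc[self.table["tier"] == tier, "feature"].tolist()


def _tier(rho: float) -> str:
    if np.isnan(rho):
        return "undefined"
    a = abs(rho)
    if a < 0.5:
        return "low"
    if a < 0.7:
        return "moderate"
    return "high"


def spearman_matrix(static: pd.DataFrame, dtp: pd.DataFrame) -> CorrelationReport:
    """Per-feature Spearman rho between matched static and DTP columns.

    Rows must describe the same lesions in the same order; constant features
    yield an undefined (NaN) correlation and are flagged.
    """
    feats = feature_columns(static)
    if feats != feature_columns(dtp):
        raise ValueError("static and DTP tables must share the feature columns")
    if len(static) != len(dtp) or len(static) < 3:
        raise ValueError("need matched lesion rows, n >= 3")
    rows = []
    for f in feats:
        x = static[f].to_numpy(float)
        y = dtp[f].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = sps.spearmanr(x, y)
        rows.append({"feature": f, "rho": rho, "p": p, "tier": _tier(rho)})
    return CorrelationReport(table=pd.DataFrame(rows))


# ------------------------------------------------------------------ DeLong

def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values via midranks (ties count one half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_scores)          # midranks
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    v10 = (ranks[:m] - rank_pos) / n          # P(neg < pos) per positive
    v01 = 1.0 - (ranks[m:] - rank_neg) / m    # per negative
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) of one score vector against binary labels."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    auc, v10, v01 = _placements(scores, labels)
    m, n = int((labels == 1).sum()), int((labels == 0).sum())
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    return auc, float(var)


def auc_p_vs_half(scores, labels) -> tuple[float, float]:
    """AUC and two-sided normal p-value against the no-discrimination AUC 0.5."""
    auc, var = roc_auc(scores, labels)
    if var <= 0:
        return auc, 0.0 if auc != 0.5 else 1.0
    z = (auc - 0.5) / np.sqrt(var)
    return auc, float(2.0 * sps.norm.sf(abs(z)))


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong comparison of two correlated AUCs on the same lesions.

    Returns (delta_auc = AUC_a - AUC_b, z, two-sided p).  Identical score
    vectors give delta 0, p = 1; a zero standard error with nonzero delta is
    a degenerate-tie error.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("score vectors and labels must describe the same lesions")
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    delta = auc_a - auc_b
    m, n = len(v10_a), len(v01_a)
    var = 0.0
    if m > 1:
        s10 = np.cov(v10_a, v10_b, ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(v01_a, v01_b, ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    if var <= 0:
        if abs(delta) < 1e-12:
            return 0.0, 0.0, 1.0
        raise ValueError(
            "zero DeLong standard error with nonzero AUC difference "
            "(exact-tie degenerate input)"
        )
    z = delta / np.sqrt(var)
    return float(delta), float(z), float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------- BH

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j,
    mapped back to the input order and clipped to [0, 1]."""
    p = np.asarray(pvals, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1D sequence")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ------------------------------------------------------------------ screen

ARMS = ("static_raw", "static_combat", "dtp_raw", "dtp_combat")
COMPARISONS = (
    # (name, arm_b "after/second", arm_a "before/first")
    ("H_vs_NonH_DTP", "dtp_combat", "dtp_raw"),
    ("H_vs_NonH_Static", "static_combat", "static_raw"),
    ("H_Static_vs_H_DTP", "static_combat", "dtp_combat"),
    ("NonH_Static_vs_NonH_DTP", "static_raw", "dtp_raw"),
)


@dataclass
class UnivariateScreen:
    per_feature: pd.DataFrame          # feature, arm, auc, auc_oriented, p, q
    comparisons: pd.DataFrame          # comparison, feature, delta_auc, p, q, verdict
    counts: pd.DataFrame               # comparison x {decreased, improved, no_difference}


def univariate_screen(
    tables: dict[str, pd.DataFrame],
    labels,
    alpha: float = 0.05,
) -> UnivariateScreen:
    """Per-feature ROC screen over the four arms plus paired DeLong counts.

    ``tables`` maps each arm name in :data:`ARMS` to a feature table whose
    rows are the same lesions in the same order; ``labels`` is the shared
    binary outcome.  Significance of the AUC comparisons uses BH q < alpha
    on the paired DeLong p-values within each comparison (65 features).
    """
    labels = np.asarray(labels, int)
    missing = [a for a in ARMS if a not in tables]
    if missing:
        raise ValueError(f"missing arm table(s): {missing}")
    feats = feature_columns(tables[ARMS[0]])
    for a in ARMS:
        if feature_columns(tables[a]) != feats or len(tables[a]) != len(labels):
            raise ValueError("all four arms must align on features and lesions")

    rows = []
    for arm in ARMS:
        pvals = []
        for f in feats:
            auc, p = auc_p_vs_half(tables[arm][f], labels)
            rows.append({"feature": f, "arm": arm, "auc": auc,
                         "auc_oriented": max(auc, 1.0 - auc), "p": p})
            pvals.append(p)
        qs = bh_fdr(pvals)
        for r, q in zip(rows[-len(feats):], qs):
            r["q"] = float(q)
    per_feature = pd.DataFrame(rows)

    comp_rows = []
    count_rows = []
    for name, arm_b, arm_a in COMPARISONS:
        deltas, ps = [], []
        for f in feats:
            delta, _, p = delong_paired_test(tables[arm_b][f], tables[arm_a][f], labels)
            deltas.append(delta)
            ps.append(p)
        qs = bh_fdr(ps)
        verdicts = []
        for f, delta, p, q in zip(feats, deltas, ps, qs):
            if q < alpha and delta > 0:
                verdict = "improved"
            elif q < alpha and delta < 0:
                verdict = "decreased"
            else:
                verdict = "no_difference"
            verdicts.append(verdict)
            comp_rows.append({"comparison": name, "feature": f, "delta_auc": delta,
                              "p": p, "q": float(q), "verdict": verdict})
        count_rows.append({
            "comparison": name,
            "decreased": verdicts.count("decreased"),
            "improved": verdicts.count("improved"),
            "no_difference": verdicts.count("no_difference"),
        })
    return UnivariateScreen(
        per_feature=per_feature,
        comparisons=pd.DataFrame(comp_rows),
        counts=pd.DataFrame(count_rows).set_index("comparison"),
    )
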