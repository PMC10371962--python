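"""Multivariate response prediction: the six model variants.

Variants cross {with, without} ComBat harmonization with {DTP, Static,
DTP+Static} feature sets.  One evaluation repeat is:

1. patient-grouped 80/20 train/test split (lesion-level behind a flag);
2. optional ComBat fit on the training split (or, paper-faithfully but
   leakily, on all lesions with ``combat_mode="all"``);
3. mRMR top-10 selection on the training split — the combined variant takes
   the top 10 of each set, pools the 20 and re-runs mRMR down to 10;
4. random search over a gradient-boosting hyperparameter grid, each
   candidate scored by mean validation AUC over B bootstrap resamples of an
   inner 80/20 training/validation split;
5. the winning configuration refit on the full training split and scored on
   the untouched test split (AUC threshold-free; ACC/SEN/SPE at probability
   0.5, positive class = responding).

The repeat loop (100 by default) yields per-repeat AUC/ACC/SEN/SPE; the
summary reports mean +/- SD and a percentile 95% CI, and variants are
compared metric-wise with two-sided Mann-Whitney tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from xgboost import XGBClassifier

from .config import MODEL_VARIANTS, PipelineConfig
from .harmonization import combat_apply, combat_fit
from .mrmr import mrmr_select
from .stats import roc_auc
from .tables import feature_columns

# random-search space for the gradient-boosted trees; deliberately compact
# (small cohorts, shallow trees) and declared here so runs are reproducible
DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "max_depth": [2, 3, 4],
    "learning_rate": [0.05, 0.1, 0.2, 0.3],
    "n_estimators": [30, 60, 100],
    "subsample": [0.7, 0.85, 1.0],
    "colsample_bytree": [0.7, 1.0],
}


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """AUC (threshold-free) plus ACC/SEN/SPE at a probability threshold.

    Sensitivity is TP/(TP+FN) for the positive (responding = 1) class.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the evaluation set")
    auc, _ = roc_auc(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return {
        "auc": auc,
        "acc": (tp + tn) / len(labels),
        "sen": tp / (tp + fn),
        "spe": tn / (tn + fp),
    }


@dataclass
class RepeatArtifacts:
    """Training-time artifacts of one repeat (for leakage auditing)."""

    selected_features: tuple[str, ...]
    best_params: dict
    combat_digest: bytes | None
    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]


@dataclass
class EvalReport:
    variant: str
    per_repeat: pd.DataFrame                 # repeat, auc, acc, sen, spe
    artifacts: list[RepeatArtifacts] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in ("auc", "acc", "sen", "spe"):
            vals = self.per_repeat[metric].to_numpy()
            lo, hi = np.percentile(vals, [2.5, 97.5])
            rows.append({
                "metric": metric, "mean": vals.mean(), "std": vals.std(ddof=1),
                "ci_lo": lo, "ci_hi": hi,
            })
        return pd.DataFrame(rows).set_index("metric")


def _variant_parts(variant: str) -> tuple[bool, str]:
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    harmonized, feature_set = variant.split("_", 1)
    return harmonized == "H", feature_set


def _grouped_split(table, rng, frac_test, level, max_tries=200):
    """Indices (train, test) with both outcome classes on both sides."""
    group_col = "patient_id" if level == "patient" else "lesion_id"
    groups = table[group_col].astype(str).to_numpy()
    uniq = np.unique(groups)
    outcomes = table["outcome"].to_numpy(int)
    centers = table["center_id"].astype(str).to_numpy()
    for _ in range(max_tries):
        perm = rng.permutation(uniq)
        n_test = max(1, int(round(len(uniq) * frac_test)))
        test_groups = set(perm[:n_test])
        test_ix = np.flatnonzero([g in test_groups for g in groups])
        train_ix = np.flatnonzero([g not in test_groups for g in groups])
        if len(np.unique(outcomes[train_ix])) < 2 or len(np.unique(outcomes[test_ix])) < 2:
            continue
        # ComBat on the training split needs >= 2 lesions per center
        counts = pd.Series(centers[train_ix]).value_counts()
        if set(counts.index) != set(np.unique(centers)) or (counts < 2).any():
            continue
        return train_ix, test_ix
    raise ValueError("could not find a split with both classes on both sides")


def _sample_params(rng, space) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in sorted(space.items())}


def _fit_xgb(params, X, y, seed) -> XGBClassifier:
    clf = XGBClassifier(
        **params,
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed),
        verbosity=0,
    )
    clf.fit(X, y)
    return clf


def _select_features(train: pd.DataFrame, labels, feature_set: str, k: int) -> list[str]:
    feats = feature_columns(train)
    static = [f for f in feats if f.startswith("static_")]
    dtp = [f for f in feats if f.startswith("dtp_")]
    if feature_set == "Static":
        return mrmr_select(train, labels, k=k, features=static).selected
    if feature_set == "DTP":
        return mrmr_select(train, labels, k=k, features=dtp).selected
    top_s = mrmr_select(train, labels, k=k, features=static).selected
    top_d = mrmr_select(train, labels, k=k, features=dtp).selected
    pooled = top_d + top_s  # canonical pooling order: DTP block then static
    return mrmr_select(train, labels, k=k, features=pooled).selected


def run_single_repeat(
    table: pd.DataFrame,
    variant: str,
    cfg: PipelineConfig,
    seed_seq: np.random.SeedSequence,
    search_space: dict | None = None,
) -> tuple[dict[str, float], RepeatArtifacts]:
    """One 80/20 evaluation repeat; returns (metrics, training artifacts)."""
    harmonized, feature_set = _variant_parts(variant)
    space = search_space or DEFAULT_SEARCH_SPACE
    rng = np.random.default_rng(seed_seq)
    fit_seed = int(seed_seq.generate_state(1)[0] % (2**31 - 1))

    train_ix, test_ix = _grouped_split(table, rng, 0.2, cfg.split_level)
    train = table.iloc[train_ix].reset_index(drop=True)
    test = table.iloc[test_ix].reset_index(drop=True)

    combat_digest = None
    if harmonized:
        fit_on = table.reset_index(drop=True) if cfg.combat_mode == "all" else train
        model = combat_fit(fit_on, batch_col="center_id")
        train = combat_apply(model, train)
        test = combat_apply(model, test)
        combat_digest = model.digest()

    y_train = train["outcome"].to_numpy(int)
    y_test = test["outcome"].to_numpy(int)
    selected = _select_features(train, y_train, feature_set, cfg.mrmr_k)

    # inner 80/20 train/validation split of the training lesions
    inner_train_ix, val_ix = _grouped_split(train, rng, 0.2, cfg.split_level)
    X_inner = train.iloc[inner_train_ix][selected].to_numpy(float)
    y_inner = y_train[inner_train_ix]
    X_val = train.iloc[val_ix][selected].to_numpy(float)
    y_val = y_train[val_ix]

    best_params, best_score = None, -np.inf
    for _ in range(cfg.n_search):
        params = _sample_params(rng, space)
        aucs = []
        for _ in range(cfg.n_boot):
            for _ in range(50):  # redraw bootstrap until both classes present
                boot = rng.integers(len(y_inner), size=len(y_inner))
                if len(np.unique(y_inner[boot])) == 2:
                    break
            clf = _fit_xgb(params, X_inner[boot], y_inner[boot], fit_seed)
            auc, _ = roc_auc(clf.predict_proba(X_val)[:, 1], y_val)
            aucs.append(auc)
        score = float(np.mean(aucs))
        if score > best_score:
            best_params, best_score = params, score

    final = _fit_xgb(best_params, train[selected].to_numpy(float), y_train, fit_seed)
    metrics = compute_metrics(final.predict_proba(test[selected].to_numpy(float))[:, 1], y_test)
    artifacts = RepeatArtifacts(
        selected_features=tuple(selected),
        best_params=dict(best_params),
        combat_digest=combat_digest,
        train_patients=tuple(sorted(train["patient_id"].astype(str).unique())),
        test_patients=tuple(sorted(test["patient_id"].astype(str).unique())),
    )
    return metrics, artifacts


def train_eval_protocol(
    table: pd.DataFrame,
    variant: str,
    cfg: PipelineConfig,
    seed: int | None = None,
    search_space: dict | None = None,
) -> EvalReport:
    """Repeated 80/20 evaluation of one model variant.

    ``table`` carries the metadata columns plus ``static_``/``dtp_``-prefixed
    feature columns; ``outcome`` is 1 = responding.  Fully reproducible from
    the master seed.
    """
    if table["patient_id"].nunique() < 5:
        raise ValueError("need at least 5 patients for the split protocol")
    master = cfg.seed if seed is None else seed
    seqs = np.random.SeedSequence(master).spawn(cfg.n_repeats)
    rows, artifacts = [], []
    for r, seq in enumerate(seqs):
        metrics, art = run_single_repeat(table, variant, cfg, seq, search_space)
        rows.append({"repeat": r, **metrics})
        artifacts.append(art)
    return EvalReport(variant=variant, per_repeat=pd.DataFrame(rows), artifacts=artifacts)


def mann_whitney_compare(
    reports: dict[str, EvalReport], metric: str = "auc"
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney p-matrix across model variants.

    Exact null distribution for small samples without ties, normal
    approximation with tie correction otherwise.  A variant against itself
    (identical samples) reports p = 1.
    """
    names = list(reports)
    n_reps = {name: len(reports[name].per_repeat) for name in names}
    if len(set(n_reps.values())) > 1:
        raise ValueError(f"mismatched repeat counts: {n_reps}")
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            x = reports[a].per_repeat[metric].to_numpy()
            y = reports[b].per_repeat[metric].to_numpy()
            if np.array_equal(x, y):
                p = 1.0
            else:
                ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
                method = "exact" if (max(len(x), len(y)) <= 15 and not ties) else "asymptotic"
                p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
            mat.loc[a, b] = mat.loc[b, a] = p
    return mat
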