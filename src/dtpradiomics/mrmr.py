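"""Minimum-redundancy maximum-relevance (mRMR) feature selection.

Greedy mutual-information difference (MID) scheme: the first feature
maximizes I(f; y); each subsequent feature maximizes

    I(f; y) - (1/|S|) * sum_{s in S} I(f; s)

over the not-yet-selected features.  Continuous features are discretized to
three states at mean +/- one standard deviation before MI estimation (the
convention of the originating method); binary labels are used as-is.  Ties
break toward the earlier feature in the table's canonical column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score


@dataclass
class MrmrSelection:
    selected: list[str]                 # ordered, length min(k, n_features)
    relevance: dict[str, float]         # I(f; y) for every candidate feature
    step_scores: list[float]            # greedy objective at each pick


def discretize_three_state(x: np.ndarray) -> np.ndarray:
    """Map a continuous vector to {0, 1, 2} at mu - sigma and mu + sigma."""
    x = np.asarray(x, float)
    mu, sigma = x.mean(), x.std()
    out = np.ones(x.shape, dtype=int)
    out[x < mu - sigma] = 0
    out[x > mu + sigma] = 2
    return out


def mrmr_select(
    table: pd.DataFrame,
    labels,
    k: int = 10,
    features: list[str] | None = None,
) -> MrmrSelection:
    """Greedy MID selection of ``k`` features against binary labels."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if features is None:
        from .tables import feature_columns

        features = feature_columns(table)
    if k > len(features):
        raise ValueError(f"k={k} exceeds the {len(features)} available features")
    y = np.asarray(labels).ravel()
    if len(y) != len(table):
        raise ValueError("labels must align with table rows")

    disc = {f: discretize_three_state(table[f].to_numpy(float)) for f in features}
    relevance = {f: float(mutual_info_score(disc[f], y)) for f in features}

    selected: list[str] = []
    step_scores: list[float] = []
    remaining = list(features)
    mi_cache: dict[tuple[str, str], float] = {}

    def mi_ff(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = float(mutual_info_score(disc[a], disc[b]))
        return mi_cache[key]

    tol = 1e-9  # scores tied to float noise resolve to canonical order
    for _ in range(k):
        best_f, best_score = None, -np.inf
        for f in remaining:  # canonical order => first max wins ties
            if selected:
                redundancy = np.mean([mi_ff(f, s) for s in selected])
            else:
                redundancy = 0.0
            score = relevance[f] - redundancy
            if score > best_score + tol:
                best_f, best_score = f, score
        selected.append(best_f)
        step_scores.append(float(best_score))
        remaining.remove(best_f)
    return MrmrSelection(selected=selected, relevance=relevance, step_scores=step_scores)
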