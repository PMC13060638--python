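"""Tissue-conserved methylation-marker discovery on beta-value matrices.

Candidate CpG sites that distinguish colorectal tissue from all other tissues
(regardless of tumour status) are discovered from Illumina 450K-style beta
matrices by a deliberately simple, reproducible filter:

1. drop every probe with at least one missing value;
2. compute mean beta per probe within the COLON and REST sample groups;
3. keep colon-hypermethylated probes (mean COLON beta > 0.75 and mean REST
   beta < 0.25) and colon-hypomethylated probes (the reverse), strict
   inequalities;
4. rank the surviving differentially methylated CpGs (DMCs) with two
   independent feature rankers and merge the two top-k lists as a union.

The rankers sit behind a minimal contract — ``ranker(beta, labels, seed) ->
ordered probe list`` — so ML-based rankers (recursive feature elimination,
random-forest importance) plug in interchangeably with the dependency-free
default (a two-group separation score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ddpcr import ValidationError

__all__ = [
    "BetaMatrix",
    "filter_missing",
    "select_dmc",
    "separation_ranker",
    "rfe_ranker",
    "random_forest_ranker",
    "rank_and_merge",
]

COLON, REST = "COLON", "REST"

Ranker = Callable[[pd.DataFrame, pd.Series, int], list[str]]


@dataclass(frozen=True)
class BetaMatrix:
    """Probes × samples beta values plus a COLON/REST group label per sample."""

    beta: pd.DataFrame  # index: probe ids; columns: sample ids
    groups: pd.Series   # index: sample ids; values: COLON or REST

    def __post_init__(self) -> None:
        if not set(self.beta.columns) <= set(self.groups.index):
            raise ValidationError("every sample column needs a group label")
        vals = set(self.groups.loc[list(self.beta.columns)].unique())
        if not vals <= {COLON, REST}:
            raise ValidationError(f"groups must be COLON/REST, got {sorted(vals)}")
        if COLON not in vals or REST not in vals:
            raise ValidationError("both COLON and REST groups must be non-empty")
        arr = self.beta.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValidationError("beta values must lie in [0, 1]")

    @property
    def colon_samples(self) -> list[str]:
        g = self.groups.loc[list(self.beta.columns)]
        return list(g.index[g == COLON])

    @property
    def rest_samples(self) -> list[str]:
        g = self.groups.loc[list(self.beta.columns)]
        return list(g.index[g == REST])


def filter_missing(matrix: BetaMatrix) -> BetaMatrix:
    """Drop every probe with one or more missing beta values."""
    kept = matrix.beta.dropna(axis=0, how="any")
    if kept.empty:
        warnings.warn("all probes had missing values; result is empty", stacklevel=2)
    return BetaMatrix(beta=kept, groups=matrix.groups)


def select_dmc(matrix: BetaMatrix, hyper_colon: float = 0.75,
               hyper_rest: float = 0.25) -> pd.DataFrame:
    """Differentially methylated CpGs by opposing group-mean thresholds.

    Returns one row per probe with ``mean_colon``, ``mean_rest``,
    ``direction`` (hyper/hypo/none) and ``selected``. Hypermethylated:
    mean COLON beta > ``hyper_colon`` and mean REST beta < ``hyper_rest``;
    hypomethylated: the mirrored condition. Inequalities are strict, so a
    probe sitting exactly on a threshold is not selected.
    """
    if not (0 < hyper_rest < hyper_colon < 1):
        raise ValidationError("need 0 < hyper_rest < hyper_colon < 1")
    colon, rest = matrix.colon_samples, matrix.rest_samples
    if not colon or not rest:
        raise ValidationError("both groups must contain samples")

    mean_colon = matrix.beta[colon].mean(axis=1)
    mean_rest = matrix.beta[rest].mean(axis=1)
    hyper = (mean_colon > hyper_colon) & (mean_rest < hyper_rest)
    hypo = (mean_colon < hyper_rest) & (mean_rest > hyper_colon)

    direction = pd.Series("none", index=matrix.beta.index)
    direction[hyper] = "hyper"
    direction[hypo] = "hypo"
    return pd.DataFrame({
        "mean_colon": mean_colon,
        "mean_rest": mean_rest,
        "direction": direction,
        "selected": hyper | hypo,
    })


def separation_ranker(beta: pd.DataFrame, labels: pd.Series, seed: int = 0) -> list[str]:
    """Default dependency-free ranker: |group mean difference| / pooled SD.

    Deterministic (the seed is accepted for contract uniformity only); ties
    broken by probe id for reproducibility.
    """
    colon = beta.loc[:, labels.loc[list(beta.columns)] == COLON]
    rest = beta.loc[:, labels.loc[list(beta.columns)] == REST]
    diff = (colon.mean(axis=1) - rest.mean(axis=1)).abs()
    n1, n2 = colon.shape[1], rest.shape[1]
    pooled_var = ((n1 - 1) * colon.var(axis=1, ddof=1) +
                  (n2 - 1) * rest.var(axis=1, ddof=1)) / max(n1 + n2 - 2, 1)
    score = diff / np.sqrt(pooled_var.clip(lower=1e-12))
    order = score.sort_values(ascending=False, kind="mergesort")
    return list(order.index)


def _cv_labels(labels: pd.Series, columns: Sequence[str]) -> np.ndarray:
    return (labels.loc[list(columns)] == COLON).to_numpy(dtype=int)


def rfe_ranker(beta: pd.DataFrame, labels: pd.Series, seed: int = 0,
               n_splits: int = 10, n_repeats: int = 5) -> list[str]:
    """Recursive feature elimination (linear SVM), rank averaged over
    repeated stratified cross-validation folds."""
    from sklearn.feature_selection import RFE
    from sklearn.model_selection import RepeatedStratifiedKFold
    from sklearn.svm import LinearSVC

    X = beta.to_numpy(dtype=float).T
    y = _cv_labels(labels, beta.columns)
    n_splits = min(n_splits, int(np.bincount(y).min()))
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                 random_state=seed)
    ranks = np.zeros(X.shape[1])
    for train, _ in cv.split(X, y):
        est = LinearSVC(dual=False, max_iter=5000)
        rfe = RFE(est, n_features_to_select=1, step=0.25)
        rfe.fit(X[train], y[train])
        ranks += rfe.ranking_
    order = np.lexsort((np.arange(len(ranks)), ranks))
    return [beta.index[i] for i in order]


def random_forest_ranker(beta: pd.DataFrame, labels: pd.Series, seed: int = 0,
                         n_splits: int = 10, n_repeats: int = 10) -> list[str]:
    """Random-forest importance ranker, averaged over repeated stratified
    cross-validation folds."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import RepeatedStratifiedKFold

    X = beta.to_numpy(dtype=float).T
    y = _cv_labels(labels, beta.columns)
    n_splits = min(n_splits, int(np.bincount(y).min()))
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                 random_state=seed)
    importance = np.zeros(X.shape[1])
    for i, (train, _) in enumerate(cv.split(X, y)):
        rf = RandomForestClassifier(n_estimators=100, random_state=seed + i)
        rf.fit(X[train], y[train])
        importance += rf.feature_importances_
    order = np.lexsort((np.arange(len(importance)), -importance))
    return [beta.index[i] for i in order]


def rank_and_merge(matrix: BetaMatrix, ranker_a: Ranker | None = None,
                   ranker_b: Ranker | None = None, k: int = 10,
                   seed: int = 0) -> list[str]:
    """Union of the two rankers' top-k probes over the DMC-restricted matrix.

    The result is ordered (ranker A's picks first, then B's novel picks) and
    has at most 2k probes. With fewer than k probes available, all are
    returned with a warning.
    """
    ranker_a = ranker_a or separation_ranker
    ranker_b = ranker_b or separation_ranker
    probes = list(matrix.beta.index)
    if len(probes) < k:
        warnings.warn(f"only {len(probes)} DMCs available for top-{k} merge; "
                      "returning all", stacklevel=2)
        return probes
    top_a = ranker_a(matrix.beta, matrix.groups, seed)[:k]
    top_b = ranker_b(matrix.beta, matrix.groups, seed)[:k]
    merged = list(top_a)
    for p in top_b:
        if p not in merged:
            merged.append(p)
    return merged
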