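"""Informative k-spaced pair selection: mRMR ranking + sequential forward search.

The full CKSAAP space holds 2000 attributes; most are noise for any one PTM.
Selection proceeds in two stages:

1. **mRMR** (minimum redundancy - maximum relevance) greedily ranks
   attributes.  The first attribute maximizes the mutual information
   I(f, c) with the class label; each subsequent pick maximizes

       score_j = I(f_j, c) - (1/m) * sum_{i in selected} I(f_i, f_j)

   i.e. relevance penalized by the mean mutual information with the m
   already-selected attributes.

2. **SFS** (sequential forward selection) walks the ranking in order,
   growing a prefix one attribute at a time; each prefix is scored by
   stratified k-fold cross-validated MCC of the downstream SVM, and the
   best-scoring prefix (ties broken toward fewer attributes) becomes the
   informative set, capped at a budget (default 30).

Mutual information is the plug-in estimator over the empirical joint
distribution, computed on the raw integer pair counts directly — CKSAAP
counts are small integers, so no binning rule is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import ConfusionMetrics, SvmConfig, cross_validate_matrix


def mutual_information(x, y, base: float = 2.0) -> float:
    """Plug-in mutual information between two discrete sequences (bits).

    I(x, y) = sum_{a,b} p(a,b) log[ p(a,b) / (p(a) p(b)) ] over the empirical
    joint distribution.  Symmetric, nonnegative, and equal to the entropy
    H(x) when y == x.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty sequences")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    return _mi_coded(xi, int(xi.max()) + 1, yi, int(yi.max()) + 1, base)


def _mi_coded(xi: np.ndarray, nx: int, yi: np.ndarray, ny: int,
              base: float = 2.0) -> float:
    n = xi.size
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).astype(float)
    joint /= n
    joint = joint.reshape(nx, ny)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    outer = np.outer(px, py)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())
    return max(mi / np.log(base), 0.0)


@dataclass
class MrmrRanking:
    """Greedy mRMR ranking of a feature matrix's columns.

    ``order`` holds column indices in rank order; ``scores`` the mRMR score
    of each column at the step it was selected (the first entry is its
    relevance); ``relevance`` holds I(f_j, c) for every column in input
    order.
    """

    order: list[int]
    names: list[str]
    scores: np.ndarray
    relevance: np.ndarray


def mrmr_rank(X, y, top_m: int | None = None,
              feature_names: Sequence[str] | None = None) -> MrmrRanking:
    """Rank feature columns by the greedy incremental mRMR criterion.

    ``X`` is (n_samples, n_features) of discrete values (integer counts for
    CKSAAP); ``y`` is the binary class label.  ``top_m`` truncates the
    ranking (the downstream SFS budget makes a full ranking unnecessary).
    Ties break toward the lower column index.
    """
    X = np.asarray(X)
    y = np.asarray(y).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if np.unique(y).size < 2:
        raise ValueError("labels are constant; relevance is undefined")
    n, p = X.shape
    if feature_names is None:
        feature_names = [str(j) for j in range(p)]
    if top_m is None or top_m > p:
        top_m = p

    _, y_codes = np.unique(y, return_inverse=True)
    ny = int(y_codes.max()) + 1
    codes = []
    levels = []
    for j in range(p):
        _, cj = np.unique(X[:, j], return_inverse=True)
        codes.append(cj)
        levels.append(int(cj.max()) + 1)

    relevance = np.array([_mi_coded(codes[j], levels[j], y_codes, ny)
                          for j in range(p)])
    order: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)

    first = int(np.argmax(relevance))
    order.append(first)
    scores.append(float(relevance[first]))
    available[first] = False

    while len(order) < top_m:
        last = order[-1]
        for j in np.nonzero(available)[0]:
            redundancy_sum[j] += _mi_coded(codes[last], levels[last],
                                           codes[j], levels[j])
        criterion = relevance - redundancy_sum / len(order)
        criterion[~available] = -np.inf
        nxt = int(np.argmax(criterion))
        order.append(nxt)
        scores.append(float(criterion[nxt]))
        available[nxt] = False

    return MrmrRanking(order=order,
                       names=[feature_names[j] for j in order],
                       scores=np.array(scores), relevance=relevance)


@dataclass
class SfsResult:
    """Outcome of sequential forward selection over an mRMR ranking prefix."""

    selected: list[str]
    selected_indices: list[int]
    trace: list[ConfusionMetrics] = field(repr=False)
    stopping_reason: str = "budget"

    @property
    def best_mcc(self) -> float:
        return self.trace[len(self.selected) - 1].mcc


def sfs_select(ranking: MrmrRanking, X, y,
               budget: int = 30, cv_folds: int = 10, seed: int = 0,
               svm_config: SvmConfig | None = None) -> SfsResult:
    """Scan ranking prefixes, keeping the prefix with the best CV MCC.

    ``X`` holds the classifier-ready feature values (one column per ranked
    attribute's source column in ``ranking.order``'s index space).  Each step
    adds the next-ranked attribute, refits the SVM (a fixed configuration —
    the final model is grid-searched separately), and records the pooled
    cross-validated confusion metrics.  Ties in best MCC go to the smaller
    attribute count; a perfect MCC stops the scan early.
    """
    if budget < 1:
        raise ValueError(f"budget must be >= 1, got {budget}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if not ranking.order:
        raise ValueError("empty ranking")
    n_steps = min(budget, len(ranking.order))
    trace: list[ConfusionMetrics] = []
    stopping_reason = "budget" if budget <= len(ranking.order) \
        else "ranking_exhausted"
    for step in range(1, n_steps + 1):
        cols = ranking.order[:step]
        pooled, _ = cross_validate_matrix(X[:, cols], y, config=svm_config,
                                          folds=cv_folds, seed=seed)
        trace.append(pooled)
        if pooled.mcc >= 1.0:
            stopping_reason = "perfect"
            break
    best_step = 1 + int(np.argmax([m.mcc for m in trace]))
    return SfsResult(selected=ranking.names[:best_step],
                     selected_indices=ranking.order[:best_step],
                     trace=trace, stopping_reason=stopping_reason)


def ranking_to_table(ranking: MrmrRanking):
    """Ranking as a DataFrame (attribute, score, relevance) for TSV export."""
    import pandas as pd

    return pd.DataFrame({
        "attribute": ranking.names,
        "score": ranking.scores,
        "relevance": ranking.relevance[ranking.order],
    })
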