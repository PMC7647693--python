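"""Position-specific composition analysis of lysine windows.

Substrate specificity shows up as position-specific residue preferences in
the flanks of modified sites — e.g. extra lysines well upstream/downstream of
a succinylated K, and a deficit of glutamate/aspartate immediately around it.
This module computes the tables behind sequence-logo style figures:

* a per-position residue frequency matrix (frequency-plot logo),
* a two-sample enrichment/depletion table contrasting positive vs negative
  windows per (residue, position) cell (two-sample logo), and
* the 20 x 20 dipeptide over/under-representation matrix (AAPC heatmap).

Rendering is an optional convenience over matplotlib; the tables are the
primary interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import DIPEPTIDES, _code_matrix, _two_proportion_p
from .seqio import STANDARD_AA, SequenceWindow

ENRICHED = "enriched"
DEPLETED = "depleted"
NONE = "none"


@dataclass(frozen=True)
class EnrichmentCell:
    """One (residue, position) contrast between positive and negative windows."""

    residue: str
    position: int
    direction: str
    effect: float
    p_value: float


def _position_counts(windows) -> tuple[np.ndarray, np.ndarray]:
    """(20 x L residue counts, per-position coverage over non-pad letters)."""
    codes = _code_matrix(windows)
    length = codes.shape[1]
    counts = np.zeros((20, length))
    for pos in range(length):
        col = codes[:, pos]
        counts[:, pos] = np.bincount(col[col >= 0], minlength=20)
    return counts, counts.sum(axis=0)


def position_labels(length: int) -> list[int]:
    """Positions -n..+n with 0 at the central residue."""
    n = (length - 1) // 2
    return list(range(-n, n + 1))


def position_frequency_matrix(windows: Sequence[SequenceWindow | str]
                              ) -> pd.DataFrame:
    """20 x (2n+1) per-position residue frequencies (columns -n..+n).

    Each covered column sums to 1 over residues; pads and 'X' are excluded
    from coverage.
    """
    if len(windows) == 0:
        raise ValueError("empty window set")
    counts, coverage = _position_counts(windows)
    freq = np.divide(counts, coverage, out=np.zeros_like(counts),
                     where=coverage > 0)
    return pd.DataFrame(freq, index=list(STANDARD_AA),
                        columns=position_labels(counts.shape[1]))


def two_sample_logo_table(pos_windows: Sequence[SequenceWindow | str],
                          neg_windows: Sequence[SequenceWindow | str],
                          alpha: float = 0.05,
                          bonferroni: bool = False) -> list[EnrichmentCell]:
    """Per-(residue, position) two-proportion contrast of the two classes.

    For each non-center cell, the frequency difference (positive minus
    negative) and a two-proportion z-test p-value are computed; significant
    cells are directed by the sign of the difference.  The central column is
    skipped (it is constant K by construction), leaving at most 20 x 2n
    cells.  With ``bonferroni`` the threshold is divided by the number of
    tested cells.
    """
    if len(pos_windows) == 0 or len(neg_windows) == 0:
        raise ValueError("both classes must be nonempty")
    pos_counts, pos_cov = _position_counts(pos_windows)
    neg_counts, neg_cov = _position_counts(neg_windows)
    if pos_counts.shape != neg_counts.shape:
        raise ValueError("window length mismatch between classes")
    length = pos_counts.shape[1]
    center = (length - 1) // 2
    labels = position_labels(length)
    n_cells = 20 * (length - 1)
    threshold = alpha / n_cells if bonferroni else alpha
    cells = []
    for pos in range(length):
        if pos == center:
            continue
        for r, residue in enumerate(STANDARD_AA):
            n1, n2 = pos_cov[pos], neg_cov[pos]
            if n1 == 0 or n2 == 0:
                continue
            f_pos = pos_counts[r, pos] / n1
            f_neg = neg_counts[r, pos] / n2
            p = _two_proportion_p(int(pos_counts[r, pos]), int(n1),
                                  int(neg_counts[r, pos]), int(n2))
            effect = f_pos - f_neg
            if p < threshold and effect != 0:
                direction = ENRICHED if effect > 0 else DEPLETED
            else:
                direction = NONE
            cells.append(EnrichmentCell(residue, labels[pos], direction,
                                        effect, p))
    return cells


def enrichment_table_to_frame(cells: Sequence[EnrichmentCell]) -> pd.DataFrame:
    return pd.DataFrame([{"residue": c.residue, "position": c.position,
                          "direction": c.direction, "effect": c.effect,
                          "p_value": c.p_value} for c in cells])


def aapc_heatmap_matrix(pos_windows: Sequence[SequenceWindow | str],
                        neg_windows: Sequence[SequenceWindow | str]
                        ) -> pd.DataFrame:
    """20 x 20 matrix of pooled dipeptide probability differences.

    Entry (i, j) is p_pos(AiAj) - p_neg(AiAj) over pooled adjacent-pair
    counts; positive entries mark dipeptides over-represented around
    succinylated sites.  Rows index the first residue.  Entries sum to 0.
    """
    if len(pos_windows) == 0 or len(neg_windows) == 0:
        raise ValueError("both classes must be nonempty")

    def pooled_freq(windows) -> np.ndarray:
        codes = _code_matrix(windows)
        first, second = codes[:, :-1], codes[:, 1:]
        valid = (first >= 0) & (second >= 0)
        idx = first[valid].astype(int) * 20 + second[valid]
        counts = np.bincount(idx, minlength=400).astype(float)
        total = counts.sum()
        return counts / total if total > 0 else counts

    diff = pooled_freq(pos_windows) - pooled_freq(neg_windows)
    return pd.DataFrame(diff.reshape(20, 20), index=list(STANDARD_AA),
                        columns=list(STANDARD_AA))


def plot_frequency_matrix(matrix: pd.DataFrame, ax=None):
    """Render a frequency matrix as a stacked-bar logo sketch (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    bottom = np.zeros(matrix.shape[1])
    for residue in matrix.index:
        ax.bar(matrix.columns, matrix.loc[residue], bottom=bottom,
               width=0.85, label=residue)
        bottom += matrix.loc[residue].to_numpy()
    ax.set_xlabel("position relative to site")
    ax.set_ylabel("frequency")
    return ax
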