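"""Window encoders and dataset-level screening statistics.

Three sequence encodings drive the classifier:

* **AAC** — amino acid composition, the 20-dim probability vector of residue
  frequencies within a window.
* **AAPC** — amino acid pair composition, the 400-dim probability vector of
  adjacent (overlapping) dipeptide frequencies.
* **CKSAAP** — composition of k-spaced amino acid pairs: for each ordered
  residue pair (Ai, Aj) and spacing k (residues separated by exactly k
  positions), the count of such pairs in the window divided by the number of
  available slots.  With k = 1..5 this yields 20 x 20 x 5 = 2000 attributes.

Pads ('-') and unknown residues ('X') never match any attribute letter; they
are excluded from numerators and reduce the per-window slot counts, so every
feature stays a proper frequency in [0, 1].

The dataset-level statistics used for feature screening also live here:
per-dipeptide class contrasts (probability difference + two-proportion test)
and the k-spaced pair strength C = log(P+/P-), the log-ratio of a pair's
conditional probability in the positive vs negative window set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.proportion import proportions_ztest

from .seqio import PAD, STANDARD_AA, SequenceWindow

AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}
DIPEPTIDES: list[str] = [a + b for a in STANDARD_AA for b in STANDARD_AA]

_CODE_TABLE = np.full(128, -1, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _CODE_TABLE[ord(_a)] = _i


@dataclass(frozen=True)
class KsaapAttribute:
    """An ordered residue pair (first, second) separated by exactly k positions.

    Canonical name ``"<first>_<k>_<second>"``, e.g. ``"K_1_A"`` for K and A
    separated by one residue.
    """

    first: str
    k: int
    second: str

    def __post_init__(self) -> None:
        if self.first not in AA_INDEX or self.second not in AA_INDEX:
            raise ValueError(f"unknown residue in pair {self.first!r}, "
                             f"{self.second!r}")
        if self.k < 1:
            raise ValueError(f"spacing k must be >= 1, got {self.k}")

    @property
    def name(self) -> str:
        return f"{self.first}_{self.k}_{self.second}"

    @classmethod
    def from_name(cls, name: str) -> "KsaapAttribute":
        first, k, second = name.split("_")
        return cls(first, int(k), second)


def all_ksaap_attributes(k_min: int = 1, k_max: int = 5) -> list[KsaapAttribute]:
    """All 20 x 20 x (k_max - k_min + 1) attributes, k-major canonical order."""
    return [KsaapAttribute(a, k, b)
            for k in range(k_min, k_max + 1)
            for a in STANDARD_AA for b in STANDARD_AA]


def _residues_of(w: SequenceWindow | str) -> str:
    return w.residues if isinstance(w, SequenceWindow) else w


def _code_matrix(windows: Sequence[SequenceWindow | str]) -> np.ndarray:
    """(n_windows, window_length) residue codes; -1 for pads/unknowns."""
    if len(windows) == 0:
        raise ValueError("empty window set")
    strings = [_residues_of(w) for w in windows]
    length = len(strings[0])
    if any(len(s) != length for s in strings):
        raise ValueError("windows must share a common length")
    raw = np.frombuffer("".join(strings).encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw].reshape(len(strings), length)


# ---------------------------------------------------------------------------
# per-window encodings


def aac_encode(window: SequenceWindow | str) -> np.ndarray:
    """20-dim amino acid composition: counts of each residue / total count.

    Pads and 'X' are excluded from both numerator and denominator.  A window
    with no countable residue yields the all-zero vector.
    """
    codes = _code_matrix([window])[0]
    counts = np.bincount(codes[codes >= 0], minlength=20).astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


def aapc_encode(window: SequenceWindow | str) -> np.ndarray:
    """400-dim adjacent-dipeptide composition.

    Counts overlapping position pairs (i, i+1) where both residues are
    standard letters, normalized by the total countable pair count.
    """
    codes = _code_matrix([window])[0]
    first, second = codes[:-1], codes[1:]
    valid = (first >= 0) & (second >= 0)
    idx = first[valid].astype(int) * 20 + second[valid]
    counts = np.bincount(idx, minlength=400).astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


def ksaap_count(window: SequenceWindow | str,
                attribute: KsaapAttribute) -> int:
    """Occurrences of ``attribute`` in the window.

    Slides through the window counting index pairs (i, i + k + 1) whose
    letters match (first, second); pads and 'X' never match.
    """
    s = _residues_of(window)
    k = attribute.k
    return sum(1 for i in range(len(s) - k - 1)
               if s[i] == attribute.first and s[i + k + 1] == attribute.second)


def ksaap_count_matrix(windows: Sequence[SequenceWindow | str],
                       k_min: int = 1, k_max: int = 5,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized k-spaced pair counts for a window set.

    Returns ``(counts, slots)``: ``counts`` is (n_windows, 400 * n_k) in the
    canonical attribute order of :func:`all_ksaap_attributes`; ``slots`` is
    (n_windows, n_k), the number of countable index pairs per spacing (pairs
    where both letters are standard residues).
    """
    codes = _code_matrix(windows)
    n, length = codes.shape
    n_k = k_max - k_min + 1
    counts = np.zeros((n, 400 * n_k), dtype=np.int32)
    slots = np.zeros((n, n_k), dtype=np.int32)
    rows = np.arange(n)
    for ki, k in enumerate(range(k_min, k_max + 1)):
        first = codes[:, : length - k - 1]
        second = codes[:, k + 1:]
        valid = (first >= 0) & (second >= 0)
        slots[:, ki] = valid.sum(axis=1)
        attr = 400 * ki + first.astype(np.int32) * 20 + second
        r, c = np.nonzero(valid)
        np.add.at(counts, (rows[r], attr[r, c]), 1)
    return counts, slots


def cksaap_encode(window: SequenceWindow | str,
                  attributes: Sequence[KsaapAttribute]) -> np.ndarray:
    """Per-window CKSAAP feature values for an ordered attribute list.

    Each value is the pair count divided by the number of countable slots at
    that spacing (``(2n+1) - k - 1`` for a pad-free window), giving bounded
    [0, 1] features.
    """
    values = np.zeros(len(attributes))
    s = _residues_of(window)
    codes = _CODE_TABLE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    slot_cache: dict[int, int] = {}
    for j, attr in enumerate(attributes):
        k = attr.k
        if k not in slot_cache:
            first, second = codes[: len(s) - k - 1], codes[k + 1:]
            slot_cache[k] = int(((first >= 0) & (second >= 0)).sum())
        n_slots = slot_cache[k]
        if n_slots:
            values[j] = ksaap_count(s, attr) / n_slots
    return values


# ---------------------------------------------------------------------------
# sklearn-style transformers


class _WindowEncoder(TransformerMixin, BaseEstimator):
    """Base for stateless window -> matrix transformers."""

    def fit(self, X, y=None):  # noqa: D102 - sklearn contract
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        raise NotImplementedError


class AacEncoder(_WindowEncoder):
    """Transformer: windows -> (n, 20) amino acid composition matrix."""

    def transform(self, X) -> np.ndarray:
        codes = _code_matrix(X)
        counts = np.stack([np.bincount(row[row >= 0], minlength=20)
                           for row in codes]).astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        np.divide(counts, totals, out=counts, where=totals > 0)
        return counts

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(list(STANDARD_AA))


class AapcEncoder(_WindowEncoder):
    """Transformer: windows -> (n, 400) adjacent-dipeptide composition matrix.

    ``dipeptides`` restricts the output to a named subset (e.g. the
    significant dipeptides surviving the screening rule) in the given order.
    """

    def __init__(self, dipeptides: Sequence[str] | None = None):
        self.dipeptides = dipeptides

    def transform(self, X) -> np.ndarray:
        codes = _code_matrix(X)
        first, second = codes[:, :-1], codes[:, 1:]
        valid = (first >= 0) & (second >= 0)
        counts = np.zeros((codes.shape[0], 400))
        idx = first.astype(int) * 20 + second
        r, c = np.nonzero(valid)
        np.add.at(counts, (r, idx[r, c]), 1.0)
        totals = counts.sum(axis=1, keepdims=True)
        np.divide(counts, totals, out=counts, where=totals > 0)
        if self.dipeptides is not None:
            cols = [DIPEPTIDES.index(d) for d in self.dipeptides]
            counts = counts[:, cols]
        return counts

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(list(self.dipeptides)
                        if self.dipeptides is not None else DIPEPTIDES)


class CksaapEncoder(_WindowEncoder):
    """Transformer: windows -> per-slot-normalized k-spaced pair frequencies.

    ``attributes=None`` emits the full 2000-attribute space (k = 1..5,
    canonical order); otherwise only the named subset, in order.
    """

    def __init__(self, attributes: Sequence[KsaapAttribute | str] | None = None,
                 k_min: int = 1, k_max: int = 5):
        self.attributes = attributes
        self.k_min = k_min
        self.k_max = k_max

    def _resolved(self) -> list[KsaapAttribute]:
        if self.attributes is None:
            return all_ksaap_attributes(self.k_min, self.k_max)
        return [a if isinstance(a, KsaapAttribute) else
                KsaapAttribute.from_name(a) for a in self.attributes]

    def transform(self, X) -> np.ndarray:
        counts, slots = ksaap_count_matrix(X, self.k_min, self.k_max)
        attrs = self._resolved()
        full = all_ksaap_attributes(self.k_min, self.k_max)
        index = {a.name: j for j, a in enumerate(full)}
        cols = [index[a.name] for a in attrs]
        values = counts[:, cols].astype(float)
        for j, a in enumerate(attrs):
            denom = slots[:, a.k - self.k_min]
            np.divide(values[:, j], denom, out=values[:, j], where=denom > 0)
        return values

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([a.name for a in self._resolved()])


# ---------------------------------------------------------------------------
# dataset-level screening statistics


def _two_proportion_p(count1: int, n1: int, count2: int, n2: int) -> float:
    """Pooled two-proportion z-test p-value; degenerate tables give p = 1."""
    pooled = (count1 + count2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 1.0
    _, p = proportions_ztest([count1, count2], [n1, n2])
    return float(p)


@dataclass(frozen=True)
class DipeptideStats:
    """Class contrast for one adjacent dipeptide.

    ``p_pos``/``p_neg`` are pooled occurrence probabilities (total count of
    the dipeptide over all windows of the class, divided by the class's total
    countable pair count); the p-value comes from a two-proportion z-test on
    window-level presence (number of windows containing the dipeptide at
    least once).
    """

    dipeptide: str
    p_pos: float
    p_neg: float
    diff: float
    p_value: float


def _pooled_dipeptide_counts(windows) -> tuple[np.ndarray, float, np.ndarray]:
    """(total counts per dipeptide, total pair count, presence per dipeptide)."""
    codes = _code_matrix(windows)
    first, second = codes[:, :-1], codes[:, 1:]
    valid = (first >= 0) & (second >= 0)
    idx = first.astype(int) * 20 + second
    counts = np.zeros((codes.shape[0], 400), dtype=np.int32)
    r, c = np.nonzero(valid)
    np.add.at(counts, (r, idx[r, c]), 1)
    return (counts.sum(axis=0).astype(float), float(valid.sum()),
            (counts > 0).sum(axis=0))


def dipeptide_diff_stats(pos_windows: Sequence[SequenceWindow | str],
                         neg_windows: Sequence[SequenceWindow | str],
                         ) -> list[DipeptideStats]:
    """Per-dipeptide class contrast over all 400 dipeptides, p-value sorted."""
    if len(pos_windows) == 0 or len(neg_windows) == 0:
        raise ValueError("both classes must be nonempty")
    pos_counts, pos_total, pos_presence = _pooled_dipeptide_counts(pos_windows)
    neg_counts, neg_total, neg_presence = _pooled_dipeptide_counts(neg_windows)
    n_pos, n_neg = len(pos_windows), len(neg_windows)
    stats = []
    for j, dip in enumerate(DIPEPTIDES):
        p_pos = pos_counts[j] / pos_total if pos_total else 0.0
        p_neg = neg_counts[j] / neg_total if neg_total else 0.0
        p_value = _two_proportion_p(int(pos_presence[j]), n_pos,
                                    int(neg_presence[j]), n_neg)
        stats.append(DipeptideStats(dip, p_pos, p_neg, p_pos - p_neg, p_value))
    return sorted(stats, key=lambda s: (s.p_value, s.dipeptide))


def select_significant_dipeptides(stats: Sequence[DipeptideStats],
                                  diff_min: float = 0.02,
                                  alpha: float = 0.05) -> list[str]:
    """Dipeptides with |probability difference| > diff_min and P < alpha.

    Returned in ascending p-value order (the screening rule used to build the
    AAPC attribute set).
    """
    passing = [s for s in stats
               if abs(s.diff) > diff_min and s.p_value < alpha]
    return [s.dipeptide for s in
            sorted(passing, key=lambda s: (s.p_value, s.dipeptide))]


@dataclass(frozen=True)
class KsaapStrength:
    """Class-contrast strength of one k-spaced pair.

    ``p_pos``/``p_neg`` are the conditional probabilities
    P(Ai x Aj) = N(Ai x Aj) / N(Ai x A*) within each class, where the
    denominator sums the pair count over all 20 second residues at the same
    spacing.  ``c_value`` = log(P+/P-) (natural log): positive means the pair
    is enriched among succinylated windows.
    """

    attribute: KsaapAttribute
    p_pos: float
    p_neg: float
    c_value: float


def _pair_and_margin_counts(windows, attribute: KsaapAttribute
                            ) -> tuple[int, int]:
    codes = _code_matrix(windows)
    k = attribute.k
    first = codes[:, : codes.shape[1] - k - 1]
    second = codes[:, k + 1:]
    ai = AA_INDEX[attribute.first]
    aj = AA_INDEX[attribute.second]
    margin = int(((first == ai) & (second >= 0)).sum())
    pair = int(((first == ai) & (second == aj)).sum())
    return pair, margin


def ksaap_strength(pos_windows: Sequence[SequenceWindow | str],
                   neg_windows: Sequence[SequenceWindow | str],
                   attribute: KsaapAttribute) -> KsaapStrength:
    """Strength C = log(P+/P-) of a k-spaced pair between the two classes.

    When either class has a zero pair count, both classes receive a
    pseudocount (+1 to the pair count, +20 to the marginal) before taking the
    ratio, so C stays finite; otherwise the raw ratio is used and
    ``c_value == log(p_pos / p_neg)`` exactly.
    """
    if len(pos_windows) == 0 or len(neg_windows) == 0:
        raise ValueError("both classes must be nonempty")
    pair_pos, margin_pos = _pair_and_margin_counts(pos_windows, attribute)
    pair_neg, margin_neg = _pair_and_margin_counts(neg_windows, attribute)
    p_pos = pair_pos / margin_pos if margin_pos else 0.0
    p_neg = pair_neg / margin_neg if margin_neg else 0.0
    if pair_pos > 0 and pair_neg > 0:
        c = math.log(p_pos / p_neg)
    else:
        c = math.log(((pair_pos + 1) / (margin_pos + 20))
                     / ((pair_neg + 1) / (margin_neg + 20)))
    return KsaapStrength(attribute, p_pos, p_neg, c)
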