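"""Sequence I/O and lysine-centered window extraction.

Succinylation is a site-specific lysine modification, so the unit of
classification throughout this package is the *sequence window*: the modified
(or candidate) lysine plus ``n`` flanking residues on each side, a
``(2n+1)``-mer (31-mer at the default ``n=15``).  This module reads protein
FASTA files and site-annotation tables, extracts labeled windows, and removes
redundant fragments at a configurable identity threshold.

Conventions
-----------
* Annotation positions are 1-based inclusive (UniProt convention).
* Windows crossing protein termini are padded with ``'-'``; pads never count
  toward any composition statistic downstream.
* Nonstandard residue letters (B, J, O, U, Z) are mapped to ``'X'`` on input
  and treated like pads by every encoder, keeping the 20-letter feature space
  exact.
* Fragment identity is the positionwise match fraction over the fixed window
  columns (windows are pre-aligned on the central K, so no realignment is
  performed).  Protein-level clustering with an external tool such as CD-HIT
  is a supported *preprocessing* step: run it on the FASTA before calling
  :func:`read_fasta`; this package only de-redundifies the fixed-length
  fragments.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO as _bio_seqio

logger = logging.getLogger(__name__)

STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)
PAD: str = "-"
UNKNOWN: str = "X"
#: letters outside the 20-letter alphabet that occur in public sequence data
_NONSTANDARD_TABLE = str.maketrans({c: UNKNOWN for c in "BJOUZ"})

POSITIVE = "positive"
NEGATIVE = "negative"


class FastaParseError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class SiteAnnotation:
    """A labeled lysine site: ``protein_id``, 1-based ``position``, label."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("annotation positions are 1-based (got "
                             f"{self.position})")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}, "
                             f"got {self.label!r}")


@dataclass(frozen=True)
class SequenceWindow:
    """A ``(2n+1)``-mer centered on a lysine, with provenance and label."""

    protein_id: str
    center_position: int
    n: int
    residues: str
    label: str

    def __post_init__(self) -> None:
        if len(self.residues) != 2 * self.n + 1:
            raise ValueError("window length must be 2n+1 "
                             f"({2 * self.n + 1}), got {len(self.residues)}")
        if self.residues[self.n] != "K":
            raise ValueError("window center must be 'K', got "
                             f"{self.residues[self.n]!r}")


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map nonstandard letters (B, J, O, U, Z) to ``'X'``."""
    return sequence.upper().translate(_NONSTANDARD_TABLE)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased and nonstandard letters mapped to ``'X'``.
    Raises :class:`FastaParseError` (naming the offending line) on an empty
    file, data before the first header, or a duplicate identifier.
    """
    text = Path(path).read_text()
    first_content = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        raise FastaParseError(f"{path}: empty FASTA file")
    if not first_content[1].startswith(">"):
        raise FastaParseError(
            f"{path}: line {first_content[0]}: expected '>' header, got "
            f"{first_content[1][:30]!r}")
    records = []
    seen: set[str] = set()
    for rec in _bio_seqio.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, normalize_sequence(str(rec.seq))))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA, preserving order (deterministic)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a site-annotation TSV with header ``protein_id position label``."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation TSV needs columns {sorted(required)}, "
                         f"found {list(df.columns)}")
    return [SiteAnnotation(r.protein_id, int(r.position), str(r.label))
            for r in df.itertuples(index=False)]


def write_annotations(annotations: Iterable[SiteAnnotation],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.position}\t{a.label}\n")


def write_windows(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    """Export windows as TSV ``protein_id position window label``."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\twindow\tlabel\n")
        for w in windows:
            fh.write(f"{w.protein_id}\t{w.center_position}\t{w.residues}\t"
                     f"{w.label}\n")


def read_windows(path: str | Path) -> list[SequenceWindow]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out = []
    for r in df.itertuples(index=False):
        residues = str(r.window)
        out.append(SequenceWindow(r.protein_id, int(r.position),
                                  (len(residues) - 1) // 2, residues,
                                  str(r.label)))
    return out


def window_residues(sequence: str, position: int, n: int = 15) -> str:
    """The ``(2n+1)``-mer around 1-based ``position``, pad-filled at termini."""
    i = position - 1
    if not 0 <= i < len(sequence):
        raise ValueError(f"position {position} outside sequence of length "
                         f"{len(sequence)}")
    left = sequence[max(0, i - n):i]
    right = sequence[i + 1:i + 1 + n]
    return (PAD * (n - len(left)) + left + sequence[i] + right
            + PAD * (n - len(right)))


def extract_windows(proteins: Sequence[ProteinRecord],
                    annotations: Sequence[SiteAnnotation],
                    n: int = 15,
                    negatives_from_unannotated: bool = True,
                    ) -> list[SequenceWindow]:
    """Extract one labeled window per annotated lysine.

    With ``negatives_from_unannotated`` (training mode), every lysine that
    carries no annotation becomes a negative window — the standard negative-set
    construction when only positive sites are curated.  Annotations whose
    residue is not K are skipped with a logged warning (public PTM tables
    contain isoform coordinate offsets); annotations referencing unknown
    proteins or out-of-range positions are hard errors.
    """
    prot_by_id = {p.id: p for p in proteins}
    if len(prot_by_id) != len(proteins):
        raise ValueError("duplicate protein ids in input")
    ann_by_protein: dict[str, dict[int, str]] = {p.id: {} for p in proteins}
    for a in annotations:
        prot = prot_by_id.get(a.protein_id)
        if prot is None:
            raise KeyError(f"annotation references unknown protein "
                           f"{a.protein_id!r}")
        if not 1 <= a.position <= len(prot.sequence):
            raise ValueError(f"{a.protein_id}:{a.position} outside sequence "
                             f"of length {len(prot.sequence)}")
        if prot.sequence[a.position - 1] != "K":
            logger.warning("skipping %s:%d — residue is %r, not K",
                           a.protein_id, a.position,
                           prot.sequence[a.position - 1])
            continue
        ann_by_protein[a.protein_id][a.position] = a.label
    windows = []
    for prot in proteins:
        site_labels = ann_by_protein[prot.id]
        positions = set(site_labels)
        if negatives_from_unannotated:
            positions.update(i + 1 for i, c in enumerate(prot.sequence)
                             if c == "K")
        for pos in sorted(positions):
            label = site_labels.get(pos, NEGATIVE)
            windows.append(SequenceWindow(
                prot.id, pos, n, window_residues(prot.sequence, pos, n),
                label))
    return windows


def _residues_of(w: SequenceWindow | str) -> str:
    return w.residues if isinstance(w, SequenceWindow) else w


def fragment_identity(w1: SequenceWindow | str,
                      w2: SequenceWindow | str) -> float:
    """Positionwise identity fraction between two equal-length windows.

    Matches are counted only where both letters are identical members of the
    20-letter alphabet (pads and 'X' never match); the denominator is the
    full window length.
    """
    a, b = _residues_of(w1), _residues_of(w2)
    if len(a) != len(b):
        raise ValueError(f"window length mismatch: {len(a)} vs {len(b)}")
    matches = sum(1 for x, y in zip(a, b)
                  if x == y and x in STANDARD_AA_SET)
    return matches / len(a)


def redundancy_filter(windows: Sequence[SequenceWindow],
                      threshold: float = 0.4,
                      reference: Sequence[SequenceWindow] | None = None,
                      ) -> list[SequenceWindow]:
    """Greedy first-kept redundancy removal at an identity ``threshold``.

    Scans ``windows`` in order and drops any window whose identity with an
    already-kept window (or with any ``reference`` window, for cross-set
    filtering of e.g. a test set against a training set) exceeds the
    threshold.  Input order therefore determines keep priority.  Idempotent.
    """
    kept: list[SequenceWindow] = []
    ref = [_residues_of(w) for w in reference] if reference else []
    for w in windows:
        r = w.residues
        if any(fragment_identity(r, other) > threshold for other in ref):
            continue
        if any(fragment_identity(r, k.residues) > threshold for k in kept):
            continue
        kept.append(w)
    return kept


def split_train_test(windows: Sequence[SequenceWindow],
                     test_fraction: float,
                     seed: int) -> tuple[list[SequenceWindow],
                                         list[SequenceWindow]]:
    """Protein-level train/test split: no protein contributes to both sides.

    Deterministic given ``seed``.  Raises if the fraction is outside (0, 1)
    or if fewer than two proteins are present.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    ids = sorted({w.protein_id for w in windows})
    if len(ids) < 2:
        raise ValueError("need windows from at least two proteins to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    n_test = min(max(n_test, 1), len(ids) - 1)
    test_ids = {ids[i] for i in order[:n_test]}
    train = [w for w in windows if w.protein_id not in test_ids]
    test = [w for w in windows if w.protein_id in test_ids]
    return train, test
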