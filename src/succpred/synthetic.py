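"""Synthetic succinylome generator.

Real succinylome training sets come from curated databases plus redundancy
filtering and are not redistributable at fixture scale, so every stage of
this package is testable against generated data with *known* structure.  The
generator emits proteins plus a site-annotation table in exactly the dialects
the I/O layer consumes, planting two kinds of signal into the flanks of
positive (succinylated) lysines:

* **position-specific composition biases** — per-(residue, offset) log-odds
  adjustments to the background distribution.  The default motif emulates
  the hallmark succinylation pattern: lysine enrichment at offsets -15..-1
  and +6..+12 and glutamate/aspartate depletion immediately around the site.
* **k-spaced pair enrichments** — named CKSAAP attributes whose expected
  occurrence count in positive flanks is multiplied relative to background,
  realized by Poisson-distributed forced pair insertions.

Background residues are uniform over the 20 letters by default, so planted
effects are the only structure in the data; a natural-abundance background
is available for more lifelike composition.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import KsaapAttribute
from .seqio import (NEGATIVE, POSITIVE, STANDARD_AA, ProteinRecord,
                    SiteAnnotation, write_annotations, write_fasta)

#: approximate residue frequencies in UniProtKB (percent, order ACDEFGHIKLMNPQRSTVWY)
_NATURAL_PCT = np.array([8.25, 1.37, 5.45, 6.75, 3.86, 7.07, 2.27, 5.96,
                         5.84, 9.66, 2.42, 4.06, 4.70, 3.93, 5.53, 6.56,
                         5.34, 6.87, 1.08, 2.92])


@dataclass(frozen=True)
class MotifSpec:
    """Planted flanking-composition structure for positive sites.

    ``position_log_odds`` maps (residue, offset) — offset relative to the
    site, never 0 — to a log-odds adjustment of that residue's background
    probability at that offset (the adjusted distribution is renormalized).
    ``pair_enrichments`` maps k-spaced pair attributes to multipliers > 0 on
    their expected occurrence count in positive windows.  ``effect_scale``
    scales the whole motif: log-odds multiply by the scale, multipliers
    interpolate as 1 + scale * (m - 1); scale 0 turns the motif off.
    """

    position_log_odds: dict[tuple[str, int], float] = field(
        default_factory=dict)
    pair_enrichments: dict[KsaapAttribute, float] = field(
        default_factory=dict)
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        for (residue, offset), _ in self.position_log_odds.items():
            if residue not in STANDARD_AA or offset == 0:
                raise ValueError(f"bad motif cell ({residue!r}, {offset})")
        for attr, mult in self.pair_enrichments.items():
            if mult <= 0:
                raise ValueError(f"multiplier for {attr.name} must be > 0")

    @classmethod
    def succinylome_default(cls, effect_scale: float = 1.0) -> "MotifSpec":
        """The default planted motif mimicking known succinylation biases.

        Lysine at log-odds +0.7 (about twofold) at offsets -15..-1 and
        +6..+12; glutamate and aspartate at log-odds -1.2 (about 0.3x) at
        offsets -5..-3 and +5; ten k-spaced pairs spread over k = 1..5 at
        multiplier 8.
        """
        log_odds: dict[tuple[str, int], float] = {}
        for off in list(range(-15, 0)) + list(range(6, 13)):
            log_odds[("K", off)] = 0.7
        for off in (-5, -4, -3, 5):
            log_odds[("E", off)] = -1.2
            log_odds[("D", off)] = -1.2
        pairs = {KsaapAttribute("K", 1, "A"): 8.0,
                 KsaapAttribute("A", 1, "K"): 8.0,
                 KsaapAttribute("L", 2, "K"): 8.0,
                 KsaapAttribute("K", 2, "G"): 8.0,
                 KsaapAttribute("G", 3, "V"): 8.0,
                 KsaapAttribute("V", 3, "L"): 8.0,
                 KsaapAttribute("S", 4, "T"): 8.0,
                 KsaapAttribute("T", 4, "A"): 8.0,
                 KsaapAttribute("L", 5, "A"): 8.0,
                 KsaapAttribute("A", 5, "G"): 8.0}
        return cls(position_log_odds=log_odds, pair_enrichments=pairs,
                   effect_scale=effect_scale)

    def scaled_log_odds(self, residue: str, offset: int) -> float:
        return self.effect_scale * self.position_log_odds.get(
            (residue, offset), 0.0)

    def scaled_multiplier(self, attr: KsaapAttribute) -> float:
        m = self.pair_enrichments.get(attr, 1.0)
        return 1.0 + self.effect_scale * (m - 1.0)


def _background(mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.full(20, 1.0 / 20)
    if mode == "natural":
        return _NATURAL_PCT / _NATURAL_PCT.sum()
    raise ValueError(f"unknown background {mode!r}")


def generate_succinylome(n_proteins: int = 100, mean_length: int = 400,
                         n_pos_sites: int = 100, n_neg_sites: int = 300,
                         motif: MotifSpec | None = None, seed: int = 0,
                         n_flank: int = 15, background: str = "uniform",
                         out_fasta: str | Path | None = None,
                         out_annotations: str | Path | None = None,
                         ) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Generate proteins with planted positive/negative succinylation sites.

    Protein lengths are geometric around ``mean_length`` with floor
    ``2*n_flank + 1``.  Candidate site slots are laid out so windows of
    adjacent sites never overlap; each slot's center residue is forced to K
    and randomly assigned positive or negative.  Positive flanks are then
    redrawn from the motif-adjusted per-offset distributions, followed by
    Poisson-sampled forced insertions of the planted k-spaced pairs
    (insertion slots never touch the central K).  Raises if the requested
    site count exceeds the available slot capacity.

    Returns (proteins, annotations); optionally writes FASTA and the
    annotation TSV.
    """
    if n_proteins < 1 or n_pos_sites < 0 or n_neg_sites < 0:
        raise ValueError("counts must be positive")
    if motif is None:
        motif = MotifSpec.succinylome_default()
    rng = np.random.default_rng(seed)
    width = 2 * n_flank + 1
    bg = _background(background)
    aa = np.frombuffer(STANDARD_AA.encode("ascii"), dtype=np.uint8)

    min_len = width
    p_geo = 1.0 / max(mean_length - min_len + 1, 1)
    lengths = min_len - 1 + rng.geometric(p_geo, size=n_proteins)

    seqs = [rng.choice(20, size=int(L), p=bg) for L in lengths]

    # non-overlapping site slots: centers spaced a full window apart
    slots: list[tuple[int, int]] = []
    for pi, L in enumerate(lengths):
        for j in range((int(L) - 2 * n_flank) // width + 1):
            slots.append((pi, n_flank + 1 + width * j))  # 1-based center
    n_sites = n_pos_sites + n_neg_sites
    if n_sites > len(slots):
        raise ValueError(f"requested {n_sites} sites but only {len(slots)} "
                         "non-overlapping slots are available; increase "
                         "n_proteins or mean_length")
    chosen = rng.choice(len(slots), size=n_sites, replace=False)
    labels = np.array([POSITIVE] * n_pos_sites + [NEGATIVE] * n_neg_sites)
    rng.shuffle(labels)

    # per-offset motif-adjusted distributions for positive flanks
    offsets = [o for o in range(-n_flank, n_flank + 1) if o != 0]
    motif_dists = {}
    for off in offsets:
        adj = bg * np.exp([motif.scaled_log_odds(r, off)
                           for r in STANDARD_AA])
        motif_dists[off] = adj / adj.sum()

    planted = [(attr, motif.scaled_multiplier(attr))
               for attr in motif.pair_enrichments]
    aa_index = {r: i for i, r in enumerate(STANDARD_AA)}

    annotations = []
    for slot_i, label in zip(chosen, labels):
        pi, center = slots[slot_i]
        seq = seqs[pi]
        ci = center - 1
        seq[ci] = aa_index["K"]
        if label == POSITIVE:
            for off in offsets:
                j = ci + off
                if 0 <= j < len(seq):
                    seq[j] = rng.choice(20, p=motif_dists[off])
            for attr, mult in planted:
                k = attr.k
                base = (width - k - 1) / 400.0  # expected background count
                n_insert = rng.poisson(max(mult - 1.0, 0.0) * base)
                for _ in range(n_insert):
                    for _attempt in range(20):
                        i0 = int(rng.integers(ci - n_flank,
                                              ci + n_flank + 1 - (k + 1)))
                        i1 = i0 + k + 1
                        if (i0 != ci and i1 != ci and 0 <= i0
                                and i1 < len(seq)):
                            seq[i0] = aa_index[attr.first]
                            seq[i1] = aa_index[attr.second]
                            break
        annotations.append(SiteAnnotation(f"SYN{pi:05d}", int(center),
                                          str(label)))

    proteins = [ProteinRecord(f"SYN{pi:05d}",
                              aa[seq].tobytes().decode("ascii"))
                for pi, seq in enumerate(seqs)]
    annotations.sort(key=lambda a: (a.protein_id, a.position))
    if out_fasta is not None:
        write_fasta(proteins, out_fasta)
    if out_annotations is not None:
        write_annotations(annotations, out_annotations)
    return proteins, annotations
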