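"""Alignment-based filters used to pick generated sequences for experimental
verification: global alignment identity, the gap-free functional-motif
filter, nearest-natural lookup, identity bands, and the structure-confidence
(plddt) hook.

Alignment scheme: Needleman-Wunsch with affine gaps (BLOSUM62, gap open 10,
extend 0.5) and free terminal gaps, so full-length homologs of slightly
different lengths are compared without penalizing overhangs.  Percent
identity is matches over alignment columns, excluding the terminal-overhang
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS, SequenceRecord

#: NAD-binding and substrate-binding residue numbers of the template enzyme
NAD_BINDING_POSITIONS = (12, 13, 35, 78, 316)
SUBSTRATE_BINDING_POSITIONS = (151, 152, 181, 183, 234)
G3PDH_MOTIF_POSITIONS = tuple(sorted(NAD_BINDING_POSITIONS +
                                     SUBSTRATE_BINDING_POSITIONS))


@dataclass(frozen=True)
class MotifSpec:
    """A template sequence plus 1-based residue positions that must align
    gap-free in any passing query."""

    template_id: str
    template_sequence: str
    motif_positions: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "motif_positions",
                           tuple(sorted(set(self.motif_positions))))
        bad = [p for p in self.motif_positions
               if p < 1 or p > len(self.template_sequence)]
        if bad:
            raise ValueError(f"motif positions {bad} outside template "
                             f"length {len(self.template_sequence)}")


@dataclass
class AlignmentResult:
    aligned_query: str
    aligned_target: str
    score: float
    percent_identity: float
    #: 1-based target position -> 1-based query position, or None at a gap
    column_map: dict[int, Optional[int]]


@dataclass
class CandidateRecord:
    id: str
    disc_score: float
    nearest_natural_id: str
    identity_to_nearest: float
    motif_pass: bool
    plddt: Optional[float]
    plddt_assessed: bool
    selected: bool


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_internal_gap_score = -10.0
    aligner.extend_internal_gap_score = -0.5
    aligner.end_gap_score = 0.0  # free terminal gaps
    return aligner


def _check_sequence(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"{what} sequence contains invalid characters "
                         f"{sorted(bad)}")


def global_align(query: str, target: str) -> AlignmentResult:
    """Optimal global alignment of two protein sequences (affine gaps,
    free end gaps); deterministic (first optimal alignment)."""
    _check_sequence(query, "query")
    _check_sequence(target, "target")
    alignment = _aligner().align(query, target)[0]
    aq, at = alignment[0], alignment[1]
    identity = _identity_from_columns(aq, at)
    column_map: dict[int, Optional[int]] = {}
    qpos = tpos = 0
    for cq, ct in zip(aq, at):
        if cq != "-":
            qpos += 1
        if ct != "-":
            tpos += 1
            column_map[tpos] = qpos if cq != "-" else None
    return AlignmentResult(aq, at, float(alignment.score), identity, column_map)


def _identity_from_columns(aq: str, at: str) -> float:
    """Matches over columns between the first and last column where both
    sequences have a residue (terminal overhangs excluded)."""
    both = [i for i, (a, b) in enumerate(zip(aq, at))
            if a != "-" and b != "-"]
    if not both:
        return 0.0
    lo, hi = both[0], both[-1]
    matches = sum(1 for a, b in zip(aq[lo:hi + 1], at[lo:hi + 1]) if a == b)
    return 100.0 * matches / (hi - lo + 1)


def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity in [0, 100]; symmetric.

    Co-optimal alignments can differ in identity; the pair is aligned in a
    canonical order so the result does not depend on argument order.
    """
    if not a or not b:
        return 0.0
    if (len(a), a) > (len(b), b):
        a, b = b, a
    return global_align(a, b).percent_identity


def motif_filter(record: SequenceRecord, motif: MotifSpec,
                 flank: int = 0) -> tuple[bool, dict[int, Optional[str]]]:
    """Pass iff every motif position (plus-minus ``flank``) of the template
    aligns to a residue, not a gap, in the query.

    Returns the flag and a per-position report mapping each motif position to
    the aligned query residue (None where gapped).
    """
    result = global_align(record.residues, motif.template_sequence)
    report: dict[int, Optional[str]] = {}
    ok = True
    for pos in motif.motif_positions:
        for p in range(max(1, pos - flank),
                       min(len(motif.template_sequence), pos + flank) + 1):
            qpos = result.column_map.get(p)
            residue = record.residues[qpos - 1] if qpos else None
            if p == pos:
                report[pos] = residue
            if residue is None:
                ok = False
    return ok, report


def nearest_natural(record: SequenceRecord,
                    naturals: Sequence[SequenceRecord]) -> tuple[str, float]:
    """The natural sequence with the highest percent identity to ``record``;
    ties broken by ascending id."""
    if not naturals:
        raise ValueError("naturals must be non-empty")
    best_id, best_identity = None, -1.0
    for nat in sorted(naturals, key=lambda r: r.id):
        ident = percent_identity(record.residues, nat.residues)
        if ident > best_identity:
            best_id, best_identity = nat.id, ident
    return best_id, best_identity


def select_candidates(pool: Sequence[SequenceRecord],
                      disc_scores: dict[str, float],
                      naturals: Sequence[SequenceRecord],
                      motif: MotifSpec,
                      identity_band: tuple[float, float] = (60.0, 90.0),
                      plddt_table: Optional[dict[str, float]] = None,
                      plddt_min: float = 90.0,
                      n_select: int = 10) -> list[CandidateRecord]:
    """Rank-and-filter selection of sequences for experimental verification.

    Keeps motif-passing records whose nearest-natural identity lies within
    ``identity_band`` (inclusive) and whose plddt, when available, is
    strictly greater than ``plddt_min``; records without a plddt entry are
    kept but flagged unassessed.  Survivors are ranked by discriminator
    score; the top ``n_select`` are marked selected.
    """
    lo, hi = identity_band
    if lo > hi:
        raise ValueError(f"empty identity band [{lo}, {hi}]")
    candidates: list[CandidateRecord] = []
    for rec in pool:
        ok, _ = motif_filter(rec, motif)
        nat_id, ident = nearest_natural(rec, naturals)
        plddt = (plddt_table or {}).get(rec.id)
        assessed = plddt is not None
        keep = ok and lo <= ident <= hi and (not assessed or plddt > plddt_min)
        if keep:
            candidates.append(CandidateRecord(
                rec.id, float(disc_scores[rec.id]), nat_id, ident,
                ok, plddt, assessed, selected=False))
    candidates.sort(key=lambda c: (-c.disc_score, c.id))
    for c in candidates[:n_select]:
        c.selected = True
    return candidates
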