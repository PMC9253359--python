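"""Curli repeat-motif scanning and homolog sequence comparison.

The major curli subunit CsgA is built from five imperfect repeat units
(R1-R5), each carrying the amyloidogenic consensus Q-X4-N-X5-Q: a
glutamine, any four residues, an asparagine, any five residues, a closing
glutamine — a 12-residue signature.  Adjacent repeats can abut and share
their terminal/initial glutamine, so overlapping matches are reported
as-is, with an optional greedy non-overlapping post-filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align

from .errors import SequenceError

__all__ = [
    "ProteinSequence",
    "RepeatMatch",
    "MOTIF_LENGTH",
    "find_curli_repeats",
    "nonoverlapping",
    "percent_identity",
]

#: Q + X4 + N + X5 + Q
MOTIF_LENGTH = 12

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# lookahead makes overlapping windows visible to finditer
_MOTIF_RE = re.compile(r"(?=(Q[A-Z]{4}N[A-Z]{5}Q))")


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence (20 standard residues + X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"{self.id!r}: empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise SequenceError(
                f"{self.id!r}: invalid residue(s) {sorted(bad)}; "
                "expected uppercase one-letter amino-acid codes"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RepeatMatch:
    """A Q-X4-N-X5-Q window, 0-based half-open coordinates."""

    start: int
    end: int
    subsequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != MOTIF_LENGTH:
            raise ValueError("repeat unit must span exactly 12 residues")


def find_curli_repeats(seq: ProteinSequence) -> list[RepeatMatch]:
    """All (possibly overlapping) curli consensus windows, sorted by start.

    A window of 12 residues matches when position 0 is Q, position 5 is N
    and position 11 is Q; the X positions accept any residue including X.
    """
    out = []
    for m in _MOTIF_RE.finditer(seq.residues):
        s = m.start()
        out.append(RepeatMatch(s, s + MOTIF_LENGTH, m.group(1)))
    return out


def nonoverlapping(matches: list[RepeatMatch]) -> list[RepeatMatch]:
    """Greedy left-to-right selection of non-overlapping repeat units."""
    picked: list[RepeatMatch] = []
    cursor = -1
    for m in sorted(matches, key=lambda m: m.start):
        # abutting repeats may share the boundary Q, so a new unit may
        # start on the previous unit's final residue
        if m.start >= cursor:
            picked.append(m)
            cursor = m.end - 1
    return picked


def percent_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Global-alignment percent identity between two sequences.

    Needleman-Wunsch with match +1, mismatch 0 and linear gap penalty -1;
    identity is the number of identical aligned pairs divided by the
    alignment length (gaps included) times 100.  Intended for comparative
    use across homologs; different aligners/objectives give somewhat
    different absolute numbers.
    """
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-1.0,
        extend_gap_score=-1.0,
    )
    aln = aligner.align(a.residues, b.residues)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length
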