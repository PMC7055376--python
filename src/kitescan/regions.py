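"""Kleisin (ScpA) middle-region length via alignment-anchored projection.

The middle region is the ScpA segment between helix α3 and the next
conserved helix — α4 in the Thermococcus onnurineus ScpA N-terminal domain
(residues 107–121), α5 in bacterial ScpAs.  In bacteria this segment carries
the ScpB-binding interface; in most archaea it is markedly shorter.

The measurement fixes two anchor residues on a reference ScpA (defaults:
residue 75, the last ordered position before the disordered stretch, and
residue 107, the first residue of α4), maps them through a pairwise or
multiple alignment, and counts the target's residues strictly between the
two mapped columns.  For the reference against itself the default anchors
give 107 - 75 - 1 = 31 residues.

Lengths are binned descriptively: 30–47 is the typical archaeal range,
61–72 the bacterial range, 48–60 in between.  Binning carries no claim
about ScpB binding — archaeal ScpAs with bacterial-length middle regions
still fail to bind ScpB.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .homology import AlignScoring, global_align_strings

__all__ = [
    "AnchorSet",
    "RegionBin",
    "RegionBreakpoints",
    "RegionLength",
    "middle_region_pairwise",
    "middle_region_msa",
    "bin_length",
]

GAP_CHARACTERS = frozenset("-.")


@dataclass(frozen=True)
class AnchorSet:
    """Two 1-based residue indices on a reference sequence.

    Defaults correspond to the T. onnurineus ScpA N-terminal domain: the
    middle region spans residues 76..106, strictly between the anchors.
    """

    ref_id: str = "ToScpA"
    left_anchor: int = 75
    right_anchor: int = 107

    def __post_init__(self) -> None:
        if not 1 <= self.left_anchor < self.right_anchor:
            raise ValueError(
                f"anchors must satisfy 1 <= left ({self.left_anchor}) "
                f"< right ({self.right_anchor})"
            )

    def validate_for(self, reference: str) -> None:
        if self.right_anchor > len(reference):
            raise ValueError(
                f"right anchor {self.right_anchor} exceeds reference "
                f"length {len(reference)}"
            )

    @property
    def reference_middle_length(self) -> int:
        return self.right_anchor - self.left_anchor - 1


class RegionBin(enum.Enum):
    SHORT_ARCHAEAL = "short_archaeal"
    INTERMEDIATE = "intermediate"
    BACTERIAL_LIKE = "bacterial_like"
    OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class RegionBreakpoints:
    """Inclusive length ranges for the descriptive bins."""

    short_archaeal: tuple[int, int] = (30, 47)
    intermediate: tuple[int, int] = (48, 60)
    bacterial_like: tuple[int, int] = (61, 72)

    def __post_init__(self) -> None:
        for lo, hi in (self.short_archaeal, self.intermediate,
                       self.bacterial_like):
            if lo > hi:
                raise ValueError("breakpoint ranges must be ordered")


@dataclass(frozen=True)
class RegionLength:
    sequence_id: str
    length: int
    method: str  # "pairwise" | "msa"
    bin: RegionBin

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be non-negative")


def bin_length(
    length: int, breakpoints: RegionBreakpoints = RegionBreakpoints()
) -> RegionBin:
    """Assign a middle-region length to a descriptive bin.

    Lengths in the bacterial range always bin ``bacterial_like`` even if a
    configured archaeal range overlaps it.
    """
    lo, hi = breakpoints.bacterial_like
    if lo <= length <= hi:
        return RegionBin.BACTERIAL_LIKE
    lo, hi = breakpoints.short_archaeal
    if lo <= length <= hi:
        return RegionBin.SHORT_ARCHAEAL
    lo, hi = breakpoints.intermediate
    if lo <= length <= hi:
        return RegionBin.INTERMEDIATE
    return RegionBin.OUT_OF_RANGE


def _anchor_columns(ref_row: str, anchors: AnchorSet) -> tuple[int, int]:
    """Column indices of the two anchor residues in a gapped reference row.

    The column actually holding the reference residue defines the boundary;
    gaps never shift anchors.
    """
    col_left = col_right = -1
    residue = 0
    for col, ch in enumerate(ref_row):
        if ch in GAP_CHARACTERS:
            continue
        residue += 1
        if residue == anchors.left_anchor:
            col_left = col
        elif residue == anchors.right_anchor:
            col_right = col
            break
    if col_right < 0:
        raise ValueError(
            f"reference row has fewer than {anchors.right_anchor} residues"
        )
    return col_left, col_right


def middle_region_pairwise(
    target: str,
    reference: str,
    anchors: AnchorSet = AnchorSet(),
    scoring: AlignScoring = AlignScoring(),
    sequence_id: str = "target",
    breakpoints: RegionBreakpoints = RegionBreakpoints(),
) -> RegionLength:
    """Middle-region length of ``target`` by global alignment to the reference.

    A global (not local) alignment is used because both ScpA termini are
    conserved and both anchor residues must be present in the alignment.
    """
    anchors.validate_for(reference)
    ref_row, tgt_row = global_align_strings(reference, target, scoring)
    col_left, col_right = _anchor_columns(ref_row, anchors)
    tgt_row = _resolve_anchor_gap_ambiguity(
        ref_row, tgt_row, col_left, col_right
    )
    segment = tgt_row[col_left + 1 : col_right]
    length = sum(ch not in GAP_CHARACTERS for ch in segment)
    return RegionLength(
        sequence_id=sequence_id,
        length=length,
        method="pairwise",
        bin=bin_length(length, breakpoints),
    )


def _resolve_anchor_gap_ambiguity(
    ref_row: str, tgt_row: str, col_left: int, col_right: int
) -> str:
    """Deterministic tie-break for gaps abutting an anchor column.

    When a deletion in the target removes residues next to an anchor and the
    flanking reference residues are identical, co-optimal alignments differ
    only in which copy the boundary target residue pairs with — leaving it
    either inside the middle region or on the anchor column.  Score-neutral
    slides (exchange of identical reference residues) move such residues
    onto the anchor column, so gaps never shift anchors and the measurement
    does not depend on the aligner's internal traceback order.
    """
    row = list(tgt_row)
    # left anchor: pull the first target residue after a gap block onto it
    while row[col_left] in GAP_CHARACTERS:
        j = col_left
        while j + 1 < len(row) and row[j + 1] in GAP_CHARACTERS:
            j += 1
        k = j + 1
        if (
            k >= len(row)
            or row[k] in GAP_CHARACTERS
            or ref_row[k] in GAP_CHARACTERS
            or ref_row[k] != ref_row[col_left]
        ):
            break
        row[col_left], row[k] = row[k], row[col_left]
    # right anchor: symmetric
    while row[col_right] in GAP_CHARACTERS:
        i = col_right
        while i - 1 >= 0 and row[i - 1] in GAP_CHARACTERS:
            i -= 1
        k = i - 1
        if (
            k < 0
            or row[k] in GAP_CHARACTERS
            or ref_row[k] in GAP_CHARACTERS
            or ref_row[k] != ref_row[col_right]
        ):
            break
        row[col_right], row[k] = row[k], row[col_right]
    return "".join(row)


def middle_region_msa(
    alignment: Iterable[tuple[str, str]] | "object",
    ref_row_id: str,
    anchors: AnchorSet = AnchorSet(),
    breakpoints: RegionBreakpoints = RegionBreakpoints(),
) -> list[RegionLength]:
    """Middle-region lengths for every row of a multiple alignment.

    ``alignment`` may be a Biopython ``MultipleSeqAlignment`` or any iterable
    of ``(id, gapped sequence)`` pairs of equal length.
    """
    rows = _as_rows(alignment)
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != width:
            raise ValueError(
                f"ragged alignment: row {rid!r} has length {len(seq)}, "
                f"expected {width}"
            )
    ref_row = next((seq for rid, seq in rows if rid == ref_row_id), None)
    if ref_row is None:
        raise KeyError(f"reference row {ref_row_id!r} not in alignment")
    col_left, col_right = _anchor_columns(ref_row, anchors)
    out = []
    for rid, seq in rows:
        segment = seq[col_left + 1 : col_right]
        length = sum(ch not in GAP_CHARACTERS for ch in segment)
        out.append(
            RegionLength(
                sequence_id=rid,
                length=length,
                method="msa",
                bin=bin_length(length, breakpoints),
            )
        )
    return out


def _as_rows(alignment) -> list[tuple[str, str]]:
    if hasattr(alignment, "__iter__") and hasattr(alignment, "__len__"):
        try:
            from Bio.Align import MultipleSeqAlignment

            if isinstance(alignment, MultipleSeqAlignment):
                return [(rec.id, str(rec.seq)) for rec in alignment]
        except ImportError:  # pragma: no cover
            pass
    return [(rid, str(seq)) for rid, seq in alignment]


def region_lengths_table(lengths: Sequence[RegionLength]):
    """Region lengths as a pandas DataFrame (sequence_id, length, method, bin)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in lengths],
            "length": [r.length for r in lengths],
            "method": [r.method for r in lengths],
            "bin": [r.bin.value for r in lengths],
        }
    )
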