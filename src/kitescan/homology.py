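"""Homology evidence and acceptance rules.

Presence calls fall back to homology when a gene is annotated under another
name ("hypothetical protein" being the usual culprit).  Evidence is an
identity/coverage pair from a local alignment (built-in aligner or an
imported BLAST tabular file) or an E-value from an imported HMMER table.

Acceptance cutoffs, all strict inequalities:

* general rule -- identity > 20% and query coverage > 70% (any class);
* kleisin rescue rule -- identity > 50% and coverage > 25% (ScpA only,
  because often only the conserved N-terminal domain of the query aligns);
* HMM rule -- E-value < 1e-4 for ScpA and ScpB, < 1e-100 for Smc (higher
  E-values routinely belong to unrelated annotations).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, TextIO

from Bio import Align
from Bio.Align import substitution_matrices

from .targets import TargetClass

__all__ = [
    "HomologyHit",
    "ThresholdRuleSet",
    "AlignScoring",
    "local_align",
    "global_align_strings",
    "classify_hit",
    "classify_hmm_hit",
    "read_hit_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class HomologyHit:
    """Alignment- or HMM-based evidence linking a query to a subject protein.

    HMM hits carry only an E-value; they are represented with
    ``aln_columns == 0`` and zero identity/coverage.
    """

    query_id: str
    subject_id: str
    identity: float
    query_coverage: float
    evalue: float | None
    aln_columns: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.aln_columns > 0 and not 0.0 < self.query_coverage <= 1.0:
            raise ValueError(
                f"coverage {self.query_coverage} outside (0, 1] for an "
                f"alignment of {self.aln_columns} columns"
            )
        if self.evalue is not None and self.evalue <= 0:
            raise ValueError("evalue must be positive")


def _default_hmm_evalues() -> dict[TargetClass, float]:
    return {
        TargetClass.SCPA: 1e-4,
        TargetClass.SCPB: 1e-4,
        TargetClass.SMC: 1e-100,
    }


@dataclass(frozen=True)
class ThresholdRuleSet:
    general_identity: float = 0.20
    general_coverage: float = 0.70
    scpA_identity: float = 0.50
    scpA_coverage: float = 0.25
    hmm_evalue: Mapping[TargetClass, float] = field(
        default_factory=_default_hmm_evalues
    )

    def __post_init__(self) -> None:
        for name in ("general_identity", "general_coverage",
                     "scpA_identity", "scpA_coverage"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        for cls, ev in self.hmm_evalue.items():
            if ev <= 0:
                raise ValueError(f"hmm_evalue[{cls}] must be positive")


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap protein scoring; defaults are BLAST's protein defaults.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


_matrix_cache: dict[str, substitution_matrices.Array] = {}


def _substitution_matrix(name: str) -> substitution_matrices.Array:
    """Load a substitution matrix with X neutralized (scored 0 vs anything)."""
    if name not in _matrix_cache:
        m = substitution_matrices.load(name).copy()
        if "X" in m.alphabet:
            for a in m.alphabet:
                m["X", a] = 0.0
                m[a, "X"] = 0.0
        _matrix_cache[name] = m
    return _matrix_cache[name]


def _make_aligner(scoring: AlignScoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _substitution_matrix(scoring.matrix)
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    aligner.mode = mode
    return aligner


def _validate_sequence(seq: str, role: str) -> None:
    if not seq:
        raise ValueError(f"{role} sequence is empty")
    for i, ch in enumerate(seq):
        if ch not in _ALPHABET:
            raise ValueError(
                f"{role} sequence: non-amino-acid character {ch!r} "
                f"at position {i + 1}"
            )


def local_align(
    query: str,
    subject: str,
    scoring: AlignScoring = AlignScoring(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> HomologyHit:
    """Optimal affine-gap local alignment of two protein sequences.

    Identity is identical aligned pairs over all alignment columns (gap
    columns included in the denominator, the BLAST ``pident`` convention);
    coverage is the query span of the single best local alignment over the
    query length.  If no positively scoring local alignment exists the hit
    has zero columns, identity and coverage.
    """
    _validate_sequence(query, "query")
    _validate_sequence(subject, "subject")
    aligner = _make_aligner(scoring, "local")
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return HomologyHit(query_id, subject_id, 0.0, 0.0, None, 0)
    aln = alignments[0]
    row_q, row_s = str(aln[0]), str(aln[1])
    columns = len(row_q)
    ident = sum(a == b and a != "-" for a, b in zip(row_q, row_s))
    q_blocks = aln.aligned[0]
    span = int(q_blocks[-1][1] - q_blocks[0][0])
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=ident / columns,
        query_coverage=span / len(query),
        evalue=None,
        aln_columns=columns,
    )


def global_align_strings(
    seq_a: str, seq_b: str, scoring: AlignScoring = AlignScoring()
) -> tuple[str, str]:
    """Global affine-gap alignment; returns the two gapped row strings."""
    _validate_sequence(seq_a, "first")
    _validate_sequence(seq_b, "second")
    aligner = _make_aligner(scoring, "global")
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def classify_hit(
    hit: HomologyHit,
    target: TargetClass,
    rules: ThresholdRuleSet = ThresholdRuleSet(),
) -> bool:
    """Apply the identity/coverage acceptance rules (strict inequalities)."""
    if (hit.identity > rules.general_identity
            and hit.query_coverage > rules.general_coverage):
        return True
    if target is TargetClass.SCPA:
        return (hit.identity > rules.scpA_identity
                and hit.query_coverage > rules.scpA_coverage)
    return False


def classify_hmm_hit(
    evalue: float,
    target: TargetClass,
    rules: ThresholdRuleSet = ThresholdRuleSet(),
) -> bool:
    """Accept an HMM hit when its E-value is strictly below the class cutoff."""
    if evalue <= 0:
        raise ValueError("evalue must be positive")
    return evalue < rules.hmm_evalue[target]


_BLAST12_COLUMNS = 12


def read_hit_table(
    stream: TextIO | str,
    dialect: str,
    query_lengths: Mapping[str, int] | None = None,
) -> list[HomologyHit]:
    """Read externally computed hits.

    ``blast_tab12`` is BLAST ``-outfmt 6`` (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore); identity is
    rescaled from percent, and query coverage is computed from the qstart/qend
    span and the supplied ``query_lengths`` map.  ``hmmer_tbl`` is HMMER3
    ``--tblout``; rows populate the E-value only.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if dialect not in ("blast_tab12", "hmmer_tbl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[HomologyHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if dialect == "blast_tab12":
            cols = line.split("\t")
            if len(cols) != _BLAST12_COLUMNS:
                raise ValueError(
                    f"line {lineno}: expected {_BLAST12_COLUMNS} columns, "
                    f"found {len(cols)}"
                )
            qid, sid = cols[0], cols[1]
            if query_lengths is None or qid not in query_lengths:
                raise ValueError(
                    f"line {lineno}: no query length supplied for {qid!r}"
                )
            qstart, qend = int(cols[6]), int(cols[7])
            hits.append(
                HomologyHit(
                    query_id=qid,
                    subject_id=sid,
                    identity=float(cols[2]) / 100.0,
                    query_coverage=(abs(qend - qstart) + 1) / query_lengths[qid],
                    evalue=float(cols[10]),
                    aln_columns=int(cols[3]),
                )
            )
        else:  # hmmer_tbl
            cols = line.split()
            if len(cols) < 5:
                raise ValueError(
                    f"line {lineno}: expected >= 5 whitespace-separated "
                    f"columns, found {len(cols)}"
                )
            hits.append(
                HomologyHit(
                    query_id=cols[2],
                    subject_id=cols[0],
                    identity=0.0,
                    query_coverage=0.0,
                    evalue=float(cols[4]),
                    aln_columns=0,
                )
            )
    return hits
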