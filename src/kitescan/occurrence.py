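"""Per-genome presence/absence calls for smc, scpA and scpB.

The primary evidence is a case-insensitive substring search of product
names; a genome whose annotation misses a class can be rescued by homology
evidence (alignment hits or imported HMM tables) classified under the
threshold rules.  String evidence always dominates homology evidence,
mirroring the two-step search order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotations import GeneFeature, GenomeAnnotation, searchable_features
from .homology import HomologyHit, ThresholdRuleSet, classify_hit, classify_hmm_hit
from .targets import ALL_TARGETS, TargetClass

__all__ = [
    "TargetClass",
    "PatternSet",
    "CallStatus",
    "OccurrenceCall",
    "string_match",
    "call_occurrence",
    "find_outliers",
]

DEFAULT_PATTERNS: dict[TargetClass, tuple[str, ...]] = {
    TargetClass.SMC: ("chromosome segregation protein SMC",),
    TargetClass.SCPA: ("segregation/condensation protein A", "ScpA"),
    TargetClass.SCPB: ("segregation and condensation protein B", "ScpB"),
}


@dataclass(frozen=True)
class PatternSet:
    """Product-name search strings per gene class (plain substrings)."""

    patterns: Mapping[TargetClass, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_PATTERNS)
    )

    def for_target(self, target: TargetClass) -> Sequence[str]:
        if target not in self.patterns:
            raise KeyError(f"no patterns configured for {target}")
        return self.patterns[target]


class CallStatus(enum.Enum):
    FOUND_BY_STRING = "found_by_string"
    FOUND_BY_HOMOLOGY = "found_by_homology"
    ABSENT = "absent"


@dataclass(frozen=True)
class OccurrenceCall:
    assembly_id: str
    target: TargetClass
    status: CallStatus
    is_pseudo: bool = False
    locus_tags: tuple[str, ...] = ()
    evidence: HomologyHit | None = None

    def __post_init__(self) -> None:
        if self.status is CallStatus.ABSENT and self.locus_tags:
            raise ValueError("absent call cannot carry locus tags")
        if self.is_pseudo and self.status is CallStatus.ABSENT:
            raise ValueError("pseudogene mark implies presence")

    @property
    def present(self) -> bool:
        return self.status is not CallStatus.ABSENT


def string_match(
    annotation: GenomeAnnotation,
    target: TargetClass,
    patterns: PatternSet = PatternSet(),
) -> list[GeneFeature]:
    """Searchable features whose product contains any pattern (case folded)."""
    needles = [p.lower() for p in patterns.for_target(target)]
    return [
        f
        for f in searchable_features(annotation)
        if f.product and any(n in f.product.lower() for n in needles)
    ]


def _hit_passes(hit: HomologyHit, target: TargetClass, rules: ThresholdRuleSet) -> bool:
    if hit.aln_columns > 0:
        return classify_hit(hit, target, rules)
    if hit.evalue is None:
        return False
    return classify_hmm_hit(hit.evalue, target, rules)


def call_occurrence(
    annotation: GenomeAnnotation,
    patterns: PatternSet = PatternSet(),
    homology_evidence: Mapping[TargetClass, Sequence[HomologyHit]] | None = None,
    rules: ThresholdRuleSet = ThresholdRuleSet(),
) -> dict[TargetClass, OccurrenceCall]:
    """Call all three classes for one genome.

    Paralogs collapse to a single call per class (the survey counts species,
    not genes); ``is_pseudo`` is set only when every matching feature is
    pseudogene-flagged.
    """
    calls: dict[TargetClass, OccurrenceCall] = {}
    for target in ALL_TARGETS:
        feats = string_match(annotation, target, patterns)
        if feats:
            calls[target] = OccurrenceCall(
                assembly_id=annotation.assembly_id,
                target=target,
                status=CallStatus.FOUND_BY_STRING,
                is_pseudo=all(f.is_pseudo for f in feats),
                locus_tags=tuple(f.locus_tag for f in feats),
            )
            continue
        passing = [
            h
            for h in (homology_evidence or {}).get(target, ())
            if _hit_passes(h, target, rules)
        ]
        if passing:
            best = max(
                passing,
                key=lambda h: (h.identity, h.query_coverage,
                               -(h.evalue or 0.0)),
            )
            calls[target] = OccurrenceCall(
                assembly_id=annotation.assembly_id,
                target=target,
                status=CallStatus.FOUND_BY_HOMOLOGY,
                is_pseudo=False,
                locus_tags=tuple(dict.fromkeys(h.subject_id for h in passing)),
                evidence=best,
            )
        else:
            calls[target] = OccurrenceCall(
                assembly_id=annotation.assembly_id,
                target=target,
                status=CallStatus.ABSENT,
            )
    return calls


def find_outliers(
    calls_by_species: Mapping[str, Iterable[OccurrenceCall]],
) -> list[tuple[str, list[TargetClass]]]:
    """Species missing at least one class, with the absent classes named."""
    outliers = []
    for species, calls in calls_by_species.items():
        by_target = {c.target: c for c in calls}
        missing_targets = set(ALL_TARGETS) - set(by_target)
        if missing_targets:
            raise ValueError(
                f"{species}: no call for {sorted(t.value for t in missing_targets)}"
            )
        absent = [t for t in ALL_TARGETS if by_target[t].status is CallStatus.ABSENT]
        if absent:
            outliers.append((species, absent))
    return outliers
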