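"""Gene-neighborhood relations: adjacency, intervening genes, flanking products.

"Neighbors" means zero searchable (protein-coding or pseudogene) features
between two loci on the same replicon; strand and base-pair distance play no
role.  Genes on different replicons are "remote" (not comparable).  Replicons
are linear by default; ``circular=True`` also considers the wrap-around path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .annotations import GeneFeature, GenomeAnnotation, searchable_features
from .occurrence import CallStatus, OccurrenceCall
from .targets import TargetClass

__all__ = [
    "AdjacencyCall",
    "intervening_gene_count",
    "flanking_products",
    "pairwise_synteny",
]


@dataclass(frozen=True)
class AdjacencyCall:
    locus_a: str
    locus_b: str
    comparable: bool
    intervening: int | None
    neighbors: bool

    def __post_init__(self) -> None:
        if self.comparable and self.intervening is None:
            raise ValueError("comparable pair needs an intervening count")
        if self.neighbors != (self.comparable and self.intervening == 0):
            raise ValueError("neighbors iff comparable with zero intervening")


def _searchable_index(
    annotation: GenomeAnnotation,
) -> dict[str, tuple[str, int, int]]:
    """locus_tag -> (replicon, index within replicon, replicon gene count)."""
    per_replicon: dict[str, list[GeneFeature]] = {}
    for f in searchable_features(annotation):
        per_replicon.setdefault(f.replicon_id, []).append(f)
    index = {}
    for replicon, feats in per_replicon.items():
        for i, f in enumerate(feats):
            index[f.locus_tag] = (replicon, i, len(feats))
    return index


def intervening_gene_count(
    annotation: GenomeAnnotation,
    locus_a: str,
    locus_b: str,
    circular: bool = False,
) -> AdjacencyCall:
    """Count searchable genes strictly between two loci.

    On a circular replicon the shorter of the two paths is reported.
    """
    if locus_a == locus_b:
        raise ValueError(f"identical loci {locus_a!r}")
    index = _searchable_index(annotation)
    for locus in (locus_a, locus_b):
        if locus not in index:
            raise KeyError(
                f"unknown locus {locus!r} in {annotation.assembly_id}"
            )
    rep_a, ia, na = index[locus_a]
    rep_b, ib, _ = index[locus_b]
    if rep_a != rep_b:
        return AdjacencyCall(locus_a, locus_b, False, None, False)
    between = abs(ia - ib) - 1
    if circular:
        between = min(between, na - abs(ia - ib) - 1)
    return AdjacencyCall(locus_a, locus_b, True, between, between == 0)


def flanking_products(
    annotation: GenomeAnnotation, locus: str
) -> tuple[GeneFeature | None, GeneFeature | None]:
    """Immediate previous/next searchable features on the same replicon.

    Returns ``None`` on a side where the locus is the first or last gene of
    its replicon.
    """
    feats = searchable_features(annotation)
    per_replicon: dict[str, list[GeneFeature]] = {}
    for f in feats:
        per_replicon.setdefault(f.replicon_id, []).append(f)
    for replicon_feats in per_replicon.values():
        for i, f in enumerate(replicon_feats):
            if f.locus_tag == locus:
                upstream = replicon_feats[i - 1] if i > 0 else None
                downstream = (
                    replicon_feats[i + 1]
                    if i + 1 < len(replicon_feats)
                    else None
                )
                return upstream, downstream
    raise KeyError(f"unknown locus {locus!r} in {annotation.assembly_id}")


def _best_pair(
    annotation: GenomeAnnotation,
    loci_a: tuple[str, ...],
    loci_b: tuple[str, ...],
    circular: bool,
) -> AdjacencyCall | None:
    """Adjacency of the locus pair minimizing the intervening count."""
    index = _searchable_index(annotation)
    best: AdjacencyCall | None = None
    for a in loci_a:
        for b in loci_b:
            if a == b or a not in index or b not in index:
                continue
            call = intervening_gene_count(annotation, a, b, circular)
            if best is None:
                best = call
            elif call.comparable and (
                not best.comparable or call.intervening < best.intervening
            ):
                best = call
    return best


def pairwise_synteny(
    calls: Mapping[TargetClass, OccurrenceCall],
    annotation: GenomeAnnotation,
    circular: bool = False,
) -> tuple[AdjacencyCall | None, AdjacencyCall | None]:
    """Adjacency of (smc, scpA) and (scpA, scpB) for one genome.

    ``None`` when either member of a pair is absent; when a class matched
    several loci the pair with the fewest intervening genes is reported.
    """
    results = []
    for first, second in (
        (TargetClass.SMC, TargetClass.SCPA),
        (TargetClass.SCPA, TargetClass.SCPB),
    ):
        ca, cb = calls.get(first), calls.get(second)
        if (
            ca is None
            or cb is None
            or ca.status is CallStatus.ABSENT
            or cb.status is CallStatus.ABSENT
        ):
            results.append(None)
            continue
        results.append(
            _best_pair(annotation, ca.locus_tags, cb.locus_tags, circular)
        )
    return results[0], results[1]
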