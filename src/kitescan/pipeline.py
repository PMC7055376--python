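"""End-to-end survey: annotations + proteomes in, three-part report out.

For each genome the product-string search runs first; only classes it
misses trigger the homology fallback, in which a per-class query protein is
locally aligned against every protein of that genome and the hits are
classified under the threshold rules.  Imported BLAST/HMMER tables can
replace or supplement the built-in aligner.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import SeqIO

from .annotations import GenomeAnnotation
from .homology import AlignScoring, HomologyHit, ThresholdRuleSet, local_align
from .occurrence import OccurrenceCall, PatternSet, call_occurrence, string_match
from .report import ThreePartOutput, build_report
from .synteny import AdjacencyCall, pairwise_synteny
from .synthetic_data import SEED_PROTEINS
from .targets import ALL_TARGETS, TargetClass

__all__ = ["GenomeInput", "scan_genome", "scan_cohort", "read_fasta"]


def read_fasta(stream) -> dict[str, str]:
    """Protein FASTA as an id -> sequence mapping (order preserved)."""
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(stream, "fasta")}


@dataclass
class GenomeInput:
    annotation: GenomeAnnotation
    proteins: Mapping[str, str] | None = None
    # externally computed evidence, already read via homology.read_hit_table
    imported_hits: Mapping[TargetClass, Sequence[HomologyHit]] | None = None
    hmm_hits: Mapping[TargetClass, Sequence[HomologyHit]] | None = None


def _alignment_evidence(
    genome: GenomeInput,
    missing: Sequence[TargetClass],
    queries: Mapping[TargetClass, str],
    scoring: AlignScoring,
) -> dict[TargetClass, list[HomologyHit]]:
    evidence: dict[TargetClass, list[HomologyHit]] = {}
    for target in missing:
        hits = list((genome.imported_hits or {}).get(target, ()))
        query = queries.get(target)
        if query and genome.proteins:
            for subject_id, subject in genome.proteins.items():
                hits.append(
                    local_align(
                        query,
                        subject,
                        scoring,
                        query_id=f"query_{target.value}",
                        subject_id=subject_id,
                    )
                )
        evidence[target] = hits
    return evidence


def scan_genome(
    genome: GenomeInput,
    patterns: PatternSet = PatternSet(),
    rules: ThresholdRuleSet = ThresholdRuleSet(),
    scoring: AlignScoring = AlignScoring(),
    queries: Mapping[TargetClass, str] | None = None,
    circular: bool = False,
) -> tuple[
    dict[TargetClass, OccurrenceCall],
    tuple[AdjacencyCall | None, AdjacencyCall | None],
]:
    """Occurrence calls plus (smc-scpA, scpA-scpB) adjacency for one genome."""
    if queries is None:
        queries = SEED_PROTEINS
    missing = [
        t
        for t in ALL_TARGETS
        if not string_match(genome.annotation, t, patterns)
    ]
    evidence = _alignment_evidence(genome, missing, queries, scoring)
    calls = call_occurrence(genome.annotation, patterns, evidence, rules)
    synteny = pairwise_synteny(calls, genome.annotation, circular)
    return calls, synteny


def _hmm_occurrence(
    genome: GenomeInput, rules: ThresholdRuleSet
) -> dict[TargetClass, OccurrenceCall] | None:
    if genome.hmm_hits is None:
        return None
    return call_occurrence(
        genome.annotation,
        patterns=PatternSet({t: () for t in ALL_TARGETS}),
        homology_evidence=genome.hmm_hits,
        rules=rules,
    )


def scan_cohort(
    genomes: Sequence[GenomeInput],
    patterns: PatternSet = PatternSet(),
    rules: ThresholdRuleSet = ThresholdRuleSet(),
    scoring: AlignScoring = AlignScoring(),
    queries: Mapping[TargetClass, str] | None = None,
    circular: bool = False,
    subtract_pseudo_in_hmm: bool = True,
    dedupe_species: bool = True,
) -> ThreePartOutput:
    """Run the full survey over a cohort and build the three-part report."""
    cohort = []
    hmm_calls = {}
    for genome in genomes:
        calls, synteny = scan_genome(
            genome, patterns, rules, scoring, queries, circular
        )
        cohort.append((genome.annotation, calls, synteny))
        hmm = _hmm_occurrence(genome, rules)
        if hmm is not None:
            hmm_calls[genome.annotation.assembly_id] = hmm
    return build_report(
        cohort,
        hmm_calls=hmm_calls or None,
        subtract_pseudo_in_hmm=subtract_pseudo_in_hmm,
        dedupe_species=dedupe_species,
    )


def verify_against_truth(cohort, anchors=None, **scan_kwargs) -> list[str]:
    """Run the full pipeline on a synthetic cohort and diff against its truth.

    Returns a list of human-readable mismatch descriptions (empty when the
    pipeline reproduces the ground truth exactly).  Checks per-genome
    occurrence statuses and pseudogene flags, the two pairwise adjacency
    relations, the measured ScpA middle-region length and the aggregated
    per-order report counts.
    """
    from .annotations import parse_gff3
    from .regions import AnchorSet, middle_region_pairwise

    if anchors is None:
        anchors = AnchorSet()
    mismatches: list[str] = []
    truth = cohort.truth.set_index("assembly_id")
    records = []
    inputs = []
    for genome in cohort.genomes:
        annotation = parse_gff3(
            genome.gff_text, genome.assembly_id,
            cohort.taxonomy[genome.assembly_id],
        )
        gin = GenomeInput(annotation=annotation, proteins=genome.proteins)
        inputs.append(gin)
        calls, synteny = scan_genome(gin, **scan_kwargs)
        records.append((annotation, calls, synteny))
        row = truth.loc[genome.assembly_id]

        for target, col in ((TargetClass.SMC, "smc"),
                            (TargetClass.SCPA, "scpA"),
                            (TargetClass.SCPB, "scpB")):
            call = calls[target]
            if call.status.value != row[f"{col}_status"]:
                mismatches.append(
                    f"{genome.assembly_id} {col}: status "
                    f"{call.status.value} != {row[f'{col}_status']}"
                )
            if call.is_pseudo != bool(row[f"{col}_pseudo"]):
                mismatches.append(
                    f"{genome.assembly_id} {col}: pseudo flag "
                    f"{call.is_pseudo} != {row[f'{col}_pseudo']}"
                )

        for adj, prefix in zip(synteny, ("smc_scpA", "scpA_scpB")):
            import pandas as pd

            expected = row[f"{prefix}_intervening"]
            expected_nb = bool(row[f"{prefix}_neighbors"])
            if expected is None or pd.isna(expected):
                if adj is not None:
                    mismatches.append(
                        f"{genome.assembly_id} {prefix}: expected no "
                        f"adjacency call, got {adj}"
                    )
                continue
            if adj is None:
                mismatches.append(
                    f"{genome.assembly_id} {prefix}: expected {expected}, "
                    f"got no adjacency call"
                )
                continue
            if str(expected) == "remote":
                if adj.comparable:
                    mismatches.append(
                        f"{genome.assembly_id} {prefix}: expected remote, "
                        f"got intervening {adj.intervening}"
                    )
            elif adj.intervening != int(expected):
                mismatches.append(
                    f"{genome.assembly_id} {prefix}: intervening "
                    f"{adj.intervening} != {expected}"
                )
            if adj is not None and adj.neighbors != expected_nb:
                mismatches.append(
                    f"{genome.assembly_id} {prefix}: neighbors "
                    f"{adj.neighbors} != {expected_nb}"
                )

        import pandas as pd

        expected_len = row["scpA_middle_length"]
        if expected_len is not None and not pd.isna(expected_len):
            scpa_call = records[-1][1][TargetClass.SCPA]
            locus = row["scpA_locus"]
            seq = genome.proteins.get(locus)
            if seq is None:
                mismatches.append(
                    f"{genome.assembly_id}: truth expects a ScpA protein "
                    f"at {locus} but none was generated"
                )
            else:
                measured = middle_region_pairwise(
                    seq, SEED_PROTEINS[TargetClass.SCPA], anchors
                ).length
                if measured != int(expected_len):
                    mismatches.append(
                        f"{genome.assembly_id}: middle region {measured} "
                        f"!= {int(expected_len)}"
                    )

    # aggregated report counts against truth-derived aggregation
    from .report import build_report

    report = build_report(records, dedupe_species=False)
    frame = report.analyses.per_order.set_index("order")
    t = cohort.truth
    expected_orders = t.groupby("order", sort=False)
    for order, group in expected_orders:
        if order not in frame.index:
            mismatches.append(f"order {order} missing from report")
            continue
        row = frame.loc[order]
        checks = {
            "n_species": len(group),
            "n_smc": (group["smc_status"] != "absent").sum(),
            "n_scpA": (group["scpA_status"] != "absent").sum(),
            "n_scpB": (group["scpB_status"] != "absent").sum(),
            "n_smc_scpA_neighbors": group["smc_scpA_neighbors"].sum(),
            "n_scpA_scpB_neighbors": group["scpA_scpB_neighbors"].sum(),
            "n_pseudo_smc": group["smc_pseudo"].sum(),
            "n_pseudo_scpA": group["scpA_pseudo"].sum(),
            "n_pseudo_scpB": group["scpB_pseudo"].sum(),
        }
        for col, expected in checks.items():
            if int(row[col]) != int(expected):
                mismatches.append(
                    f"order {order}: {col} {int(row[col])} != {int(expected)}"
                )

    n_outliers = len(report.outliers)
    expected_outliers = int(
        (
            (t["smc_status"] == "absent")
            | (t["scpA_status"] == "absent")
            | (t["scpB_status"] == "absent")
        ).sum()
    )
    if n_outliers != expected_outliers:
        mismatches.append(
            f"outliers {n_outliers} != {expected_outliers}"
        )
    return mismatches
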