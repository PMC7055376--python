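"""Cohort aggregation: the three-part output and per-order count table.

The survey's output has three parts.  *Results* lists, per species, the
taxonomy, the locus tags called for each class and the products flanking
scpA.  *Analyses* is the per-order count table: species containing each
gene (string/alignment evidence and, separately, imported HMM evidence),
species with smc-scpA and scpA-scpB juxtaposed, and pseudogene-marked genes
per class.  *Outliers* names the species in which any class is absent.

When one species has several assemblies only the first (by assembly-id
sort) contributes, so every count is a species count.  Pseudogene-marked
genes count as present in the string/alignment columns; in the HMM columns
they are subtracted by default (``subtract_pseudo_in_hmm``), reproducing
the convention that an HMM column can run one or two lower than the
corresponding alignment column because of pseudogene annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotations import GenomeAnnotation
from .occurrence import CallStatus, OccurrenceCall, find_outliers
from .synteny import AdjacencyCall, flanking_products
from .targets import ALL_TARGETS, TargetClass

__all__ = ["CohortReport", "ThreePartOutput", "build_report", "render"]

ANALYSES_COLUMNS = [
    "order",
    "n_species",
    "n_smc",
    "n_scpA",
    "n_scpB",
    "n_smc_hmm",
    "n_scpA_hmm",
    "n_scpB_hmm",
    "n_smc_scpA_neighbors",
    "n_scpA_scpB_neighbors",
    "n_pseudo_smc",
    "n_pseudo_scpA",
    "n_pseudo_scpB",
]


@dataclass
class CohortReport:
    """Per-order occurrence and juxtaposition counts."""

    per_order: pd.DataFrame
    hmm_supplied: bool = False

    def __post_init__(self) -> None:
        if list(self.per_order.columns) != ANALYSES_COLUMNS:
            raise ValueError("unexpected Analyses column layout")

    @property
    def total_species(self) -> int:
        return int(self.per_order["n_species"].sum())


@dataclass
class ThreePartOutput:
    results: list[dict]
    analyses: CohortReport
    outliers: list[tuple[str, list[TargetClass]]] = field(default_factory=list)


GenomeRecord = tuple[
    GenomeAnnotation,
    Mapping[TargetClass, OccurrenceCall],
    tuple[AdjacencyCall | None, AdjacencyCall | None],
]


def _dedupe_by_species(cohort: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    ordered = sorted(cohort, key=lambda rec: rec[0].assembly_id)
    seen: set[str] = set()
    out = []
    for rec in ordered:
        if rec[0].species in seen:
            continue
        seen.add(rec[0].species)
        out.append(rec)
    return out


def build_report(
    cohort: Sequence[GenomeRecord],
    hmm_calls: Mapping[str, Mapping[TargetClass, OccurrenceCall]] | None = None,
    subtract_pseudo_in_hmm: bool = True,
    dedupe_species: bool = True,
) -> ThreePartOutput:
    """Aggregate per-genome calls into the three-part output.

    ``hmm_calls`` maps assembly_id to an independent set of occurrence calls
    derived from imported HMM hit tables; the HMM columns stay zero when it
    is not supplied.
    """
    for annotation, _, _ in cohort:
        if annotation.taxonomy is None:
            raise ValueError(
                f"genome {annotation.assembly_id} has no taxonomy"
            )
    records = _dedupe_by_species(cohort) if dedupe_species else list(cohort)

    results = []
    per_order: dict[str, dict[str, int]] = {}
    calls_by_species: dict[str, list[OccurrenceCall]] = {}
    order_first_seen: list[str] = []

    for annotation, calls, (smc_scpa, scpa_scpb) in records:
        taxon = annotation.taxonomy
        order = taxon.order
        if order not in per_order:
            per_order[order] = {c: 0 for c in ANALYSES_COLUMNS if c != "order"}
            order_first_seen.append(order)
        row = per_order[order]
        row["n_species"] += 1

        for target, column in (
            (TargetClass.SMC, "smc"),
            (TargetClass.SCPA, "scpA"),
            (TargetClass.SCPB, "scpB"),
        ):
            call = calls[target]
            if call.present:
                row[f"n_{column}"] += 1
            if call.is_pseudo:
                row[f"n_pseudo_{column}"] += 1
            if hmm_calls and annotation.assembly_id in hmm_calls:
                hmm_call = hmm_calls[annotation.assembly_id].get(target)
                hmm_present = hmm_call is not None and hmm_call.present
                if hmm_present and subtract_pseudo_in_hmm and call.is_pseudo:
                    hmm_present = False
                if hmm_present:
                    row[f"n_{column}_hmm"] += 1

        if smc_scpa is not None and smc_scpa.neighbors:
            row["n_smc_scpA_neighbors"] += 1
        if scpa_scpb is not None and scpa_scpb.neighbors:
            row["n_scpA_scpB_neighbors"] += 1

        calls_by_species[annotation.species] = [calls[t] for t in ALL_TARGETS]

        scpa_call = calls[TargetClass.SCPA]
        flank_up = flank_down = None
        if scpa_call.locus_tags:
            try:
                up, down = flanking_products(annotation, scpa_call.locus_tags[0])
                flank_up = (up.locus_tag, up.product) if up else None
                flank_down = (down.locus_tag, down.product) if down else None
            except KeyError:
                pass  # homology call naming a protein absent from the GFF
        results.append(
            {
                "species": annotation.species,
                "assembly_id": annotation.assembly_id,
                "phylum": taxon.phylum,
                "class": taxon.class_,
                "order": order,
                "smc_loci": list(calls[TargetClass.SMC].locus_tags),
                "scpA_loci": list(scpa_call.locus_tags),
                "scpB_loci": list(calls[TargetClass.SCPB].locus_tags),
                "smc_status": calls[TargetClass.SMC].status.value,
                "scpA_status": scpa_call.status.value,
                "scpB_status": calls[TargetClass.SCPB].status.value,
                "scpA_flank_upstream": flank_up,
                "scpA_flank_downstream": flank_down,
            }
        )

    frame = pd.DataFrame(
        [{"order": order, **per_order[order]} for order in order_first_seen],
        columns=ANALYSES_COLUMNS,
    )
    if frame.empty:
        frame = pd.DataFrame(columns=ANALYSES_COLUMNS)
    report = CohortReport(per_order=frame, hmm_supplied=bool(hmm_calls))
    outliers = find_outliers(calls_by_species)
    return ThreePartOutput(results=results, analyses=report, outliers=outliers)


def render(report: ThreePartOutput, format: str) -> str:
    """Serialize the three-part output deterministically as ``tsv`` or ``json``."""
    if format == "tsv":
        return _render_tsv(report)
    if format == "json":
        return _render_json(report)
    raise ValueError(f"unknown format {format!r}")


def _flank_str(flank) -> str:
    return f"{flank[0]}|{flank[1]}" if flank else ""


def _render_tsv(report: ThreePartOutput) -> str:
    lines = ["## Results"]
    header = [
        "species", "assembly_id", "phylum", "class", "order",
        "smc_status", "scpA_status", "scpB_status",
        "smc_loci", "scpA_loci", "scpB_loci",
        "scpA_flank_upstream", "scpA_flank_downstream",
    ]
    lines.append("\t".join(header))
    for rec in report.results:
        lines.append(
            "\t".join(
                [
                    rec["species"], rec["assembly_id"], rec["phylum"],
                    rec["class"], rec["order"],
                    rec["smc_status"], rec["scpA_status"], rec["scpB_status"],
                    ",".join(rec["smc_loci"]),
                    ",".join(rec["scpA_loci"]),
                    ",".join(rec["scpB_loci"]),
                    _flank_str(rec["scpA_flank_upstream"]),
                    _flank_str(rec["scpA_flank_downstream"]),
                ]
            )
        )
    lines.append("")
    lines.append("## Analyses")
    lines.append(
        report.analyses.per_order.to_csv(sep="\t", index=False).rstrip("\n")
    )
    lines.append("")
    lines.append("## Outliers")
    lines.append("species\tmissing")
    for species, missing in report.outliers:
        lines.append(f"{species}\t{','.join(t.value for t in missing)}")
    return "\n".join(lines) + "\n"


def _render_json(report: ThreePartOutput) -> str:
    payload = {
        "results": [
            {**rec,
             "scpA_flank_upstream": _flank_str(rec["scpA_flank_upstream"]),
             "scpA_flank_downstream": _flank_str(rec["scpA_flank_downstream"])}
            for rec in report.results
        ],
        "analyses": report.analyses.per_order.to_dict(orient="records"),
        "outliers": [
            {"species": species, "missing": [t.value for t in missing]}
            for species, missing in report.outliers
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
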