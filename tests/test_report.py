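import io

import pandas as pd
import pytest

from kitescan.annotations import GenomeAnnotation, parse_gff3
from kitescan.occurrence import CallStatus, OccurrenceCall, call_occurrence
from kitescan.pipeline import GenomeInput, scan_genome
from kitescan.report import ANALYSES_COLUMNS, build_report, render
from kitescan.synteny import pairwise_synteny
from kitescan.targets import TargetClass

from conftest import gene_cds, gff_for, make_taxon


def scan_cohort_records(cohort):
    records = []
    for genome in cohort.genomes:
        ann = parse_gff3(
            genome.gff_text, genome.assembly_id,
            cohort.taxonomy[genome.assembly_id],
        )
        calls, synteny = scan_genome(
            GenomeInput(annotation=ann, proteins=genome.proteins)
        )
        records.append((ann, calls, synteny))
    return records


class TestBuildReport:
    def test_counts_match_four_genome_truth(self, four_genome_cohort):
        report = build_report(scan_cohort_records(four_genome_cohort))
        frame = report.analyses.per_order
        assert frame["n_species"].sum() == 4
        row = frame.iloc[0]
        assert row["n_smc"] == 4
        assert row["n_scpA"] == 4
        assert row["n_scpB"] == 1
        assert row["n_smc_scpA_neighbors"] == 3

    def test_empty_cohort(self):
        report = build_report([])
        assert report.analyses.per_order.empty
        assert report.outliers == []

    def test_two_scpa_matches_counted_once(self):
        rows = (
            gene_cds("chr1", 1, 900, "L001", "ScpA paralog one")
            + gene_cds("chr1", 1200, 2100, "L002", "ScpA paralog two")
        )
        ann = parse_gff3(gff_for(rows), "A1", make_taxon(1))
        calls = call_occurrence(ann)
        report = build_report([(ann, calls, pairwise_synteny(calls, ann))])
        assert report.analyses.per_order.iloc[0]["n_scpA"] == 1

    def test_missing_taxonomy_names_assembly(self):
        ann = GenomeAnnotation("GCF_X1", "sp", None, [])
        calls = {
            t: OccurrenceCall("GCF_X1", t, CallStatus.ABSENT)
            for t in TargetClass
        }
        with pytest.raises(ValueError, match="GCF_X1"):
            build_report([(ann, calls, (None, None))])

    def test_species_deduplicated_across_assemblies(self):
        rows = gene_cds("chr1", 1, 900, "L001",
                        "chromosome segregation protein SMC")
        records = []
        for assembly in ("GCF_B2.1", "GCF_B1.1"):
            ann = parse_gff3(gff_for(rows), assembly, make_taxon(1))
            calls = call_occurrence(ann)
            records.append((ann, calls, pairwise_synteny(calls, ann)))
        report = build_report(records)
        assert report.analyses.per_order.iloc[0]["n_species"] == 1
        # first assembly by id wins
        assert report.results[0]["assembly_id"] == "GCF_B1.1"

    def test_outlier_complement(self, four_genome_cohort):
        records = scan_cohort_records(four_genome_cohort)
        report = build_report(records)
        complete = sum(
            all(calls[t].present for t in TargetClass)
            for _, calls, _ in records
        )
        assert len(report.outliers) == len(records) - complete

    def test_invariant_counts_bounded_by_species(self, four_genome_cohort):
        frame = build_report(
            scan_cohort_records(four_genome_cohort)
        ).analyses.per_order
        for col in ANALYSES_COLUMNS[2:]:
            assert (frame[col] <= frame["n_species"]).all()
        assert (
            frame["n_smc_scpA_neighbors"]
            <= frame[["n_smc", "n_scpA"]].min(axis=1)
        ).all()


class TestHmmColumns:
    def build_record(self, pseudo):
        rows = gene_cds("chr1", 1, 900, "L001",
                        "chromosome segregation protein SMC", pseudo=pseudo)
        ann = parse_gff3(gff_for(rows), "GCF_H1.1", make_taxon(1))
        calls = call_occurrence(ann)
        return ann, calls, pairwise_synteny(calls, ann)

    def hmm_calls(self, present):
        status = (CallStatus.FOUND_BY_HOMOLOGY if present
                  else CallStatus.ABSENT)
        return {
            "GCF_H1.1": {
                t: OccurrenceCall(
                    "GCF_H1.1", t, status,
                    locus_tags=("L001",) if present else (),
                )
                for t in TargetClass
            }
        }

    def test_hmm_columns_zero_without_tables(self):
        report = build_report([self.build_record(pseudo=False)])
        assert report.analyses.per_order.iloc[0]["n_smc_hmm"] == 0
        assert not report.analyses.hmm_supplied

    def test_hmm_columns_populated_when_supplied(self):
        report = build_report(
            [self.build_record(pseudo=False)], hmm_calls=self.hmm_calls(True)
        )
        assert report.analyses.per_order.iloc[0]["n_smc_hmm"] == 1

    def test_pseudogene_subtracted_from_hmm_column_only(self):
        record = self.build_record(pseudo=True)
        report = build_report([record], hmm_calls=self.hmm_calls(True))
        row = report.analyses.per_order.iloc[0]
        assert row["n_smc"] == 1          # counted as present
        assert row["n_pseudo_smc"] == 1
        assert row["n_smc_hmm"] == 0      # subtracted here
        relaxed = build_report(
            [record], hmm_calls=self.hmm_calls(True),
            subtract_pseudo_in_hmm=False,
        )
        assert relaxed.analyses.per_order.iloc[0]["n_smc_hmm"] == 1


class TestRender:
    def test_tsv_analyses_round_trip(self, four_genome_cohort):
        report = build_report(scan_cohort_records(four_genome_cohort))
        text = render(report, "tsv")
        section = text.split("## Analyses\n")[1].split("\n## Outliers")[0]
        parsed = pd.read_csv(io.StringIO(section), sep="\t")
        pd.testing.assert_frame_equal(
            parsed, report.analyses.per_order, check_dtype=False
        )

    def test_renders_are_deterministic(self, four_genome_cohort):
        report = build_report(scan_cohort_records(four_genome_cohort))
        assert render(report, "tsv") == render(report, "tsv")
        assert render(report, "json") == render(report, "json")

    def test_json_contains_three_parts(self, four_genome_cohort):
        import json

        report = build_report(scan_cohort_records(four_genome_cohort))
        payload = json.loads(render(report, "json"))
        assert set(payload) == {"results", "analyses", "outliers"}

    def test_unknown_format_rejected(self, four_genome_cohort):
        report = build_report(scan_cohort_records(four_genome_cohort))
        with pytest.raises(ValueError, match="format"):
            render(report, "xml")
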