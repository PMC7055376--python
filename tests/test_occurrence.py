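import pytest

from kitescan.annotations import parse_gff3
from kitescan.homology import HomologyHit
from kitescan.occurrence import (
    CallStatus,
    PatternSet,
    TargetClass,
    call_occurrence,
    find_outliers,
    string_match,
)

from conftest import gene_cds, gff_for, make_taxon


def annotation_with(products, pseudo=None):
    rows = []
    pos = 1
    for i, product in enumerate(products):
        rows.extend(
            gene_cds("chr1", pos, pos + 899, f"L{i:03d}", product,
                     pseudo=bool(pseudo and i in pseudo))
        )
        pos += 1100
    return parse_gff3(gff_for(rows), "A1", make_taxon())


def hit(identity, coverage, subject="L000"):
    return HomologyHit("q", subject, identity, coverage, None, 100)


class TestStringMatch:
    @pytest.mark.parametrize(
        "product,target,matched",
        [
            ("chromosome segregation protein SMC", TargetClass.SMC, True),
            ("hypothetical protein", TargetClass.SMC, False),
            ("hypothetical protein", TargetClass.SCPA, False),
            ("hypothetical protein", TargetClass.SCPB, False),
            ("Segregation and condensation protein B", TargetClass.SCPB, True),
            ("segregation/condensation protein A", TargetClass.SCPA, True),
            ("ScpA-like kleisin", TargetClass.SCPA, True),
        ],
    )
    def test_default_patterns(self, product, target, matched):
        ann = annotation_with([product])
        assert bool(string_match(ann, target)) is matched

    def test_genome_order_preserved(self):
        ann = annotation_with(
            ["ScpA paralog one", "glutamine synthetase", "ScpA paralog two"]
        )
        loci = [f.locus_tag for f in string_match(ann, TargetClass.SCPA)]
        assert loci == ["L000", "L002"]


class TestCallOccurrence:
    def test_canonical_annotation_found_by_string(self):
        ann = annotation_with(["segregation/condensation protein A"])
        calls = call_occurrence(ann)
        assert calls[TargetClass.SCPA].status is CallStatus.FOUND_BY_STRING

    def test_hypothetical_rescued_by_homology(self):
        ann = annotation_with(["hypothetical protein"])
        evidence = {TargetClass.SCPB: [hit(0.25, 0.80)]}
        calls = call_occurrence(ann, homology_evidence=evidence)
        call = calls[TargetClass.SCPB]
        assert call.status is CallStatus.FOUND_BY_HOMOLOGY
        assert call.locus_tags == ("L000",)

    def test_string_evidence_dominates_homology(self):
        ann = annotation_with(["segregation and condensation protein B"])
        evidence = {TargetClass.SCPB: [hit(0.99, 0.99, subject="other")]}
        calls = call_occurrence(ann, homology_evidence=evidence)
        assert calls[TargetClass.SCPB].status is CallStatus.FOUND_BY_STRING

    def test_pseudogene_marked_present(self):
        ann = annotation_with(["chromosome segregation protein SMC"],
                              pseudo={0})
        call = call_occurrence(ann)[TargetClass.SMC]
        assert call.status is CallStatus.FOUND_BY_STRING
        assert call.is_pseudo

    def test_pseudo_flag_requires_all_matches_pseudo(self):
        ann = annotation_with(
            ["chromosome segregation protein SMC",
             "chromosome segregation protein SMC"],
            pseudo={0},
        )
        assert not call_occurrence(ann)[TargetClass.SMC].is_pseudo

    def test_paralogs_collapse_to_one_call(self):
        ann = annotation_with(["ScpA one", "ScpA two"])
        call = call_occurrence(ann)[TargetClass.SCPA]
        assert call.locus_tags == ("L000", "L001")

    def test_hmm_style_hit_routed_by_evalue(self):
        ann = annotation_with(["hypothetical protein"])
        hmm_hit = HomologyHit("q", "L000", 0.0, 0.0, 1e-6, 0)
        calls = call_occurrence(
            ann, homology_evidence={TargetClass.SCPB: [hmm_hit]}
        )
        assert calls[TargetClass.SCPB].status is CallStatus.FOUND_BY_HOMOLOGY

    def test_determinism(self):
        ann = annotation_with(["hypothetical protein"])
        evidence = {TargetClass.SCPA: [hit(0.55, 0.30)]}
        first = call_occurrence(ann, homology_evidence=evidence)
        second = call_occurrence(ann, homology_evidence=evidence)
        assert first == second

    def test_adding_pattern_only_converts_absent_to_found(self):
        ann = annotation_with(["putative kleisin partner protein"])
        base = call_occurrence(ann)
        extended_patterns = PatternSet(
            {
                TargetClass.SMC: ("chromosome segregation protein SMC",),
                TargetClass.SCPA: ("segregation/condensation protein A",
                                   "ScpA"),
                TargetClass.SCPB: ("segregation and condensation protein B",
                                   "ScpB", "kleisin partner"),
            }
        )
        extended = call_occurrence(ann, patterns=extended_patterns)
        for target in TargetClass:
            if base[target].status is not CallStatus.ABSENT:
                assert extended[target].status is not CallStatus.ABSENT
        assert extended[TargetClass.SCPB].status is CallStatus.FOUND_BY_STRING


class TestOutliers:
    def make_calls(self, assembly, statuses):
        from kitescan.occurrence import OccurrenceCall

        return [
            OccurrenceCall(
                assembly_id=assembly,
                target=t,
                status=s,
                locus_tags=("L1",) if s is not CallStatus.ABSENT else (),
            )
            for t, s in statuses.items()
        ]

    def test_species_missing_one_class_listed(self):
        ok = {t: CallStatus.FOUND_BY_STRING for t in TargetClass}
        lacking = dict(ok)
        lacking[TargetClass.SCPB] = CallStatus.ABSENT
        result = find_outliers(
            {"sp one": self.make_calls("A1", ok),
             "sp two": self.make_calls("A2", lacking)}
        )
        assert result == [("sp two", [TargetClass.SCPB])]

    def test_all_present_yields_empty(self):
        ok = {t: CallStatus.FOUND_BY_STRING for t in TargetClass}
        assert find_outliers({"sp": self.make_calls("A1", ok)}) == []

    def test_all_absent_lists_all_three(self):
        gone = {t: CallStatus.ABSENT for t in TargetClass}
        result = find_outliers({"sp": self.make_calls("A1", gone)})
        assert result == [
            ("sp", [TargetClass.SMC, TargetClass.SCPA, TargetClass.SCPB])
        ]

    def test_incomplete_calls_rejected(self):
        partial = {TargetClass.SMC: CallStatus.FOUND_BY_STRING}
        with pytest.raises(ValueError, match="no call"):
            find_outliers({"sp": self.make_calls("A1", partial)})
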