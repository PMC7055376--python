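import numpy as np
import pytest

from kitescan.homology import (
    AlignScoring,
    HomologyHit,
    ThresholdRuleSet,
    _make_aligner,
    classify_hit,
    classify_hmm_hit,
    local_align,
    read_hit_table,
)
from kitescan.synthetic_data import SEED_PROTEINS, mutate_to_identity
from kitescan.targets import TargetClass

from alignment_oracle import local_affine_dp


class TestLocalAlign:
    def test_self_alignment_is_perfect(self):
        seq = SEED_PROTEINS[TargetClass.SCPB][:50]
        hit = local_align(seq, seq)
        assert hit.identity == 1.0
        assert hit.query_coverage == 1.0
        assert hit.aln_columns == 50

    def test_coverage_is_query_span_fraction(self):
        query = SEED_PROTEINS[TargetClass.SCPA][:100]
        subject = query[10:90]  # best local alignment spans query 11..90
        hit = local_align(query, subject)
        assert hit.query_coverage == pytest.approx(0.80)
        assert hit.identity == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_align("", "ACDE")

    def test_bad_character_error_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            local_align("AC1DE", "ACDE")

    def test_x_permitted(self):
        hit = local_align("ACDEXFGH", "ACDEXFGH")
        assert hit.aln_columns > 0

    def test_dissimilar_sequences_give_empty_hit(self):
        hit = local_align("W", "A")  # BLOSUM62 W/A scores negative
        assert hit.aln_columns == 0
        assert hit.identity == 0.0 and hit.query_coverage == 0.0


class TestOracleEquivalence:
    """The built-in aligner agrees with an exhaustive affine-gap DP."""

    @pytest.mark.parametrize("trial_block", range(5))
    def test_random_short_pairs_match_oracle(self, trial_block):
        rng = np.random.default_rng(1000 + trial_block)
        alphabet = "ACDE"
        scoring = AlignScoring()
        aligner = _make_aligner(scoring, "local")
        for _ in range(100):
            n, m = rng.integers(1, 13, size=2)
            q = "".join(alphabet[i] for i in rng.integers(4, size=n))
            s = "".join(alphabet[i] for i in rng.integers(4, size=m))
            oracle_score, oracle_identities = local_affine_dp(q, s)
            alignments = aligner.align(q, s)
            impl_score = alignments.score if len(alignments) else 0.0
            assert max(impl_score, 0.0) == pytest.approx(
                oracle_score
            ), f"score mismatch for {q} vs {s}"
            hit = local_align(q, s, scoring)
            if oracle_score > 0:
                assert any(
                    abs(hit.identity - v) < 1e-9 for v in oracle_identities
                ), f"identity {hit.identity} not optimal for {q} vs {s}"
            else:
                assert hit.aln_columns == 0

    def test_identity_degrades_with_substitutions(self):
        seq = SEED_PROTEINS[TargetClass.SCPA]
        means = []
        for ident in (0.9, 0.7, 0.5):
            vals = [
                local_align(seq, mutate_to_identity(seq, ident, s)).identity
                for s in range(8)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestClassifyHit:
    @pytest.mark.parametrize(
        "identity,coverage,target,accepted",
        [
            # general rule: >20% identity and >70% coverage, any class
            (0.25, 0.80, TargetClass.SCPB, True),
            (0.25, 0.80, TargetClass.SMC, True),
            (0.20, 0.80, TargetClass.SCPB, False),   # boundary: strict
            (0.21, 0.80, TargetClass.SCPB, True),
            (0.25, 0.70, TargetClass.SCPB, False),   # boundary: strict
            (0.25, 0.71, TargetClass.SCPB, True),
            (0.19, 0.99, TargetClass.SMC, False),
            # kleisin rescue rule: >50% identity and >25% coverage, ScpA only
            (0.55, 0.30, TargetClass.SCPA, True),
            (0.55, 0.30, TargetClass.SCPB, False),
            (0.55, 0.30, TargetClass.SMC, False),
            (0.50, 0.30, TargetClass.SCPA, False),   # boundary: strict
            (0.51, 0.26, TargetClass.SCPA, True),
            (0.51, 0.25, TargetClass.SCPA, False),   # boundary: strict
            (0.51, 0.24, TargetClass.SCPA, False),
        ],
    )
    def test_rule_grid(self, identity, coverage, target, accepted):
        hit = HomologyHit("q", "s", identity, coverage, None, 100)
        assert classify_hit(hit, target) is accepted

    def test_monotone_in_identity_and_coverage(self):
        rules = ThresholdRuleSet()
        for target in TargetClass:
            grid = np.linspace(0.01, 0.99, 25)
            for coverage in (0.3, 0.75):
                accepted = [
                    classify_hit(
                        HomologyHit("q", "s", i, coverage, None, 10),
                        target, rules,
                    )
                    for i in grid
                ]
                # once accepted, higher identity never flips back
                assert accepted == sorted(accepted)


class TestClassifyHmm:
    @pytest.mark.parametrize(
        "evalue,target,accepted",
        [
            (1e-3, TargetClass.SCPA, False),
            (1e-4, TargetClass.SCPA, False),   # boundary: strict
            (1e-5, TargetClass.SCPA, True),
            (1e-5, TargetClass.SCPB, True),
            (1e-5, TargetClass.SMC, False),
            (1e-99, TargetClass.SMC, False),
            (1e-100, TargetClass.SMC, False),  # boundary: strict
            (1e-101, TargetClass.SMC, True),
        ],
    )
    def test_evalue_grid(self, evalue, target, accepted):
        assert classify_hmm_hit(evalue, target) is accepted

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ValueError):
            classify_hmm_hit(0.0, TargetClass.SCPA)


class TestReadHitTable:
    def test_blast_row_arithmetic(self):
        row = "q1\ts1\t25.0\t80\t55\t2\t1\t80\t5\t84\t1e-20\t90.1\n"
        hits = read_hit_table(row, "blast_tab12", {"q1": 100})
        (hit,) = hits
        assert hit.identity == pytest.approx(0.25)
        assert hit.query_coverage == pytest.approx(0.80)
        assert hit.evalue == pytest.approx(1e-20)

    def test_blast_wrong_column_count_names_line(self):
        with pytest.raises(ValueError, match="line 1"):
            read_hit_table("q1\ts1\t25.0\n", "blast_tab12", {"q1": 100})

    def test_blast_unknown_query_length(self):
        row = "q9\ts1\t25.0\t80\t55\t2\t1\t80\t5\t84\t1e-20\t90.1\n"
        with pytest.raises(ValueError, match="q9"):
            read_hit_table(row, "blast_tab12", {"q1": 100})

    def test_hmmer_comments_skipped_and_evalue_only(self):
        text = (
            "# comment line\n"
            "#\n"
            "L001 - query_scpB - 1.2e-30 50.1 0.0 1.5e-30 49.9 0.0 "
            "1.0 1 0 0 1 1 1 1 description here\n"
        )
        (hit,) = read_hit_table(text, "hmmer_tbl")
        assert hit.evalue == pytest.approx(1.2e-30)
        assert hit.aln_columns == 0
        assert hit.subject_id == "L001" and hit.query_id == "query_scpB"

    def test_empty_stream(self):
        assert read_hit_table("", "blast_tab12", {}) == []

    def test_unknown_dialect(self):
        with pytest.raises(ValueError, match="dialect"):
            read_hit_table("", "csv")


class TestValidation:
    def test_scoring_requires_extend_le_open(self):
        with pytest.raises(ValueError):
            AlignScoring(gap_open=1, gap_extend=5)

    def test_hit_invariants(self):
        with pytest.raises(ValueError):
            HomologyHit("q", "s", 1.5, 0.5, None, 10)
        with pytest.raises(ValueError):
            HomologyHit("q", "s", 0.5, 0.0, None, 10)
        # zero-column HMM-style hit is legal with zero coverage
        HomologyHit("q", "s", 0.0, 0.0, 1e-5, 0)
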