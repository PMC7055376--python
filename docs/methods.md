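# Methods

This note documents what the pipeline computes, the assumptions behind
each stage, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate about real genomes.

## Annotation model

RefSeq GFF3 files spread one gene over several rows. The parser unifies
them into one gene-level feature per gene: the `product` string is taken
from the gene row or, failing that, from the first CDS child referencing
the gene via `Parent`; orphan CDS rows become features of their own.
A feature is *searchable* (eligible for the string search and counted as
an intervening gene) when it is protein-coding (has a CDS child, is a CDS,
or carries `gene_biotype=protein_coding`) or is a pseudogene
(`pseudo=true`, `gene_biotype=pseudogene`, or feature type `pseudogene`).
RNA genes are parsed but not searchable. Coordinates stay 1-based
inclusive and are used only for ordering; strand is recorded and ignored
everywhere downstream. Missing locus tags are synthesized as
`REPLICON:START-END` so adjacency logic always has unique keys.

The survey scans the unified gene-level product text. Whether an upstream
tool would scan every GFF row or only gene/CDS rows is an open choice;
gene-level scanning is this package's stated behavior.

## Occurrence calls

Default search strings per class (plain case-insensitive substrings, no
regular expressions — RefSeq capitalization varies, and the short tokens
`ScpA`/`ScpB` have no plausible case-folded false positives in product
names):

| class | patterns |
|---|---|
| smc  | `chromosome segregation protein SMC` |
| scpA | `segregation/condensation protein A`, `ScpA` |
| scpB | `segregation and condensation protein B`, `ScpB` |

A genome is counted once per class no matter how many features match
(species counts, not gene counts). String evidence dominates: the
homology fallback runs only for classes with no string match, and a
class found by string is never reported as found by homology. `is_pseudo`
is set when *every* matching feature is pseudogene-flagged; such a class
still counts as present, and the report subtracts pseudogene-marked genes
only in the HMM columns (configurable via `subtract_pseudo_in_hmm`,
default on — the convention under which an HMM column can run one or two
lower than the alignment column).

## Homology evidence and thresholds

The built-in aligner is an optimal affine-gap local alignment
(Smith–Waterman–Gotoh via Biopython's `PairwiseAligner`) with BLOSUM62
and BLAST's protein gap defaults: a gap of length k costs 11 + k (open
11, extend 1). `X` is permitted and scored 0 against everything. Identity
is identical pairs over all alignment columns, gap columns included in the
denominator (the BLAST `pident` convention); coverage is the query span
of the single best local alignment over the query length — no HSP tiling,
the simplest defensible reading of "coverage of the query sequence".
The built-in aligner computes no E-values (Karlin–Altschul statistics are
out of scope); E-values enter only through imported tables.

Acceptance rules, all strict inequalities ("higher than" / "less than"):

* identity > 0.20 and coverage > 0.70, any class;
* identity > 0.50 and coverage > 0.25, ScpA only (the kleisin N-terminal
  domain is the conserved part, so often only it aligns);
* imported HMM hits: E-value < 1e-4 (ScpA), < 1e-4 (ScpB), < 1e-100
  (Smc) — looser cutoffs routinely admit unrelated annotations.

Boundary behavior is pinned by tests: identity exactly 0.20 or coverage
exactly 0.70 is rejected.

## Synteny

"Neighbors" means zero searchable genes strictly between two loci on the
same replicon — a positional criterion, independent of strand, base-pair
distance or operon structure. Genes on different replicons are *remote*
(not comparable). Replicons are treated as linear; `circular=True`
(CLI `--circular`) also considers the wrap-around path and reports the
shorter count. GFF3 carries no topology information, so linear is the
default; wrap-around affects at most one gene pair per replicon. When a
class matched several loci, the pair minimizing the intervening count is
reported.

## Middle-region measurement

The ScpA middle region is the segment between helix α3 and the next
conserved helix. On the reference the region is delimited by two anchor
residues — defaults 75 and 107, chosen so that the region spans residues
76–106 (31 residues, consistent with a helix α4 starting at residue 107
and the disordered stretch beginning at 76). Anchors are configurable.

Projection uses a *global* affine-gap alignment (both ScpA termini are
conserved, and both anchors must be present in the alignment); the length
is the number of target residues in columns strictly between the columns
holding the two anchor residues. Gaps never shift anchors: the column
actually holding the reference residue defines the boundary. When a
deletion abuts an anchor and the flanking reference residues are
identical, co-optimal alignments differ in whether the boundary target
residue sits inside the region or on the anchor column; a score-neutral
gap slide (exchanging identical reference residues) deterministically
moves such residues onto the anchor column, so the measurement does not
depend on the aligner's internal traceback order.

For multiple alignments the rows are taken as given (no realignment):
anchor columns are located on the named reference row and non-gap
characters are counted per row.

Bins are descriptive summaries of observed ranges: 30–47 short archaeal,
48–60 intermediate, 61–72 bacterial-like, anything else out of range;
the bacterial range wins if a configured archaeal range overlaps it.
Bin membership makes no claim about ScpB binding — archaeal ScpAs with
bacterial-length middle regions still fail to bind ScpB — and the
breakpoints are configurable.

## Synthetic cohorts and what they show

The generator emulates the input universe of a RefSeq survey: gene + CDS
row structure, `product`/`locus_tag`/`pseudo` attributes, one or two
replicons, decoy filler products (checked never to substring-match any
search pattern), one RNA gene per genome to exercise the searchable
filter, and proteins diverged from fixed bundled seed sequences by
uniform random substitutions (only the identity level matters to the
thresholds under test; no transition bias). Seed proteins are synthetic
sequences length-matched to the real subunits (Smc ≈ 1180 aa, ScpA 220
aa, ScpB 190 aa); no real sequence is redistributed. Identical spec and
seed give byte-identical output.

Detectability gray zone: for a substitution-only mutant, the optimal
local alignment trims low-scoring ends, so query coverage falls below
70 % somewhere between 40 % and 12 % identity, at an instance-specific
point — the same behavior real near-threshold BLAST hits show. The
generator therefore assigns homology-fallback ground truth only outside
that zone (hypothetical-style entries must have identity ≥ 0.40, always
detected in calibration, or ≤ 0.12, never detected) and rejects specs
inside it. Pseudogene-flagged genes keep their canonical product (a
pseudogene is found by string, with the flag) and contribute no protein.

What passing tests show: the pipeline's bookkeeping — parsing, string
search, fallback classification, adjacency, per-order aggregation,
outlier listing — is exact on inputs whose truth is known. What they do
not show: performance on real annotation idiosyncrasies (nonstandard
product vocabulary, split or frame-shifted pseudogenes, multi-isoform
records), on genuinely homologous-but-divergent proteins whose alignment
behavior differs from substitution mutants, or the database-dependent
headline counts of any particular survey snapshot, which depend on the
assembly set at retrieval time and are not reproducible offline.

## Problem sizes and determinism

The default verification conditions are: a matrix of 30 seeded cohorts of
4–50 genomes (one 50-genome cohort; 263 genomes total) covering every
presence combination, annotation style, pseudogene flag and adjacency
arrangement; 500 random length-≤12 pairs over a 4-letter alphabet for the
aligner-versus-oracle comparison (the oracle is an independent exhaustive
Gotoh dynamic program that also enumerates co-optimal identities); the
full identity/coverage/E-value boundary grid; and anchor-projection
checks at insertions of 1, 5, 18 and 35 residues (expected 32, 36, 49,
66). All randomness flows from explicit integer seeds; `--seed` controls
the acceptance script end to end.

## Known limitations

* Annotation-only parsing: no GenBank flat files, no GTF, no nucleotide
  sequences.
* Single-HSP query coverage; a multi-domain homolog split across HSPs
  may under-cover.
* The built-in aligner reports no E-value; statistical significance
  requires imported search results.
* HMM evidence is supported only as imported tables; profile scoring is
  out of scope.
* Species deduplication keeps the first assembly by identifier sort when
  one species has several assemblies — a stated convention, not a claim
  about which assembly is best.
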