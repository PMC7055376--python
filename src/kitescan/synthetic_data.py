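"""Synthetic cohorts of mock archaeal genomes with known ground truth.

Every pipeline stage is testable offline: the generator writes RefSeq-style
GFF3 annotations (gene + CDS rows, ``product``/``locus_tag``/``pseudo``
attributes), protein FASTA files, a taxonomy sidecar and a truth table of
the occurrence/adjacency/region-length results the pipeline is expected to
reproduce.  Per-genome controls cover presence of each gene class,
annotation style (canonical product name vs "hypothetical protein"),
pseudogene flags, protein divergence from the bundled seed proteins, gene
spacing (intervening counts or placement on another replicon) and the
length of the ScpA middle region.

Seed proteins are fixed synthetic sequences, length-matched to the real
subunits (Smc ~1180 aa, ScpA ~220 aa, ScpB ~190 aa); no real sequence is
redistributed.  Identical seed => byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
from urllib.parse import quote

import numpy as np
import pandas as pd

from .annotations import Taxon
from .regions import AnchorSet
from .targets import ALL_TARGETS, TargetClass

__all__ = [
    "SEED_PROTEINS",
    "GenomeSpec",
    "SyntheticCohortSpec",
    "SyntheticGenome",
    "SyntheticCohort",
    "generate_cohort",
    "mutate_to_identity",
    "insert_middle_segment",
    "write_cohort",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Fixed synthetic seed proteins (generated once from a fixed RNG with a
# mildly protein-like residue composition, then frozen as literals).
_SEED_SMC = (
    "TNDISKAGLGANLALLSPFSIYQDVSHNNTLDNLMIQAQRLEGVEIGSNILMKVTGRRPL"
    "PDPMVIWIWRTFGSLASHKFQVDLGAGIIISGRLAIKQKLPATRHRQTRVDVEIPENLVA"
    "ERNHFKDGANTRYSETRTKHKCLKITKDNGLIEPFNDVHMAFAQGVGRARRGKVEAIHRL"
    "WTLVAVDAKALTQEHSECQHNLVIAKTVVCDEIRATNYGVREVEIRNESSHRVVSERILL"
    "ADLMECQETLVEEPVELAIYQTYGRDLAKFASQWFIELGLTPKHQDIIVFVTILRYKMAA"
    "ADDLQMEGFKEDKALAAEAMENMSASEGSYATGLLQTAFGVADIYHAWAFELTRFFWDVY"
    "VEPKEEQMEISLIWKVSIKTCKNTGGNTLVIASIIAVTATSMMCRKREDNVSGAVPRAVR"
    "PTPGRFISHCRSEPLDFDPGPVAVDISPLDFKQQITGEHPFGKQDDTAEFCQIEHAGINS"
    "IEEATWVENSNALKFTPFGNLMHDRAGVIFQVGICMLIGPCHADGDSRYYKRQLADSSGG"
    "KPLGSNNKDITTTEVIKQFGKSRGVLAHMLQAKRMKAYKISESVRRSNTRFGNAMFTIDI"
    "GLGADLEKCENTFSNKTLQNGESDWNVDQGDIKEEDQYDHLISIMNESLHTKWLPNEQMK"
    "YFYAQGESLDTQNHAYLVIRFQITLQCLSWVYLVQLAVVPEDLRPHGWAAETVIVVDVIL"
    "ANLVATMIAKLLQTRLYLTVAKTTCPARIDPSERSGVSCLAYVLLVLLTHMGLLILCVST"
    "EDFPLKGIQLTVPDTRKLIGGLDLIRQLGKTAWNFYNELDFTSLLMMIVVAVKGEDIAAK"
    "SQLDLATLLEPSDEGFPIEKIKRDGQLRDEVDMFHLYPQEGSVVGQRMYPAPGNRLKRRS"
    "PHLADSQKRATVPGFLKEKMPAKVRLCVKVGLMNNFPKPHKIFERRQASLLFPREGPHER"
    "CLRMIIKSQTVLVFTSAAPGEDAETEYAAPTSLMRPRLFSDLDHKTNNELRSTVGVVYTE"
    "LKQAHACRLGTVPKIETNMLEPNIAAVRLPIGGVTVEQEPDPWQNVTLWILALNLTIQAV"
    "LHTKEWFRIGKMAILVGFRLDVLCAYKIRCENNERFVGSFTYITQSRRNFVLPSKKSHCW"
    "VGYSRIDVGSIIVMPIRQGVAAIMANLQRDLHVITSGQEL"
)
_SEED_SCPA = (
    "DGDVIVQYVKKPEEQYDMMAEQIKVSSQDYADHKEDVVVKTAQYVSRRVKEAVIGLNIAN"
    "NSIYSTLLIGKDSFLERGRLDHVMIPIMNTPPAAGSSIQRCISYNLIGIYEFAFSLLMRI"
    "ANPTSVGLENNGKRTGILQSGEDKLGYKLVAYMPNLISAEDALVLFYVYEARIFSSTLDA"
    "HSSGFALEISPMTKDYTEYVIPNADIRSKPKLLRCIALSH"
)
_SEED_SCPB = (
    "NLQDVVETALESPQCDDAGTSRYENTREGVGAEMGKRGLINPELLLIGDKRFCFGKGEDK"
    "TNIQSAEMGQVNYLGLEHMKNTTHHNGSLQADNRPFAILTFPNRSEEKYTWPTDDDQPTN"
    "AISKAAKKNPLIASQKARHFFRGSVTVISTEGYSVGYIEDAQAPIALDLINMHGALIYTV"
    "RNKLAQNIPA"
)

SEED_PROTEINS: dict[TargetClass, str] = {
    TargetClass.SMC: _SEED_SMC,
    TargetClass.SCPA: _SEED_SCPA,
    TargetClass.SCPB: _SEED_SCPB,
}

CANONICAL_PRODUCTS: dict[TargetClass, str] = {
    TargetClass.SMC: "chromosome segregation protein SMC",
    TargetClass.SCPA: "segregation/condensation protein A",
    TargetClass.SCPB: "segregation and condensation protein B",
}
HYPOTHETICAL_PRODUCT = "hypothetical protein"

# Filler products; none may substring-match any default search pattern.
DECOY_PRODUCTS: tuple[str, ...] = (
    "DNA polymerase II large subunit",
    "30S ribosomal protein S4",
    "ABC transporter ATP-binding protein",
    "translation initiation factor IF-2",
    "methyl-coenzyme M reductase subunit alpha",
    "archaeal histone A",
    "V-type ATP synthase subunit B",
    "tRNA pseudouridine synthase D",
    "glutamine synthetase",
    "cell division protein FtsZ",
    "proteasome subunit beta",
    "DNA topoisomerase VI subunit A",
    "replication factor C small subunit",
    "aspartate aminotransferase",
    "phosphoribosylformylglycinamidine synthase",
    "preprotein translocase subunit SecY",
)


def _assert_no_pattern_leakage() -> None:
    needles = [
        "chromosome segregation protein smc",
        "segregation/condensation protein a",
        "scpa",
        "segregation and condensation protein b",
        "scpb",
    ]
    for decoy in DECOY_PRODUCTS:
        low = decoy.lower()
        for needle in needles:
            if needle in low:
                raise AssertionError(
                    f"decoy product {decoy!r} matches pattern {needle!r}"
                )


_assert_no_pattern_leakage()


@dataclass
class GenomeSpec:
    """Controls for one mock genome.

    ``smc_scpa`` / ``scpa_scpb`` give the number of filler genes placed
    between the pair, or ``"remote"`` to put the second gene on a separate
    replicon.  ``None`` means unspecified: the typical archaeal arrangement
    is used (smc and scpA juxtaposed; scpB, when present, remote).  An
    explicit spacing for a pair with an absent member is a contradiction and
    rejected.  ``identity`` is the target fraction of identical positions
    relative to the class seed protein (substitutions only).
    """

    assembly_id: str
    species: str
    taxon: Taxon
    presence: dict[TargetClass, bool] = field(
        default_factory=lambda: {t: True for t in ALL_TARGETS}
    )
    style: dict[TargetClass, str] = field(
        default_factory=lambda: {t: "canonical" for t in ALL_TARGETS}
    )
    pseudo: dict[TargetClass, bool] = field(
        default_factory=lambda: {t: False for t in ALL_TARGETS}
    )
    identity: dict[TargetClass, float] = field(
        default_factory=lambda: {t: 1.0 for t in ALL_TARGETS}
    )
    smc_scpa: int | str | None = None
    scpa_scpb: int | str | None = None
    middle_insertion: int = 0
    n_filler: int = 12

    def resolved_pair(self, name: str) -> int | str | None:
        """Pair spacing with ``None`` replaced by the typical arrangement."""
        value = getattr(self, name)
        members = (
            (TargetClass.SMC, TargetClass.SCPA)
            if name == "smc_scpa"
            else (TargetClass.SCPA, TargetClass.SCPB)
        )
        if not all(self.presence.get(m, True) for m in members):
            return None
        if value is None:
            return 0 if name == "smc_scpa" else "remote"
        return value

    def validate(self) -> None:
        for t in ALL_TARGETS:
            if self.style.get(t, "canonical") not in ("canonical", "hypothetical"):
                raise ValueError(f"{self.assembly_id}: bad style for {t}")
            ident = self.identity.get(t, 1.0)
            if not 0.0 < ident <= 1.0:
                raise ValueError(
                    f"{self.assembly_id}: identity for {t} must be in (0, 1]"
                )
            if (
                self.style.get(t, "canonical") == "hypothetical"
                and self.presence.get(t, True)
                and UNDETECTABLE_IDENTITY < ident < DETECTABLE_IDENTITY
            ):
                raise ValueError(
                    f"{self.assembly_id}: identity {ident} for hypothetical "
                    f"{t} lies in the detectability gray zone "
                    f"({UNDETECTABLE_IDENTITY}, {DETECTABLE_IDENTITY}); "
                    f"no ground truth can be guaranteed there"
                )
            if self.pseudo.get(t, False):
                if not self.presence.get(t, True):
                    raise ValueError(
                        f"{self.assembly_id}: pseudogene flag for absent {t}"
                    )
                if self.style.get(t, "canonical") != "canonical":
                    raise ValueError(
                        f"{self.assembly_id}: pseudogene {t} must keep its "
                        f"canonical product name"
                    )
        for name, pair, members in (
            ("smc_scpa", self.smc_scpa, (TargetClass.SMC, TargetClass.SCPA)),
            ("scpa_scpb", self.scpa_scpb, (TargetClass.SCPA, TargetClass.SCPB)),
        ):
            if pair is None:
                continue
            if isinstance(pair, str) and pair != "remote":
                raise ValueError(f"{self.assembly_id}: bad {name} value {pair!r}")
            if isinstance(pair, int) and pair < 0:
                raise ValueError(f"{self.assembly_id}: negative {name}")
            if not all(self.presence.get(m, True) for m in members):
                raise ValueError(
                    f"{self.assembly_id}: {name} adjacency requested but a "
                    f"member gene is absent"
                )
        if self.middle_insertion < 0:
            raise ValueError(f"{self.assembly_id}: negative middle insertion")
        budget = sum(
            p
            for p in (self.resolved_pair("smc_scpa"),
                      self.resolved_pair("scpa_scpb"))
            if isinstance(p, int)
        )
        if self.n_filler < budget:
            raise ValueError(
                f"{self.assembly_id}: n_filler={self.n_filler} cannot supply "
                f"{budget} intervening genes"
            )


@dataclass
class SyntheticCohortSpec:
    genomes: list[GenomeSpec]
    seed: int = 0

    def validate(self) -> None:
        ids = [g.assembly_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate assembly ids in cohort spec")
        for g in self.genomes:
            g.validate()


@dataclass
class SyntheticGenome:
    assembly_id: str
    gff_text: str
    fasta_text: str
    proteins: dict[str, str]  # locus_tag -> sequence


@dataclass
class SyntheticCohort:
    genomes: list[SyntheticGenome]
    taxonomy: dict[str, Taxon]
    truth: pd.DataFrame


def mutate_to_identity(sequence: str, target_identity: float, seed: int) -> str:
    """Substitute positions so the result keeps ``target_identity`` to input.

    Length-preserving; the realized identity is within +-0.02 of the target
    (exact granularity 1/len).  Deterministic per seed.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity == 1.0:
        return sequence
    rng = np.random.default_rng(seed)
    n = len(sequence)
    k = int(round((1.0 - target_identity) * n))
    positions = rng.choice(n, size=k, replace=False)
    chars = list(sequence)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def insert_middle_segment(
    scpA_seq: str, k: int, anchors: AnchorSet = AnchorSet(), seed: int = 0
) -> str:
    """Insert ``k`` random residues strictly between the anchor residues."""
    if k < 0:
        raise ValueError("insertion length must be non-negative")
    anchors.validate_for(scpA_seq)
    if k == 0:
        return scpA_seq
    rng = np.random.default_rng(seed)
    # insertion point after residue j keeps the insert strictly inside
    j = int(rng.integers(anchors.left_anchor, anchors.right_anchor - 1))
    insert = "".join(
        AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=k)
    )
    return scpA_seq[:j] + insert + scpA_seq[j:]


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=n))


_TRNA_PRODUCT = "tRNA-Ala"


def _gff_attributes(pairs: Sequence[tuple[str, str]]) -> str:
    return ";".join(f"{k}={quote(v, safe=' /,-')}" for k, v in pairs if v)


class _GenomeBuilder:
    def __init__(self, assembly_id: str, rng: np.random.Generator):
        self.assembly_id = assembly_id
        self.rng = rng
        self.rows: list[str] = []
        self.proteins: dict[str, str] = {}
        self.products: dict[str, str] = {}
        self._counter = 0
        self._cursor: dict[str, int] = {}

    def _next_locus(self) -> str:
        self._counter += 1
        return f"{self.assembly_id.replace('.', '_')}_{self._counter:04d}"

    def add_gene(
        self,
        replicon: str,
        product: str,
        protein: str | None,
        pseudo: bool = False,
        rna: bool = False,
    ) -> str:
        locus = self._next_locus()
        start = self._cursor.get(replicon, 1)
        length_nt = (len(protein) * 3 + 3) if protein else 900
        end = start + length_nt - 1
        self._cursor[replicon] = end + 200
        strand = "+" if self.rng.integers(2) else "-"
        gene_id = f"gene-{locus}"
        gene_attrs = [("ID", gene_id), ("locus_tag", locus)]
        if pseudo:
            gene_attrs.append(("pseudo", "true"))
        gene_attrs.append(
            ("gene_biotype", "tRNA" if rna else
             ("pseudogene" if pseudo else "protein_coding"))
        )
        self.rows.append(
            "\t".join(
                [replicon, "RefSeq", "gene", str(start), str(end), ".",
                 strand, ".", _gff_attributes(gene_attrs)]
            )
        )
        child_type = "tRNA" if rna else "CDS"
        child_attrs = [
            ("ID", f"{'rna' if rna else 'cds'}-{locus}"),
            ("Parent", gene_id),
            ("locus_tag", locus),
            ("product", product),
        ]
        if pseudo:
            child_attrs.append(("pseudo", "true"))
        self.rows.append(
            "\t".join(
                [replicon, "RefSeq", child_type, str(start), str(end), ".",
                 strand, "0" if child_type == "CDS" else ".",
                 _gff_attributes(child_attrs)]
            )
        )
        if protein is not None and not pseudo and not rna:
            self.proteins[locus] = protein
        self.products[locus] = product
        return locus

    def gff(self) -> str:
        return "##gff-version 3\n" + "\n".join(self.rows) + "\n"

    def fasta(self) -> str:
        chunks = []
        for locus, seq in self.proteins.items():
            chunks.append(f">{locus} {self.products[locus]}")
            chunks.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        return "\n".join(chunks) + ("\n" if chunks else "")


def _build_genome(
    g: GenomeSpec, rng: np.random.Generator, anchors: AnchorSet
) -> tuple[SyntheticGenome, dict]:
    builder = _GenomeBuilder(g.assembly_id, rng)

    proteins: dict[TargetClass, str | None] = {}
    for t in ALL_TARGETS:
        if not g.presence.get(t, True):
            proteins[t] = None
            continue
        seq = SEED_PROTEINS[t]
        sub_seed = int(rng.integers(2**31))
        seq = mutate_to_identity(seq, g.identity.get(t, 1.0), sub_seed)
        if t is TargetClass.SCPA and g.middle_insertion:
            seq = insert_middle_segment(
                seq, g.middle_insertion, anchors, int(rng.integers(2**31))
            )
        proteins[t] = seq

    def product_of(t: TargetClass) -> str:
        if g.style.get(t, "canonical") == "canonical":
            return CANONICAL_PRODUCTS[t]
        return HYPOTHETICAL_PRODUCT

    # replicon layout
    chr_order: list[TargetClass | None] = []  # None = filler slot
    remote: list[TargetClass] = []
    budget = g.n_filler

    def spend(n: int) -> int:
        nonlocal budget
        n = min(n, budget)
        budget -= n
        return n

    smc_here = g.presence.get(TargetClass.SMC, True)
    scpa_here = g.presence.get(TargetClass.SCPA, True)
    scpb_here = g.presence.get(TargetClass.SCPB, True)
    smc_scpa = g.resolved_pair("smc_scpa")
    scpa_scpb = g.resolved_pair("scpa_scpb")

    if smc_here and smc_scpa == "remote":
        remote.append(TargetClass.SMC)
        smc_here = False
    if scpb_here and scpa_scpb == "remote":
        remote.append(TargetClass.SCPB)
        scpb_here = False

    if smc_here:
        chr_order.append(TargetClass.SMC)
        if scpa_here and isinstance(smc_scpa, int):
            chr_order.extend([None] * spend(smc_scpa))
    if scpa_here:
        chr_order.append(TargetClass.SCPA)
        if scpb_here and isinstance(scpa_scpb, int):
            chr_order.extend([None] * spend(scpa_scpb))
    if scpb_here:
        chr_order.append(TargetClass.SCPB)

    # remaining fillers split around the target block
    front = spend(int(rng.integers(0, budget + 1))) if budget else 0
    chr_order = [None] * front + chr_order + [None] * budget

    locus_of: dict[TargetClass, str] = {}
    for slot in chr_order:
        if slot is None:
            product = DECOY_PRODUCTS[int(rng.integers(len(DECOY_PRODUCTS)))]
            builder.add_gene(
                "chr1", product, _random_protein(rng, int(rng.integers(150, 400)))
            )
        else:
            locus_of[slot] = builder.add_gene(
                "chr1",
                product_of(slot),
                proteins[slot],
                pseudo=g.pseudo.get(slot, False),
            )
    # one RNA gene at the chromosome end exercises searchable filtering
    builder.add_gene("chr1", _TRNA_PRODUCT, None, rna=True)

    for t in remote:
        builder.add_gene(
            "plasmid1",
            DECOY_PRODUCTS[int(rng.integers(len(DECOY_PRODUCTS)))],
            _random_protein(rng, int(rng.integers(150, 400))),
        )
        locus_of[t] = builder.add_gene(
            "plasmid1", product_of(t), proteins[t], pseudo=g.pseudo.get(t, False)
        )

    genome = SyntheticGenome(
        assembly_id=g.assembly_id,
        gff_text=builder.gff(),
        fasta_text=builder.fasta(),
        proteins=builder.proteins,
    )
    return genome, locus_of


# Detectability bounds for the homology fallback on substitution-only
# mutants of the seed proteins.  Above the upper bound the optimal local
# alignment always keeps > 70% query coverage; below the lower bound no
# acceptable alignment survives.  In between, coverage straddles the cutoff
# and the verdict is instance-specific (as with real near-threshold BLAST
# hits), so the generator refuses to assign a ground truth there.
DETECTABLE_IDENTITY = 0.40
UNDETECTABLE_IDENTITY = 0.12


def _expected_status(g: GenomeSpec, t: TargetClass) -> str:
    if not g.presence.get(t, True):
        return "absent"
    if g.style.get(t, "canonical") == "canonical":
        return "found_by_string"
    if g.identity.get(t, 1.0) >= DETECTABLE_IDENTITY:
        return "found_by_homology"
    return "absent"


def generate_cohort(
    spec: SyntheticCohortSpec, anchors: AnchorSet = AnchorSet()
) -> SyntheticCohort:
    """Generate GFF3 + FASTA text per genome plus the ground-truth table.

    The truth table records, per genome, the expected occurrence status and
    pseudogene flag per class, the expected smc-scpA and scpA-scpB
    adjacency (intervening count, remoteness, neighbor verdict) and the
    expected ScpA middle-region length.
    """
    spec.validate()
    genomes = []
    taxonomy = {}
    truth_rows = []
    for idx, g in enumerate(spec.genomes):
        rng = np.random.default_rng([spec.seed, idx])
        genome, locus_of = _build_genome(g, rng, anchors)
        genomes.append(genome)
        taxonomy[g.assembly_id] = g.taxon

        statuses = {t: _expected_status(g, t) for t in ALL_TARGETS}

        def pair_truth(pair, a: TargetClass, b: TargetClass):
            if statuses[a] == "absent" or statuses[b] == "absent":
                return None, False
            if pair == "remote":
                return "remote", False
            return int(pair), pair == 0

        smc_scpa, smc_scpa_nb = pair_truth(
            g.resolved_pair("smc_scpa"), TargetClass.SMC, TargetClass.SCPA
        )
        scpa_scpb, scpa_scpb_nb = pair_truth(
            g.resolved_pair("scpa_scpb"), TargetClass.SCPA, TargetClass.SCPB
        )
        scpa_detectable = statuses[TargetClass.SCPA] != "absent"
        has_scpa_protein = (
            g.presence.get(TargetClass.SCPA, True)
            and not g.pseudo.get(TargetClass.SCPA, False)
        )
        truth_rows.append(
            {
                "assembly_id": g.assembly_id,
                "species": g.species,
                "order": g.taxon.order,
                "smc_status": statuses[TargetClass.SMC],
                "scpA_status": statuses[TargetClass.SCPA],
                "scpB_status": statuses[TargetClass.SCPB],
                "smc_pseudo": g.pseudo.get(TargetClass.SMC, False),
                "scpA_pseudo": g.pseudo.get(TargetClass.SCPA, False),
                "scpB_pseudo": g.pseudo.get(TargetClass.SCPB, False),
                "smc_scpA_intervening": smc_scpa,
                "smc_scpA_neighbors": smc_scpa_nb,
                "scpA_scpB_intervening": scpa_scpb,
                "scpA_scpB_neighbors": scpa_scpb_nb,
                "scpA_locus": locus_of.get(TargetClass.SCPA, ""),
                "scpA_middle_length": (
                    anchors.reference_middle_length + g.middle_insertion
                    if has_scpa_protein and scpa_detectable
                    else None
                ),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(genomes=genomes, taxonomy=taxonomy, truth=truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write gff/, proteins/, taxonomy.tsv and truth.tsv under ``out_dir``."""
    out = Path(out_dir)
    (out / "gff").mkdir(parents=True, exist_ok=True)
    (out / "proteins").mkdir(parents=True, exist_ok=True)
    for genome in cohort.genomes:
        (out / "gff" / f"{genome.assembly_id}.gff").write_text(genome.gff_text)
        (out / "proteins" / f"{genome.assembly_id}.faa").write_text(
            genome.fasta_text
        )
    tax_rows = [
        {
            "assembly_id": aid,
            "species": t.species,
            "order": t.order,
            "class": t.class_,
            "phylum": t.phylum,
        }
        for aid, t in cohort.taxonomy.items()
    ]
    pd.DataFrame(tax_rows).to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def build_cohort_matrix(
    seed: int = 0, n_cohorts: int = 30
) -> list[SyntheticCohortSpec]:
    """Seeded matrix of cohort specs covering the generator's factor space.

    Genome archetypes enumerate every presence combination of the three
    classes crossed with the annotation styles (canonical, hypothetical at
    detectable identity, hypothetical diverged beyond detection), pseudogene
    flags and the adjacency arrangements (juxtaposed, separated by 2 or 40
    intervening genes, remote).  Cohorts of 4 to 50 genomes draw from the
    archetype list deterministically.
    """
    archetypes: list[dict] = []
    presences = [
        {TargetClass.SMC: a, TargetClass.SCPA: b, TargetClass.SCPB: c}
        for a in (True, False) for b in (True, False) for c in (True, False)
    ]
    for presence in presences:
        archetypes.append({"presence": dict(presence)})
    # annotation styles per class: detectable homolog and diverged-beyond-
    # detection homolog (both annotated "hypothetical protein")
    for t in ALL_TARGETS:
        for ident in (0.45, 0.60, 0.05):
            archetypes.append(
                {
                    "style": {t: "hypothetical"},
                    "identity": {t: ident},
                }
            )
    # pseudogene-marked copies (canonical product kept)
    for t in ALL_TARGETS:
        archetypes.append({"pseudo": {t: True}})
    # adjacency arrangements
    for smc_scpa in (0, 2, "remote"):
        for scpa_scpb in (0, 40, "remote"):
            archetypes.append(
                {"smc_scpa": smc_scpa, "scpa_scpb": scpa_scpb,
                 "n_filler": max(12, (smc_scpa if isinstance(smc_scpa, int) else 0)
                                 + (scpa_scpb if isinstance(scpa_scpb, int) else 0) + 4)}
            )
    # ScpA middle-region variants
    for k in (1, 5, 18, 35):
        archetypes.append({"middle_insertion": k})

    orders = [
        ("Euryarchaeota", "Thermococci", "Thermococcales"),
        ("Euryarchaeota", "Halobacteria", "Halobacteriales"),
        ("Euryarchaeota", "Methanomicrobia", "Methanosarcinales"),
        ("Korarchaeota", "(No class)", "(No order)"),
        ("Thaumarchaeota", "Nitrososphaeria", "Nitrososphaerales"),
    ]

    rng = np.random.default_rng(seed)
    sizes = [4, 5, 6, 8, 10, 12]
    specs = []
    for c in range(n_cohorts):
        size = 50 if c == n_cohorts - 1 else sizes[c % len(sizes)]
        genomes = []
        # walk the archetype list in a rotating window so every archetype
        # appears in several cohorts
        for i in range(size):
            arche = archetypes[(c * 7 + i) % len(archetypes)]
            phylum, class_, order = orders[int(rng.integers(len(orders)))]
            species = f"Synthspecies c{c}g{i}"
            genomes.append(
                GenomeSpec(
                    assembly_id=f"GCF_{c:03d}{i:04d}.1",
                    species=species,
                    taxon=Taxon(phylum=phylum, class_=class_, order=order,
                                species=species),
                    presence={t: arche.get("presence", {}).get(t, True)
                              for t in ALL_TARGETS},
                    style={t: arche.get("style", {}).get(t, "canonical")
                           for t in ALL_TARGETS},
                    pseudo={t: arche.get("pseudo", {}).get(t, False)
                            for t in ALL_TARGETS},
                    identity={t: arche.get("identity", {}).get(t, 1.0)
                              for t in ALL_TARGETS},
                    smc_scpa=arche.get("smc_scpa"),
                    scpa_scpb=arche.get("scpa_scpb"),
                    middle_insertion=arche.get("middle_insertion", 0),
                    n_filler=arche.get("n_filler", 8),
                )
            )
        specs.append(
            SyntheticCohortSpec(genomes=genomes, seed=int(rng.integers(2**31)))
        )
    return specs
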