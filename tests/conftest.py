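import pytest

from kitescan.annotations import Taxon, parse_gff3
from kitescan.synthetic_data import (
    GenomeSpec,
    SyntheticCohortSpec,
    generate_cohort,
)
from kitescan.targets import TargetClass


def make_taxon(i: int = 1, order: str = "Thermococcales") -> Taxon:
    return Taxon(
        phylum="Euryarchaeota",
        class_="Thermococci",
        order=order,
        species=f"Testspecies sp{i}",
    )


def gff_for(rows: list[str]) -> str:
    return "##gff-version 3\n" + "\n".join(rows) + "\n"


def gene_cds(replicon, start, end, locus, product, pseudo=False, strand="+"):
    """A RefSeq-style gene + CDS row pair."""
    pseudo_attr = ";pseudo=true" if pseudo else ""
    gene = (
        f"{replicon}\tRefSeq\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
        f"ID=gene-{locus};locus_tag={locus}{pseudo_attr}"
    )
    cds = (
        f"{replicon}\tRefSeq\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
        f"ID=cds-{locus};Parent=gene-{locus};locus_tag={locus};"
        f"product={product.replace(' ', '%20') if '%' in product else product}"
    )
    return [gene, cds]


@pytest.fixture
def basic_annotation():
    """Five protein-coding genes and one tRNA on a single replicon."""
    rows = []
    products = [
        ("L001", "chromosome segregation protein SMC"),
        ("L002", "DNA polymerase II large subunit"),
        ("L003", "segregation/condensation protein A"),
        ("L004", "30S ribosomal protein S4"),
        ("L005", "hypothetical protein"),
    ]
    pos = 1
    for locus, product in products:
        rows.extend(gene_cds("chr1", pos, pos + 899, locus, product))
        pos += 1100
    rows.append(
        f"chr1\tRefSeq\tgene\t{pos}\t{pos + 75}\t.\t+\t.\t"
        f"ID=gene-T001;locus_tag=T001;gene_biotype=tRNA"
    )
    rows.append(
        f"chr1\tRefSeq\ttRNA\t{pos}\t{pos + 75}\t.\t+\t.\t"
        f"ID=rna-T001;Parent=gene-T001;product=tRNA-Ala"
    )
    return parse_gff3(gff_for(rows), "GCF_TEST01", make_taxon(1))


@pytest.fixture
def four_genome_cohort():
    """Truth: 4 smc, 4 scpA, 1 scpB, 3 smc-scpA neighbor pairs."""
    absent_b = {TargetClass.SMC: True, TargetClass.SCPA: True,
                TargetClass.SCPB: False}
    specs = [
        GenomeSpec("GCF_A01.1", "Testspecies sp1", make_taxon(1)),
        GenomeSpec("GCF_A02.1", "Testspecies sp2", make_taxon(2),
                   presence=dict(absent_b)),
        GenomeSpec("GCF_A03.1", "Testspecies sp3", make_taxon(3),
                   presence=dict(absent_b)),
        GenomeSpec("GCF_A04.1", "Testspecies sp4", make_taxon(4),
                   presence=dict(absent_b), smc_scpa=2),
    ]
    return generate_cohort(SyntheticCohortSpec(genomes=specs, seed=7))
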