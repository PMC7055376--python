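"""Gene-level model of RefSeq-style GFF3 genome annotations.

RefSeq GFF3 files split each gene across several rows (a ``gene`` row plus
``CDS``/``tRNA``/... children).  The survey counts genes, so this module
unifies the rows into one :class:`GeneFeature` per gene, inheriting the
``product`` string from the first CDS child when the gene row itself lacks
one.  Coordinates stay 1-based inclusive (GFF3 native); they are only ever
used for ordering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

from gffutils.feature import feature_from_line

__all__ = [
    "Taxon",
    "GeneFeature",
    "GenomeAnnotation",
    "GFF3ParseError",
    "parse_gff3",
    "searchable_features",
]

NO_ORDER = "(No order)"
NO_CLASS = "(No class)"


class GFF3ParseError(ValueError):
    """Raised for malformed GFF3 input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Taxon:
    """Taxonomic labels of one genome; missing ranks use explicit markers."""

    phylum: str
    class_: str
    order: str
    species: str

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("Taxon.species must be non-empty")


@dataclass(frozen=True)
class GeneFeature:
    """One gene-level record of an annotation.

    ``coding`` is true when the gene carries (or is) a CDS and can therefore
    hold a protein product name; pseudogenes keep their product and are
    flagged ``is_pseudo`` instead.
    """

    replicon_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    locus_tag: str
    product: str
    is_pseudo: bool
    coding: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.locus_tag or self.product!r}: start > end"
            )


@dataclass
class GenomeAnnotation:
    assembly_id: str
    species: str
    taxonomy: Taxon | None
    features: list[GeneFeature] = field(default_factory=list)

    def feature_by_locus(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"unknown locus {locus_tag!r} in {self.assembly_id}")


_PSEUDO_TRUE = {"true", "1", "yes"}
_GENE_LEVEL = {"gene", "pseudogene"}


def _attr_first(attributes, key: str) -> str:
    vals = attributes.get(key, [])
    return vals[0] if vals else ""


def _is_pseudo(feature) -> bool:
    if feature.featuretype == "pseudogene":
        return True
    if _attr_first(feature.attributes, "pseudo").lower() in _PSEUDO_TRUE:
        return True
    return _attr_first(feature.attributes, "gene_biotype") == "pseudogene"


def parse_gff3(
    stream: TextIO | str,
    assembly_id: str,
    taxonomy: Taxon | None = None,
) -> GenomeAnnotation:
    """Parse a GFF3 stream into a gene-level :class:`GenomeAnnotation`.

    Each ``gene``/``pseudogene`` row becomes one feature; its ``product``
    comes from the row itself or from the first CDS child referencing it via
    ``Parent``.  Orphan CDS rows (no gene parent) become features of their
    own.  Features are returned sorted by (replicon, start, end) and missing
    locus_tags are synthesized as ``REPLICON:START-END`` so downstream
    adjacency logic has unique keys.

    Raises
    ------
    GFF3ParseError
        For a row with the wrong column count or non-numeric coordinates,
        naming the offending line.  An empty stream is not an error.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    genes: dict[str, dict] = {}  # gffutils ID -> record group
    order_of_appearance: list[str] = []
    anonymous = 0

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("##FASTA"):
            break
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GFF3ParseError(
                f"expected 9 tab-separated columns, found {len(cols)}", lineno
            )
        if not (cols[3].isdigit() and cols[4].isdigit()):
            raise GFF3ParseError(
                f"non-numeric coordinates {cols[3]!r}..{cols[4]!r}", lineno
            )
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # pragma: no cover - gffutils edge cases
            raise GFF3ParseError(str(exc), lineno) from exc

        ftype = feat.featuretype
        fid = _attr_first(feat.attributes, "ID")
        parent = _attr_first(feat.attributes, "Parent")

        if ftype in _GENE_LEVEL:
            key = fid or f"_anon{anonymous}"
            anonymous += fid == ""
            genes[key] = {"gene": feat, "cds": [], "children": []}
            order_of_appearance.append(key)
        elif parent and parent in genes:
            group = genes[parent]
            (group["cds"] if ftype == "CDS" else group["children"]).append(feat)
        elif ftype == "CDS":
            # orphan CDS: promote to its own gene-level record
            key = fid or f"_anon{anonymous}"
            anonymous += 1
            genes[key] = {"gene": feat, "cds": [feat], "children": []}
            order_of_appearance.append(key)
        # other parent-less child types (tRNA without gene row, region
        # pragmas as rows, ...) carry no product and are ignored

    features = []
    for key in order_of_appearance:
        group = genes[key]
        gene = group["gene"]
        product = _attr_first(gene.attributes, "product")
        if not product:
            for child in group["cds"]:
                product = _attr_first(child.attributes, "product")
                if product:
                    break
        pseudo = _is_pseudo(gene) or any(_is_pseudo(c) for c in group["cds"])
        biotype = _attr_first(gene.attributes, "gene_biotype")
        coding = bool(group["cds"]) or gene.featuretype == "CDS" or (
            biotype == "protein_coding"
        )
        locus_tag = _attr_first(gene.attributes, "locus_tag")
        if not locus_tag:
            locus_tag = f"{gene.seqid}:{gene.start}-{gene.end}"
        features.append(
            GeneFeature(
                replicon_id=gene.seqid,
                start=int(gene.start),
                end=int(gene.end),
                strand=gene.strand if gene.strand in "+-" else "unknown",
                feature_type=gene.featuretype,
                locus_tag=locus_tag,
                product=product,
                is_pseudo=pseudo,
                coding=coding,
            )
        )

    features.sort(key=lambda f: (f.replicon_id, f.start, f.end))
    features = _deduplicate_locus_tags(features)
    species = taxonomy.species if taxonomy else assembly_id
    return GenomeAnnotation(
        assembly_id=assembly_id,
        species=species,
        taxonomy=taxonomy,
        features=features,
    )


def _deduplicate_locus_tags(features: list[GeneFeature]) -> list[GeneFeature]:
    seen: dict[str, int] = {}
    out = []
    for f in features:
        n = seen.get(f.locus_tag, 0)
        seen[f.locus_tag] = n + 1
        if n:
            f = replace(f, locus_tag=f"{f.locus_tag}.{n + 1}")
        out.append(f)
    return out


def searchable_features(annotation: GenomeAnnotation) -> list[GeneFeature]:
    """Features that can carry a product name: protein-coding + pseudogenes.

    RNA genes and other non-coding records are excluded; genome order is
    preserved.
    """
    return [f for f in annotation.features if f.coding or f.is_pseudo]


def read_taxonomy_table(stream: TextIO | str) -> dict[str, Taxon]:
    """Read the taxonomy sidecar TSV (assembly_id, species, order, class, phylum)."""
    import pandas as pd

    df = pd.read_csv(stream, sep="\t", dtype=str).fillna("")
    required = {"assembly_id", "species", "order", "class", "phylum"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[row["assembly_id"]] = Taxon(
            phylum=row["phylum"] or "(No phylum)",
            class_=row["class"] or NO_CLASS,
            order=row["order"] or NO_ORDER,
            species=row["species"],
        )
    return out
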