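"""Genome data model and readers/writers for FASTA, GFF3, Newick and TSV.

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the file boundary and nowhere else.

A genome is a single replicon (one FASTA record) with an ordered list of
typed gene features. The feature ``category`` drives every downstream
analysis: ``host`` (vertically inherited genes), ``sge`` (selfish genetic
elements such as IS transposases/integrases/repressors), ``trna``,
``lgt`` (laterally transferred genes), ``phage`` and ``other``. In GFF3 the
category travels in a ``category=`` attribute; tRNA features additionally
carry ``anticodon=`` (a DNA triplet; the decoded codon is its reverse
complement).
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mobilecodon")

CATEGORIES = ("host", "sge", "trna", "lgt", "phage", "other")

#: categories whose features are protein coding and enter codon counting
CODING_CATEGORIES = ("host", "sge", "lgt", "phage", "other")


class GenomeCoordinateError(ValueError):
    """A feature interval falls outside its genome sequence."""


class DuplicateTipError(ValueError):
    """A Newick tree contains duplicate tip labels."""


@dataclass
class GeneFeature:
    """One gene on a genome, in 0-based half-open coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    category: str = "other"
    product: str = ""
    anticodon: str | None = None  # tRNA only, DNA alphabet
    unusable: bool = False  # e.g. CDS length not divisible by 3

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown category {self.category!r}")
        if (self.anticodon is not None) != (self.category == "trna"):
            # anticodon present iff the feature is a tRNA
            if self.category == "trna":
                logger.warning("tRNA feature %s lacks an anticodon", self.gene_id)
            else:
                raise ValueError(f"{self.gene_id}: anticodon on non-tRNA feature")
        if self.category != "trna" and (self.end - self.start) % 3 != 0:
            self.unusable = True

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A strain's replicon sequence plus its ordered gene features."""

    strain_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for f in self.features:
            if f.start < 0 or f.end > len(self.sequence):
                raise GenomeCoordinateError(
                    f"{self.strain_id}/{f.gene_id}: [{f.start},{f.end}) outside "
                    f"sequence of length {len(self.sequence)}"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.gene_id))

    def feature_seq(self, feat: GeneFeature) -> str:
        """Coding-orientation sequence of a feature (minus strand revcomp'd)."""
        s = self.sequence[feat.start:feat.end]
        return str(Seq(s).reverse_complement()) if feat.strand == "-" else s

    def features_of(self, *categories: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category in categories]


@dataclass
class StrainTree:
    """A strain phylogeny; a thin wrapper over a rooted dendropy tree."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, text: str) -> "StrainTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except dendropy.dataio.newickreader.NewickReader.\
                NewickReaderDuplicateTaxonError as exc:
            raise DuplicateTipError(str(exc)) from exc
        tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise DuplicateTipError(f"duplicate tip labels in tree: {sorted(labels)}")
        return cls(tree)

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def has_branch_lengths(self) -> bool:
        return any(e.length is not None for e in self.tree.preorder_edge_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


# ---------------------------------------------------------------------------
# FASTA + GFF3
# ---------------------------------------------------------------------------

_GFF_TYPE_BY_CATEGORY = {"trna": "tRNA"}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = urllib.parse.unquote(v.strip())
    return out


def read_genome(fasta_path: str | Path, gff3_path: str | Path,
                strain_id: str | None = None) -> AnnotatedGenome:
    """Read one replicon FASTA plus its GFF3 feature table.

    Unknown feature categories map to ``other``; a CDS whose length is not a
    multiple of 3 is kept but flagged unusable (and excluded from codon
    counting). A feature interval outside the sequence raises
    :class:`GenomeCoordinateError`.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one FASTA record, "
                         f"found {len(records)}")
    rec = records[0]
    features: list[GeneFeature] = []
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff3_path}: malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if seqid != rec.id:
                raise ValueError(
                    f"{gff3_path}: feature seqid {seqid!r} does not match "
                    f"FASTA record {rec.id!r}")
            a = _parse_gff_attributes(attrs)
            category = a.get("category", "")
            if category not in CATEGORIES:
                category = "trna" if ftype == "tRNA" else "other"
            start = int(start1) - 1  # GFF3 is 1-based inclusive
            end = int(end1)
            if start < 0 or end > len(rec.seq):
                raise GenomeCoordinateError(
                    f"{gff3_path}: {a.get('ID', '?')} [{start1},{end1}] outside "
                    f"sequence of length {len(rec.seq)}")
            feat = GeneFeature(
                gene_id=a.get("ID", f"{seqid}:{start1}-{end1}"),
                start=start, end=end, strand=strand,
                category=category,
                product=a.get("product", ""),
                anticodon=a.get("anticodon") if category == "trna" else None,
            )
            if feat.unusable:
                logger.warning("CDS %s length %d not divisible by 3; flagged "
                               "unusable", feat.gene_id, feat.length)
            features.append(feat)
    return AnnotatedGenome(
        strain_id=strain_id or rec.id, sequence=str(rec.seq), features=features
    )


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path,
                 gff3_path: str | Path) -> None:
    """Write a genome as one FASTA record plus a GFF3 feature table."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.strain_id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.strain_id} 1 {len(genome.sequence)}\n")
        for f in genome.features:
            ftype = _GFF_TYPE_BY_CATEGORY.get(f.category, "CDS")
            attrs = [f"ID={f.gene_id}", f"category={f.category}"]
            if f.product:
                attrs.append(f"product={urllib.parse.quote(f.product, safe=' ')}")
            if f.anticodon:
                attrs.append(f"anticodon={f.anticodon}")
            fh.write("\t".join([
                genome.strain_id, "mobilecodon", ftype,
                str(f.start + 1), str(f.end), ".", f.strand, ".",
                ";".join(attrs),
            ]) + "\n")


def extract_cds(genome: AnnotatedGenome,
                categories: Sequence[str] = CODING_CATEGORIES,
                max_n_fraction: float = 0.10) -> list[tuple[str, str]]:
    """Return ``(gene_id, coding sequence)`` for protein-coding features.

    Minus-strand features are reverse-complemented. Features flagged
    unusable, and features with more than ``max_n_fraction`` ambiguous
    bases, are excluded with a warning.
    """
    out: list[tuple[str, str]] = []
    for f in genome.features:
        if f.category not in categories or f.category == "trna":
            continue
        if f.unusable:
            continue
        seq = genome.feature_seq(f)
        if seq.count("N") > max_n_fraction * len(seq):
            logger.warning("CDS %s has >%.0f%% N; excluded", f.gene_id,
                           100 * max_n_fraction)
            continue
        out.append((f.gene_id, seq))
    return out


# ---------------------------------------------------------------------------
# Newick + TSV
# ---------------------------------------------------------------------------

def read_tree(newick_path: str | Path) -> StrainTree:
    return StrainTree.from_newick(Path(newick_path).read_text())


def write_tree(tree: StrainTree, newick_path: str | Path) -> None:
    Path(newick_path).write_text(tree.as_newick() + "\n")


def write_table(rows: Iterable[Sequence], tsv_path: str | Path,
                header: Sequence[str] | None = None) -> None:
    """Write rows as UTF-8 TSV with an optional header row."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        if header is not None:
            fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_genome_dir(directory: str | Path) -> dict[str, AnnotatedGenome]:
    """Read every ``<strain>.fasta`` + ``<strain>.gff3`` pair in a directory."""
    directory = Path(directory)
    genomes: dict[str, AnnotatedGenome] = {}
    for fasta in sorted(directory.glob("*.fasta")):
        gff = fasta.with_suffix(".gff3")
        if not gff.exists():
            raise FileNotFoundError(f"no GFF3 next to {fasta}")
        g = read_genome(fasta, gff, strain_id=fasta.stem)
        genomes[g.strain_id] = g
    if not genomes:
        raise FileNotFoundError(f"no *.fasta genomes under {directory}")
    return genomes


__all__ = [
    "AnnotatedGenome", "GeneFeature", "StrainTree", "GenomeCoordinateError",
    "DuplicateTipError", "CATEGORIES", "CODING_CATEGORIES",
    "read_genome", "write_genome", "extract_cds", "read_tree", "write_tree",
    "write_table", "read_genome_dir",
]
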