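"""Genome and annotation model plus GenBank/FASTA input and output.

Coordinates are 0-based half-open on the forward strand throughout the
library; the CLI converts to 1-based inclusive (GenBank convention) on
output.  Circular genomes are first-class: a gene may wrap the index
origin, in which case ``end <= start`` and the unwrapped length is
``(end - start) mod L``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._util import encode, normalize, revcomp

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
# codon families whose third position is fully degenerate under the standard code
FOURFOLD_PREFIXES = frozenset({"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"})


class GenomeFormatError(ValueError):
    """Raised for malformed or unsupported sequence files."""


class FlaggedGeneError(ValueError):
    """Raised when a CDS violates the coding-sequence contract (e.g. length % 3)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval on the forward strand.

    ``end <= start`` encodes a gene wrapping the index origin of a
    circular genome.
    """

    id: str
    start: int
    end: int
    strand: int  # +1 or -1
    is_cds: bool = True

    def __post_init__(self) -> None:
        if self.strand not in (+1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")

    def length(self, genome_length: int) -> int:
        n = (self.end - self.start) % genome_length
        if n == 0:
            raise ValueError(f"gene {self.id}: zero unwrapped length")
        return n

    def wraps(self) -> bool:
        return self.end <= self.start

    def midpoint(self, genome_length: int) -> int:
        return (self.start + self.length(genome_length) // 2) % genome_length


@dataclass
class AnnotatedGenome:
    """Circular or linear nucleotide sequence with stranded gene annotations."""

    sequence: str
    topology: str = "circular"
    genes: list[GeneAnnotation] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise GenomeFormatError("empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology}")
        self.sequence = normalize(self.sequence)
        L = len(self.sequence)
        for g in self.genes:
            if not (0 <= g.start < L and 0 <= g.end <= L):
                raise ValueError(f"gene {g.id} outside [0, {L})")

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def codes(self) -> np.ndarray:
        """2-bit base codes (A=0, C=1, G=2, T=3, N=4) of the forward strand."""
        return encode(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def slice(self, start: int, end: int) -> str:
        """Forward-strand subsequence [start, end), wrapping when end <= start."""
        if end > start:
            return self.sequence[start:end]
        if not self.is_circular:
            raise ValueError("wrapping slice on a linear genome")
        return self.sequence[start:] + self.sequence[:end]

    def cds_genes(self) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.is_cds]


def coding_sequence(genome: AnnotatedGenome, gene: GeneAnnotation) -> str:
    """5'->3' coding-strand sequence of a CDS gene.

    Reverse-strand genes are reverse-complemented; genes wrapping the
    circular index origin are stitched across the junction.
    """
    if not gene.is_cds:
        raise FlaggedGeneError(f"gene {gene.id} is not a CDS")
    seq = genome.slice(gene.start, gene.end)
    if gene.strand == -1:
        seq = revcomp(seq)
    if len(seq) % 3 != 0:
        raise FlaggedGeneError(
            f"gene {gene.id}: CDS length {len(seq)} not divisible by 3"
        )
    return seq


def third_codon_bases(cds: str, fourfold_only: bool = False) -> str:
    """Concatenated third-position bases of the codons of ``cds``.

    Stop codons are always excluded.  With ``fourfold_only`` the result is
    restricted to codons from the eight standard-code families whose third
    position is fully degenerate (GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN).
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            continue
        if fourfold_only and codon[:2] not in FOURFOLD_PREFIXES:
            continue
        out.append(codon[2])
    return "".join(out)


# ---------------------------------------------------------------------------
# File IO (Biopython-backed)
# ---------------------------------------------------------------------------


def _feature_to_gene(feature: SeqFeature, L: int, idx: int) -> GeneAnnotation | None:
    loc = feature.location
    if loc is None or loc.strand not in (+1, -1):
        return None
    name = feature.qualifiers.get("locus_tag", feature.qualifiers.get("gene", [f"cds_{idx}"]))[0]
    parts = loc.parts
    if len(parts) == 1:
        return GeneAnnotation(name, int(loc.start), int(loc.end), int(loc.strand))
    if len(parts) == 2:
        # join() spanning the circular origin: [x, L) + [0, y) in transcript order
        a, b = sorted(parts, key=lambda p: int(p.start))
        if int(a.start) == 0 and int(b.end) == L:
            return GeneAnnotation(name, int(b.start), int(a.end), int(loc.strand))
    return None


def read_genbank(path) -> AnnotatedGenome:
    """Read a single-record GenBank flatfile into an AnnotatedGenome."""
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise GenomeFormatError(str(exc)) from exc
    seq = str(record.seq)
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise GenomeFormatError(f"{path}: record has no sequence")
    topology = record.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    L = len(seq)
    genes: list[GeneAnnotation] = []
    for idx, feature in enumerate(record.features):
        if feature.type != "CDS":
            continue
        gene = _feature_to_gene(feature, L, idx)
        if gene is None:
            logger.warning("skipping CDS with unresolvable coordinates: %s", feature)
            continue
        genes.append(gene)
    return AnnotatedGenome(seq, topology, genes, id=record.id or record.name)


def read_fasta(path, topology: str = "circular") -> AnnotatedGenome:
    """Read a single-record FASTA; topology is declared by the caller."""
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 1:
        raise GenomeFormatError(
            f"{path}: expected exactly 1 record, found {len(records)}"
        )
    seq = str(records[0].seq)
    if not seq:
        raise GenomeFormatError(f"{path}: empty sequence")
    return AnnotatedGenome(seq, topology, [], id=records[0].id)


def _gene_to_feature(gene: GeneAnnotation, L: int) -> SeqFeature:
    if gene.wraps():
        loc = CompoundLocation(
            [
                SimpleLocation(gene.start, L, gene.strand),
                SimpleLocation(0, gene.end, gene.strand),
            ]
        )
    else:
        loc = SimpleLocation(gene.start, gene.end, gene.strand)
    return SeqFeature(loc, type="CDS", qualifiers={"locus_tag": [gene.id]})


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write a minimal single-record GenBank flatfile."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id or "synthetic",
        name=(genome.id or "synthetic")[:16],
        description="",
        annotations={"molecule_type": "DNA", "topology": genome.topology},
    )
    L = len(genome)
    record.features = [_gene_to_feature(g, L) for g in genome.genes]
    SeqIO.write(record, path, "genbank")


def write_fasta(genome: AnnotatedGenome, path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id or "synthetic", description="")
    SeqIO.write(record, path, "fasta")
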