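"""Readers and writers for the plain-text formats the pipeline touches.

Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive.  Conversions between the two are kept in one place
(:func:`gff_to_internal` / :func:`internal_to_gff`) so they stay involutive.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio.Seq import Seq
from gffutils.feature import feature_from_line

GFF_GENE_TYPE = "gene"
GFF_CLUSTER_TYPE = "gene_cluster"


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class GeneFeature:
    """A protein-coding gene with internal (0-based half-open) coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    cds: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ParseError(
                f"feature {self.gene_id}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClusterInterval:
    """A labeled genomic interval (e.g. a secondary-metabolite gene cluster)."""

    name: str
    contig: str
    start: int
    end: int
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One strain: its contigs plus gene and cluster annotations."""

    strain_id: str
    sequences: dict[str, str]
    genes: list[GeneFeature] = field(default_factory=list)
    clusters: list[ClusterInterval] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ParseError(f"duplicate gene id {g.gene_id} in {self.strain_id}")
            seen.add(g.gene_id)
            if g.contig not in self.sequences:
                raise ParseError(f"feature {g.gene_id}: unknown contig {g.contig}")
            if g.end > len(self.sequences[g.contig]) or g.start < 0:
                raise ParseError(
                    f"feature {g.gene_id}: [{g.start},{g.end}) outside contig "
                    f"{g.contig} of length {len(self.sequences[g.contig])}"
                )

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def proteome(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}

    def cds_set(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes}


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """GFF3 1-based inclusive [start, end] -> 0-based half-open [start-1, end)."""
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> GFF3 1-based inclusive [start+1, end]."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _as_handle(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def parse_fasta(source: str | Path | TextIO) -> dict[str, str]:
    """Parse FASTA into an order-preserving ``{name: sequence}`` mapping.

    Sequences are uppercased; whitespace inside records is ignored.  The name
    is the first whitespace-delimited token of the header.
    """
    handle = _as_handle(source)
    close = isinstance(source, (str, Path))
    try:
        records: dict[str, str] = {}
        name: str | None = None
        chunks: list[str] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                if name in records:
                    raise ParseError(f"line {lineno}: duplicate record name {name}")
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"line {lineno}: sequence data before first FASTA header"
                    )
                chunks.append(line.upper())
        if name is not None:
            records[name] = "".join(chunks)
        return records
    finally:
        if close:
            handle.close()


def write_fasta(
    records: dict[str, str], dest: str | Path | TextIO, width: int = 70
) -> None:
    """Write sequences in input order, wrapped to ``width`` columns."""
    handle: TextIO
    if isinstance(dest, (str, Path)):
        handle = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def fasta_string(records: dict[str, str], width: int = 70) -> str:
    buf = _io.StringIO()
    write_fasta(records, buf, width=width)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str, table: int = 11) -> str:
    """Translate a CDS under the bacterial code, dropping a terminal stop."""
    prot = str(Seq(cds).translate(table=table))
    return prot[:-1] if prot.endswith("*") else prot


def parse_gff(
    source: str | Path | TextIO, sequences: dict[str, str]
) -> tuple[list[GeneFeature], list[ClusterInterval]]:
    """Parse GFF3 gene and gene_cluster features against known contigs.

    Coordinates are converted to internal 0-based half-open; CDS is sliced
    from the contig (reverse-complemented on the minus strand) and translated.
    """
    handle = _as_handle(source)
    close = isinstance(source, (str, Path))
    genes: list[GeneFeature] = []
    clusters: list[ClusterInterval] = []
    try:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.seqid not in sequences:
                raise ParseError(
                    f"feature at {feat.seqid}:{feat.start}-{feat.end}: unknown contig"
                )
            contig_len = len(sequences[feat.seqid])
            if feat.end < feat.start:
                raise ParseError(
                    f"feature {feat.attributes.get('ID', ['?'])[0]}: "
                    f"end {feat.end} < start {feat.start}"
                )
            if feat.start < 1 or feat.end > contig_len:
                raise ParseError(
                    f"feature {feat.attributes.get('ID', ['?'])[0]}: "
                    f"{feat.start}..{feat.end} outside contig of length {contig_len}"
                )
            start, end = gff_to_internal(feat.start, feat.end)
            if feat.featuretype == GFF_GENE_TYPE:
                gene_id = feat.attributes.get("ID", [None])[0]
                if gene_id is None:
                    raise ParseError(f"gene feature without ID at line: {line}")
                region = sequences[feat.seqid][start:end]
                cds = reverse_complement(region) if feat.strand == "-" else region
                genes.append(
                    GeneFeature(
                        gene_id=gene_id,
                        contig=feat.seqid,
                        start=start,
                        end=end,
                        strand=feat.strand,
                        cds=cds,
                        protein=translate_cds(cds),
                    )
                )
            elif feat.featuretype == GFF_CLUSTER_TYPE:
                name = feat.attributes.get("Name", feat.attributes.get("ID", ["?"]))[0]
                gene_list = feat.attributes.get("genes", [""])[0]
                clusters.append(
                    ClusterInterval(
                        name=name,
                        contig=feat.seqid,
                        start=start,
                        end=end,
                        genes=[g for g in gene_list.split(",") if g],
                    )
                )
        return genes, clusters
    finally:
        if close:
            handle.close()


def write_gff(record: GenomeRecord, dest: str | Path | TextIO) -> None:
    """Write gene and cluster features as GFF3 (1-based inclusive)."""
    if isinstance(dest, (str, Path)):
        handle = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        handle.write("##gff-version 3\n")
        for g in record.genes:
            start, end = internal_to_gff(g.start, g.end)
            handle.write(
                f"{g.contig}\tpanclade\t{GFF_GENE_TYPE}\t{start}\t{end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )
        for c in record.clusters:
            start, end = internal_to_gff(c.start, c.end)
            genes = ",".join(c.genes)
            handle.write(
                f"{c.contig}\tpanclade\t{GFF_CLUSTER_TYPE}\t{start}\t{end}\t.\t+\t.\t"
                f"ID={c.name};Name={c.name};genes={genes}\n"
            )
    finally:
        if close:
            handle.close()


def read_genome(
    strain_id: str, fasta_path: str | Path, gff_path: str | Path | None = None
) -> GenomeRecord:
    sequences = parse_fasta(fasta_path)
    genes: list[GeneFeature] = []
    clusters: list[ClusterInterval] = []
    if gff_path is not None:
        genes, clusters = parse_gff(gff_path, sequences)
    rec = GenomeRecord(
        strain_id=strain_id, sequences=sequences, genes=genes, clusters=clusters
    )
    rec.validate()
    return rec


def gc_fraction(seq: str) -> float:
    """GC over unambiguous bases only; NaN-free: raises on empty denominator."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return (seq.count("G") + seq.count("C")) / acgt


def iter_tsv(path: str | Path) -> Iterable[list[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                yield line.split("\t")
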