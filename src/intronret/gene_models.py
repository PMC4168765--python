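"""Gene structures and transcript model construction.

A :class:`GeneModel` is an ordered list of exon intervals (5'->3' in
transcript orientation) on a genomic sequence, plus a frame anchor: the
1-based transcript position known to be the first base of a codon.  From it
two transcript models are built:

* the **spliced** (type I) transcript — exons concatenated;
* an **intron-retained** (type II) transcript — exons plus one designated
  intron left unspliced.  Introns are indexed by the exon they follow, so
  intron ``k`` lies between exon ``k`` and exon ``k+1`` ("intron 8-9" is
  intron index 8).

Every build carries an exact bidirectional transcript<->genomic segment map,
so features found on the transcript (stop codons, primer sites, polyA
signals) can be reported in genomic coordinates and vice versa.  All
user-facing coordinates are 1-based inclusive; minus-strand genes are
handled by reverse-complementing extracted segments, with transcript-level
coordinates always strand-relative 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seq_io import SequenceRecord, reverse_complement

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Segment",
    "TranscriptBuild",
    "CoordinateError",
    "build_spliced",
    "build_intron_retained",
    "map_transcript_to_genomic",
    "map_genomic_to_transcript",
    "read_gff3_gene_models",
    "write_gff3",
    "read_exon_tsv",
    "write_segment_map_tsv",
]


class CoordinateError(ValueError):
    """A coordinate fell outside the sequence or build it refers to."""


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a chromosome/contig."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon intervals plus a transcript-space frame anchor.

    ``exons`` are listed 5'->3' in transcript orientation: genomically
    ascending for ``+`` strand genes, descending for ``-`` strand.
    ``cds_start_in_transcript`` is the 1-based transcript position of the
    first base of a codon (frame anchor).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start_in_transcript: int = 1

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        if self.cds_start_in_transcript < 1:
            raise ValueError("cds_start_in_transcript must be >= 1")
        object.__setattr__(self, "exons", tuple(self.exons))
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"exon on {ex.chrom} but gene on {self.chrom}")
        ordered = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end + 1:
                raise ValueError(
                    f"exons must be non-overlapping and separated by >= 1 nt "
                    f"of intron: {a.start}-{a.end} then {b.start}-{b.end}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def intron(self, k: int) -> GenomicInterval:
        """Intron ``k`` (1-based: between exon k and exon k+1), transcript orientation."""
        if not 1 <= k <= self.n_introns:
            raise CoordinateError(
                f"intron index {k} out of range 1..{self.n_introns}")
        up, down = self.exons[k - 1], self.exons[k]
        if self.strand == "+":
            return GenomicInterval(self.chrom, up.end + 1, down.start - 1, "+")
        return GenomicInterval(self.chrom, down.end + 1, up.start - 1, "-")


@dataclass(frozen=True)
class Segment:
    """One transcript segment: transcript interval <-> genomic interval."""

    t_start: int
    t_end: int
    genomic: GenomicInterval
    label: str  # "exon_i" or "intron_k"

    def __post_init__(self) -> None:
        if self.t_end - self.t_start != len(self.genomic) - 1:
            raise ValueError("transcript and genomic spans differ in length")

    @property
    def is_intron(self) -> bool:
        return self.label.startswith("intron")


@dataclass(frozen=True)
class TranscriptBuild:
    """A spliced or intron-retained transcript with its segment map."""

    transcript_id: str
    variant: str  # "spliced" or "retained:<k>"
    strand: str
    sequence: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        total = sum(s.t_end - s.t_start + 1 for s in self.segments)
        if total != len(self.sequence):
            raise ValueError("segment lengths do not sum to sequence length")
        pos = 1
        for s in self.segments:
            if s.t_start != pos:
                raise ValueError("segments must be contiguous from position 1")
            pos = s.t_end + 1
        n_introns = sum(1 for s in self.segments if s.is_intron)
        if self.variant.startswith("retained") and n_introns != 1:
            raise ValueError("retained build must contain exactly one intron segment")
        if self.variant == "spliced" and n_introns:
            raise ValueError("spliced build must contain no intron segment")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def retained_segment(self) -> Segment:
        for s in self.segments:
            if s.is_intron:
                return s
        raise ValueError(f"build {self.transcript_id!r} has no retained intron")

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(id=self.transcript_id, residues=self.sequence,
                              description=self.variant)


def _extract(genome: Mapping[str, SequenceRecord], iv: GenomicInterval) -> str:
    if iv.chrom not in genome:
        raise CoordinateError(f"no sequence for {iv.chrom!r}")
    rec = genome[iv.chrom]
    try:
        seq = rec.slice_1based(iv.start, iv.end)
    except IndexError as exc:
        raise CoordinateError(str(exc)) from None
    return reverse_complement(seq) if iv.strand == "-" else seq


def _assemble(gene: GeneModel, genome: Mapping[str, SequenceRecord],
              parts: Sequence[tuple[GenomicInterval, str]],
              transcript_id: str, variant: str) -> TranscriptBuild:
    sequence = []
    segments = []
    pos = 1
    for iv, label in parts:
        seq = _extract(genome, iv)
        segments.append(Segment(pos, pos + len(seq) - 1, iv, label))
        sequence.append(seq)
        pos += len(seq)
    return TranscriptBuild(transcript_id=transcript_id, variant=variant,
                           strand=gene.strand, sequence="".join(sequence),
                           segments=tuple(segments))


def build_spliced(gene: GeneModel,
                  genome: Mapping[str, SequenceRecord]) -> TranscriptBuild:
    """Concatenate exon sequences in transcript orientation (type I model)."""
    parts = [
        (GenomicInterval(ex.chrom, ex.start, ex.end, gene.strand), f"exon_{i}")
        for i, ex in enumerate(gene.exons, start=1)
    ]
    return _assemble(gene, genome, parts, f"{gene.gene_id}.spliced", "spliced")


def build_intron_retained(gene: GeneModel, genome: Mapping[str, SequenceRecord],
                          intron_index: int) -> TranscriptBuild:
    """Exons plus intron ``intron_index`` left unspliced (type II model)."""
    intron = gene.intron(intron_index)  # validates the index
    parts: list[tuple[GenomicInterval, str]] = []
    for i, ex in enumerate(gene.exons, start=1):
        parts.append((GenomicInterval(ex.chrom, ex.start, ex.end, gene.strand),
                      f"exon_{i}"))
        if i == intron_index:
            parts.append((intron, f"intron_{intron_index}"))
    return _assemble(gene, genome, parts,
                     f"{gene.gene_id}.retained_intron{intron_index}",
                     f"retained:{intron_index}")


def map_transcript_to_genomic(build: TranscriptBuild, pos: int) -> GenomicInterval:
    """Genomic position (width-1 interval) of transcript position ``pos``."""
    if not 1 <= pos <= len(build.sequence):
        raise CoordinateError(
            f"transcript position {pos} out of range 1..{len(build.sequence)}")
    for s in build.segments:
        if s.t_start <= pos <= s.t_end:
            off = pos - s.t_start
            if s.genomic.strand == "+":
                g = s.genomic.start + off
            else:
                g = s.genomic.end - off
            return GenomicInterval(s.genomic.chrom, g, g, s.genomic.strand)
    raise CoordinateError(f"position {pos} not covered by any segment")  # pragma: no cover


def map_genomic_to_transcript(build: TranscriptBuild, chrom: str, gpos: int) -> int:
    """Transcript position of genomic position ``gpos`` (inverse of the above)."""
    for s in build.segments:
        if s.genomic.chrom == chrom and s.genomic.start <= gpos <= s.genomic.end:
            if s.genomic.strand == "+":
                return s.t_start + (gpos - s.genomic.start)
            return s.t_start + (s.genomic.end - gpos)
    raise CoordinateError(f"{chrom}:{gpos} not covered by build {build.transcript_id!r}")


# ---------------------------------------------------------------------------
# I/O: GFF3 and TSV interchange


def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (exon features grouped by Parent).

    The frame anchor is taken from an mRNA/gene attribute
    ``cds_start_in_transcript`` when present (default 1); GFF phase columns
    are ignored in favour of the transcript-space anchor.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    parents: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        for parent in exon.attributes.get("Parent", ["(orphan)"]):
            parents.setdefault(parent, []).append(exon)
    for parent_id, exons in parents.items():
        strand = exons[0].strand
        chrom = exons[0].seqid
        ivs = sorted(
            (GenomicInterval(e.seqid, e.start, e.end, strand) for e in exons),
            key=lambda iv: iv.start, reverse=(strand == "-"),
        )
        cds_start = 1
        try:
            parent = db[parent_id]
            if "cds_start_in_transcript" in parent.attributes:
                cds_start = int(parent.attributes["cds_start_in_transcript"][0])
        except gffutils.FeatureNotFoundError:
            pass
        models.append(GeneModel(gene_id=parent_id, chrom=chrom, strand=strand,
                                exons=tuple(ivs),
                                cds_start_in_transcript=cds_start))
    return models


def write_gff3(gene: GeneModel, path: str | Path, source: str = "intronret") -> None:
    """Write a gene model as GFF3 (gene + mRNA + exon features)."""
    g_start = min(ex.start for ex in gene.exons)
    g_end = max(ex.end for ex in gene.exons)
    mrna_id = f"{gene.gene_id}.t1"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\t".join([gene.chrom, source, "gene", str(g_start), str(g_end),
                            ".", gene.strand, ".", f"ID={gene.gene_id}"]) + "\n")
        fh.write("\t".join([
            gene.chrom, source, "mRNA", str(g_start), str(g_end), ".",
            gene.strand, ".",
            f"ID={mrna_id};Parent={gene.gene_id};"
            f"cds_start_in_transcript={gene.cds_start_in_transcript}",
        ]) + "\n")
        for i, ex in enumerate(gene.exons, start=1):
            fh.write("\t".join([
                gene.chrom, source, "exon", str(ex.start), str(ex.end), ".",
                gene.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}",
            ]) + "\n")


def read_exon_tsv(path: str | Path, gene_id: str = "gene",
                  strand: str = "+", cds_start: int = 1) -> GeneModel:
    """Read a 4-column exon TSV (chrom, start, end, strand) into a GeneModel."""
    exons = []
    chrom = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, s, e, st = line.split("\t")
            chrom = c
            strand = st
            exons.append((int(s), int(e)))
    if not exons:
        raise ValueError(f"{path}: no exon rows")
    exons.sort(reverse=(strand == "-"))
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=ivs,
                     cds_start_in_transcript=cds_start)


def write_segment_map_tsv(build: TranscriptBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_start\ttranscript_end\tchrom\tgenomic_start\t"
                 "genomic_end\tlabel\n")
        for s in build.segments:
            fh.write(f"{s.t_start}\t{s.t_end}\t{s.genomic.chrom}\t"
                     f"{s.genomic.start}\t{s.genomic.end}\t{s.label}\n")
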