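"""Bundled IL18R1 locus resources and the packaged demonstration locus.

The human *IL18R1* gene (chromosome 2) encodes the ligand-binding alpha
subunit of the IL-18 receptor.  Retention of intron 8-9 in the mature
transcript (the "type II" variant) truncates the receptor shortly after
the transmembrane segment.  This module packages the published,
text-printable facts about that locus:

* the 362 nt type-II query sequence (coding sequence of exons 7-8 followed
  by the first 60 nt of intron 8-9);
* the validated primer panel with binding coordinates and expected product
  sizes on the reference (type I) and intron-retained (type II) templates;
* the hg19 coordinates of intron 8-9 (chr2:103,006,678-103,010,928), the
  transcript coordinate of the exon 8 end (nt 1135) and the frame anchor
  (nt 1132, the first base of the codon for protein residue 370).

From these it assembles a *demonstration locus*: a chr2-anchored sequence
slice in which every printed segment (the 362 nt query, the primer binding
sites at their published coordinates) is embedded verbatim and everything
else is SYNTHETIC seeded background — including the intron continuation
beyond the printed 60 nt, which plants the 22-codon novel C-terminal tail
and stop described for the human variant, an AATAAA signal at intron
position 290, a termination site at 357, and a synthetic Alu-like element
(12 nt target-site duplication, oligo(dA) tail, 79 nt downstream of the
signal).  The demo locus therefore reproduces all printed coordinate
arithmetic exactly, while sequence-level results outside the printed
segments are illustrative only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

from .gene_models import (GeneModel, GenomicInterval, build_intron_retained,
                          build_spliced)
from .insilico_pcr import Primer, find_binding_sites
from .orf_truncation import predict_truncation
from .polya_tts import find_polya_signals
from .repeat_insert import detect_tsd
from .seq_io import SequenceRecord, read_fasta, reverse_complement
from .synthetic_data import (GenerationError, InsertSpec, LocusParams,
                             MAX_RETRIES, SyntheticLocus, _build_insert,
                             random_dna)

__all__ = [
    "CHROM",
    "INTRON_8_9",
    "EXON8_END_TRANSCRIPT",
    "FRAME_ANCHOR",
    "TYPE2_REVERSE_PRIMER_GENOMIC",
    "QUERY_EXONIC_LENGTH",
    "QUERY_INTRONIC_LENGTH",
    "load_query",
    "load_primers",
    "primer_table",
    "build_demo_locus",
    "build_actb_template",
]

CHROM = "chr2"
#: hg19 span of human IL18R1 intron 8-9 (1-based inclusive; 4,251 nt)
INTRON_8_9 = GenomicInterval(CHROM, 103_006_678, 103_010_928, "+")
#: transcript position of the final exon 8 nucleotide on NM_003855.2
EXON8_END_TRANSCRIPT = 1135
#: transcript position of the first base of the codon for protein residue 370
FRAME_ANCHOR = 1132
#: hg19 binding site of the type II reverse primer (inside intron 8-9)
TYPE2_REVERSE_PRIMER_GENOMIC = (103_006_939, 103_006_960)
#: composition of the 362 nt query: exons 7-8 coding sequence + intron start
QUERY_EXONIC_LENGTH = 302
QUERY_INTRONIC_LENGTH = 60

# demo locus layout (exon lengths sum to 1135 = exon 8 transcript end)
_DEMO_EXON_LENGTHS = (180, 120, 160, 180, 120, 73, 151, 151, 200)
_DEMO_UPSTREAM_INTRON = 120   # synthetic introns 1..7
_DEMO_FLANK = 100
#: planted features of the synthetic intron continuation (intron-relative)
DEMO_STOP_INTRON_POSITION = 66      # -> 22 novel codons before the stop
DEMO_POLYA_SIGNAL_POSITION = 290
DEMO_TTS_POSITION = 357
DEMO_TSD_LENGTH = 12
DEMO_TAIL_LENGTH = 15
DEMO_SIGNAL_TO_TSD = 79


def _data_path(name: str):
    return resources.files("intronret.data").joinpath(name)


def load_query() -> SequenceRecord:
    """The 362 nt type-II query sequence packaged with the module."""
    with resources.as_file(_data_path("il18r1_typeII_query_362nt.fasta")) as p:
        return read_fasta(p)[0]


def primer_table() -> list[dict]:
    """The primer panel as a list of dicts (one per primer, TSV columns)."""
    rows = []
    with resources.as_file(_data_path("il18r1_primers.tsv")) as p:
        lines = p.read_text().strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        for col in ("binding_start", "binding_end", "expected_product_bp"):
            row[col] = int(row[col])
        rows.append(row)
    return rows


def load_primers() -> dict[str, Primer]:
    return {
        row["name"]: Primer(name=row["name"], role=row["role"],
                            sequence=row["sequence"])
        for row in primer_table()
    }


@dataclass(frozen=True)
class _DemoLayout:
    exon_coords: tuple[tuple[int, int], ...]
    slice_start: int
    slice_end: int


def _demo_layout() -> _DemoLayout:
    """Genomic exon coordinates anchored so exon 8 ends at the intron start."""
    exon8_end_g = INTRON_8_9.start - 1
    coords = []
    g = exon8_end_g
    for L in reversed(_DEMO_EXON_LENGTHS[:8]):
        coords.append((g - L + 1, g))
        g = g - L - _DEMO_UPSTREAM_INTRON
    coords.reverse()
    exon9 = (INTRON_8_9.end + 1, INTRON_8_9.end + _DEMO_EXON_LENGTHS[8])
    coords.append(exon9)
    slice_start = coords[0][0] - _DEMO_FLANK
    slice_end = exon9[1] + _DEMO_FLANK
    return _DemoLayout(tuple(coords), slice_start, slice_end)


def _assemble_demo(rng: np.random.Generator, query: str,
                   primers: dict[str, Primer]) -> SyntheticLocus:
    layout = _demo_layout()
    exon_lengths = _DEMO_EXON_LENGTHS
    cum8 = sum(exon_lengths[:8])
    assert cum8 == EXON8_END_TRANSCRIPT

    # ---- spliced transcript space (exons 1..9 concatenated) ----
    total = sum(exon_lengths)
    spliced = list(random_dna(rng, total))
    # printed 362 nt query: exons 7-8 coding sequence at transcript 834..1135
    q_exonic = query[:QUERY_EXONIC_LENGTH]
    spliced[cum8 - QUERY_EXONIC_LENGTH: cum8] = q_exonic
    # printed primer sites on the reference transcript
    fw = primers["human_ref_F"]
    spliced[544: 544 + len(fw)] = fw.sequence
    rv = primers["human_ref_R"]
    site = reverse_complement(rv.sequence)
    spliced[1208: 1208 + len(site)] = site
    spliced = "".join(spliced)

    # ---- intron 8-9 (4,251 nt) ----
    intron_len = len(INTRON_8_9)
    q_intron = query[QUERY_EXONIC_LENGTH:]
    tII = primers["human_typeII_R"]
    tII_site = reverse_complement(tII.sequence)
    tII_start = TYPE2_REVERSE_PRIMER_GENOMIC[0] - INTRON_8_9.start + 1  # 262
    sig = DEMO_POLYA_SIGNAL_POSITION
    tsd5_start = sig + 5 + 1 + DEMO_SIGNAL_TO_TSD  # 375

    consensus = random_dna(rng, 300)
    consensus = consensus[:-2] + consensus[-2:].replace("A", "G")
    spec = InsertSpec(tsd_length=DEMO_TSD_LENGTH, tail_length=DEMO_TAIL_LENGTH,
                      transitions=14, transversions=2, deletion_lengths=(2,),
                      signal_to_tsd_distance=DEMO_SIGNAL_TO_TSD)
    body, insert_truth = _build_insert(rng, spec, consensus)

    pieces = [q_intron]                      # intron 1..60 printed
    pieces.append("GC")                      # completes novel codon 21 (non-stop)
    pieces.append("CTG")                     # novel codon 22
    pieces.append("TAA")                     # premature stop at intron 66..68
    pos = 68
    pieces.append(random_dna(rng, tII_start - 1 - pos))
    pieces.append(tII_site)                  # type II reverse primer site 262..283
    pos = tII_start + len(tII_site) - 1
    pieces.append(random_dna(rng, sig - 1 - pos))
    pieces.append("AATAAA")                  # polyA signal 290..295
    pos = sig + 5
    pieces.append(random_dna(rng, tsd5_start - 1 - pos + DEMO_TSD_LENGTH))
    pos = tsd5_start - 1 + DEMO_TSD_LENGTH
    head = "".join(pieces)
    tsd_site = head[tsd5_start - 1: tsd5_start - 1 + DEMO_TSD_LENGTH]
    pieces.append(body)
    pieces.append(tsd_site)
    pos += len(body) + DEMO_TSD_LENGTH
    pieces.append(random_dna(rng, intron_len - pos))
    intron = "".join(pieces)
    assert len(intron) == intron_len

    # ---- genome slice ----
    chunks = [random_dna(rng, _DEMO_FLANK)]
    exons = []
    t = 0
    for i, L in enumerate(exon_lengths):
        exons.append(spliced[t: t + L])
        t += L
    for i, ex in enumerate(exons[:8]):
        chunks.append(ex)
        if i < 7:
            chunks.append(random_dna(rng, _DEMO_UPSTREAM_INTRON))
    chunks.append(intron)
    chunks.append(exons[8])
    chunks.append(random_dna(rng, _DEMO_FLANK))
    genome_seq = "".join(chunks)
    layout_len = layout.slice_end - layout.slice_start + 1
    assert len(genome_seq) == layout_len

    genome = {CHROM: SequenceRecord(id=CHROM, residues=genome_seq,
                                    description="synthetic hg19-anchored slice",
                                    origin=layout.slice_start)}
    gene = GeneModel(
        gene_id="IL18R1_demo", chrom=CHROM, strand="+",
        exons=tuple(GenomicInterval(CHROM, s, e, "+")
                    for s, e in layout.exon_coords),
        cds_start_in_transcript=FRAME_ANCHOR,
    )
    insert_start = tsd5_start + DEMO_TSD_LENGTH
    truth = {
        "exon_lengths": list(exon_lengths),
        "retained_intron": 8,
        "frame_anchor": FRAME_ANCHOR,
        "boundary_phase": 1,
        "novel_length": 22,
        "stop_intron_position": DEMO_STOP_INTRON_POSITION,
        "polya_signal_pos": DEMO_POLYA_SIGNAL_POSITION,
        "tts_pos": DEMO_TTS_POSITION,
        "insert": {
            "interval": [insert_start, insert_start + len(body) - 1],
            "tsd_length": DEMO_TSD_LENGTH,
            "tail_length": DEMO_TAIL_LENGTH,
            "transitions": 14,
            "transversions": 2,
            "deletion_lengths": [2],
            "signal_to_tsd_distance": DEMO_SIGNAL_TO_TSD,
            **insert_truth,
        },
        "consensus": consensus,
        "expected_products": {"human_ref": 687, "human_typeII": 874},
    }
    params = LocusParams(
        exon_lengths=exon_lengths,
        intron_lengths=(_DEMO_UPSTREAM_INTRON,) * 7 + (intron_len,),
        retained_intron=8, cds_start=FRAME_ANCHOR, boundary_phase=1,
        novel_length=22, polya_signal_pos=DEMO_POLYA_SIGNAL_POSITION,
        tts_pos=DEMO_TTS_POSITION, chrom=CHROM, gene_id="IL18R1_demo")
    return SyntheticLocus(genome=genome, gene=gene,
                          primers=[primers["human_ref_F"],
                                   primers["human_ref_R"],
                                   primers["human_typeII_R"]],
                          truth=truth, params=params, seed=-1)


def _validate_demo(locus: SyntheticLocus, primers: dict[str, Primer]) -> None:
    spliced = build_spliced(locus.gene, locus.genome)
    retained = build_intron_retained(locus.gene, locus.genome, 8)
    report = predict_truncation(retained, FRAME_ANCHOR)
    if report.novel_length != 22 or report.stop_codon is None \
            or report.stop_codon.intron_relative_position != DEMO_STOP_INTRON_POSITION:
        raise GenerationError("demo truncation features not as planted")
    seg = retained.retained_segment
    intron_seq = retained.sequence[seg.t_start - 1: seg.t_end]
    hits = find_polya_signals(intron_seq)
    if [h.position for h in hits] != [DEMO_POLYA_SIGNAL_POSITION]:
        raise GenerationError("demo polyA signal not unique")
    it = locus.truth["insert"]
    tsd = detect_tsd(intron_seq, tuple(it["interval"]))
    if tsd is None or tsd.length != DEMO_TSD_LENGTH or tsd.mismatches:
        raise GenerationError("demo TSD not recovered")
    s_rec, r_rec = spliced.to_record(), retained.to_record()
    for name, template, n_expected in (
            ("human_ref_F", s_rec, 1), ("human_ref_F", r_rec, 1),
            ("human_ref_R", s_rec, 1), ("human_typeII_R", s_rec, 0),
            ("human_typeII_R", r_rec, 1)):
        if len(find_binding_sites(template, primers[name])) != n_expected:
            raise GenerationError(f"demo primer {name} site count wrong")


def build_demo_locus(seed: int = 0) -> SyntheticLocus:
    """The packaged human demonstration locus (printed data + synthetic fill).

    Deterministic for a fixed seed; the locus is validated by re-detection
    of every planted feature before being returned.
    """
    query = load_query().residues
    primers = load_primers()
    root = np.random.SeedSequence(seed)
    last: Optional[Exception] = None
    for attempt in range(MAX_RETRIES):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(2000 + attempt,)))
        try:
            locus = _assemble_demo(rng, query, primers)
            _validate_demo(locus, primers)
        except GenerationError as exc:
            last = exc
            continue
        locus.seed = seed
        locus.truth["seed"] = seed
        return locus
    raise GenerationError(f"could not assemble demo locus: {last}")


def build_actb_template(seed: int = 0, length: int = 700) -> SequenceRecord:
    """Synthetic rat Actb-like control template with the published primer
    sites planted at their printed transcript coordinates (28-51, 657-676)."""
    primers = load_primers()
    fw, rv = primers["rat_actb_F"], primers["rat_actb_R"]
    root = np.random.SeedSequence(seed)
    for attempt in range(MAX_RETRIES):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(3000 + attempt,)))
        seq = list(random_dna(rng, length))
        seq[27: 27 + len(fw)] = fw.sequence
        site = reverse_complement(rv.sequence)
        seq[656: 656 + len(site)] = site
        rec = SequenceRecord(id="rat_actb_synthetic", residues="".join(seq),
                             description="synthetic control template")
        if (len(find_binding_sites(rec, fw)) == 1
                and len(find_binding_sites(rec, rv)) == 1):
            return rec
    raise GenerationError("could not assemble Actb template")
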