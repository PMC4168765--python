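"""Reading-frame continuation across the exon/intron boundary.

When an intron is retained in a mature transcript, the ribosome is expected
to read straight across the former splice donor site into intronic sequence
until it meets an in-frame stop codon.  This module propagates the reading
frame from an upstream anchor (a transcript position known to start a
codon), identifies the boundary codon (the codon split between exonic and
intronic bases), translates the novel C-terminal region, and locates the
premature stop.

The *novel C-terminal peptide* is defined operationally as the residues
encoded by codons containing at least one intronic nucleotide, up to but
excluding the stop codon.  Under this definition a codon split across the
boundary contributes the first novel residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

from .gene_models import TranscriptBuild
from .pairwise_align import AlignParams, PairwiseAlignment, align

__all__ = [
    "STOP_CODONS",
    "TruncationReport",
    "StopCodon",
    "AnchorError",
    "translate",
    "scan_inframe_stops",
    "predict_truncation",
    "compare_cterminal",
]

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TABLE = dict(standard_dna_table.forward_table)


class AnchorError(ValueError):
    """Frame anchor inconsistent with the build (inside/downstream of the intron)."""


def translate(dna: str, frame_offset: int = 0) -> str:
    """Translate ``dna`` in the given frame with the standard nuclear code.

    Stop codons render ``*``.  Any codon containing a base outside
    {A, C, G, T} (N or another ambiguity code) renders ``X`` and is never
    treated as a stop: conservative for ambiguous genome assemblies.
    Trailing bases that do not fill a codon are dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    out = []
    for i in range(frame_offset, len(dna) - 2, 3):
        codon = dna[i:i + 3]
        if codon in _CODON_TABLE:
            out.append(_CODON_TABLE[codon])
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def scan_inframe_stops(dna: str, frame_offset: int = 0) -> list[int]:
    """1-based start positions of all in-frame stop codons in ``dna``."""
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    return [
        i + 1
        for i in range(frame_offset, len(dna) - 2, 3)
        if dna[i:i + 3] in STOP_CODONS
    ]


@dataclass(frozen=True)
class StopCodon:
    triplet: str
    transcript_position: int        # 1-based codon start on the transcript
    intron_relative_position: int   # 1-based codon start within the retained intron

    def __post_init__(self) -> None:
        if self.triplet not in STOP_CODONS:
            raise ValueError(f"{self.triplet!r} is not a stop codon")


@dataclass(frozen=True)
class TruncationReport:
    """Predicted truncated protein of an intron-retained transcript."""

    frame_anchor: int
    boundary_codon: Optional[tuple[int, int]]  # (exonic nt, intronic nt); None on clean boundary
    shared_prefix_length: int                  # residues before the first novel codon
    novel_peptide: str
    stop_codon: Optional[StopCodon]
    no_stop: bool = False

    @property
    def novel_length(self) -> int:
        return len(self.novel_peptide)

    def to_dict(self) -> dict:
        return {
            "frame_anchor": self.frame_anchor,
            "boundary_codon": (None if self.boundary_codon is None
                               else {"exonic_nt": self.boundary_codon[0],
                                     "intronic_nt": self.boundary_codon[1]}),
            "shared_prefix_length": self.shared_prefix_length,
            "novel_peptide": self.novel_peptide,
            "novel_length": self.novel_length,
            "stop_codon": (None if self.stop_codon is None else {
                "triplet": self.stop_codon.triplet,
                "transcript_position": self.stop_codon.transcript_position,
                "intron_relative_position": self.stop_codon.intron_relative_position,
            }),
            "no_stop": self.no_stop,
        }


def predict_truncation(build: TranscriptBuild,
                       frame_anchor: int) -> TruncationReport:
    """Continue the reading frame into the retained intron and find the stop.

    Codons are scanned 5'->3' from ``frame_anchor``.  The first codon that
    overlaps the retained segment starts the novel region; the report
    terminates at the first in-frame stop at or after that codon.  If no
    stop occurs before the transcript end, the peptide runs to the last
    complete codon and the report is flagged ``no_stop``.
    """
    retained = build.retained_segment
    seq = build.sequence
    if not 1 <= frame_anchor <= len(seq):
        raise AnchorError(f"frame anchor {frame_anchor} outside transcript "
                          f"1..{len(seq)}")
    if frame_anchor >= retained.t_start:
        raise AnchorError(
            f"frame anchor {frame_anchor} must be upstream of the retained "
            f"segment (starts at {retained.t_start})")

    novel: list[str] = []
    boundary: Optional[tuple[int, int]] = None
    shared_prefix = 0
    stop: Optional[StopCodon] = None
    no_stop = False
    in_novel = False

    i = frame_anchor - 1  # 0-based codon start
    while True:
        if i + 3 > len(seq):
            no_stop = True
            break
        codon = seq[i:i + 3]
        codon_start = i + 1
        codon_end = i + 3
        if not in_novel:
            if codon_end >= retained.t_start:
                in_novel = True
                if codon_start < retained.t_start:
                    exonic = retained.t_start - codon_start
                    boundary = (exonic, 3 - exonic)
            else:
                shared_prefix += 1
        if in_novel:
            if codon in STOP_CODONS:
                stop = StopCodon(
                    triplet=codon,
                    transcript_position=codon_start,
                    intron_relative_position=codon_start - retained.t_start + 1,
                )
                break
            novel.append(translate(codon))
        i += 3

    return TruncationReport(frame_anchor=frame_anchor, boundary_codon=boundary,
                            shared_prefix_length=shared_prefix,
                            novel_peptide="".join(novel), stop_codon=stop,
                            no_stop=no_stop)


def compare_cterminal(predicted: str, motif: str,
                      params: AlignParams | None = None) -> PairwiseAlignment:
    """Best local alignment of a predicted C-terminal tail against a motif.

    Used to ask whether the novel peptide resembles a known signalling-domain
    segment (e.g. the TIR-domain "Box 1" motif).  An empty predicted tail
    yields an empty alignment with score 0.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not predicted:
        return PairwiseAlignment("", "", 0.0)
    if params is None:
        params = AlignParams.local_defaults()
    elif params.mode != "local":
        raise ValueError("C-terminal motif comparison uses local mode")
    return align(predicted, motif, params)
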