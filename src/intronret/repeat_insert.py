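"""Characterization of a candidate retrotransposon insertion.

Target-primed reverse transcription (the mechanism behind Alu/LINE
insertion) leaves two diagnostic scars: a short direct repeat of host
sequence flanking the insert (target-site duplication, TSD) and an
oligo(dA)-rich tail at the insert's 3' end.  This module detects both,
measures the distance from an upstream polyadenylation signal to the 5'
TSD copy, and quantifies divergence from a user-supplied consensus element
as a transition/transversion/gap spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .pairwise_align import (AlignParams, PairwiseAlignment,
                             SubstitutionSpectrum, align,
                             substitution_spectrum)
from .seq_io import SequenceRecord

__all__ = [
    "TSD",
    "InsertionCall",
    "detect_tsd",
    "measure_polyA_tail",
    "compare_to_consensus",
    "characterize_insertion",
]


@dataclass(frozen=True)
class TSD:
    sequence: str        # the 5' copy
    length: int
    mismatches: int      # between the two copies


@dataclass(frozen=True)
class InsertionCall:
    insert_interval: tuple[int, int]   # 1-based on the host sequence
    tsd: Optional[TSD]
    polyA_tail_length: int
    signal_to_tsd_distance: Optional[int]  # nt between signal end and 5' TSD start
    consensus_spectrum: Optional[SubstitutionSpectrum] = None
    full_spectrum: Optional[SubstitutionSpectrum] = None

    def to_dict(self) -> dict:
        return {
            "insert_interval": list(self.insert_interval),
            "tsd": (None if self.tsd is None else {
                "sequence": self.tsd.sequence,
                "length": self.tsd.length,
                "mismatches": self.tsd.mismatches,
            }),
            "polyA_tail_length": self.polyA_tail_length,
            "signal_to_tsd_distance": self.signal_to_tsd_distance,
            "consensus_spectrum": (None if self.consensus_spectrum is None
                                   else list(self.consensus_spectrum)),
            "full_spectrum": (None if self.full_spectrum is None
                              else list(self.full_spectrum)),
        }


def detect_tsd(host: str, insert_interval: tuple[int, int],
               min_len: int = 5, max_len: int = 25,
               max_mismatch: int = 1) -> Optional[TSD]:
    """Longest direct repeat flanking the insert, or None.

    One copy must end immediately 5' of the insert and the other begin
    immediately 3' of it; copies may differ by up to ``max_mismatch``
    substitutions.  Bounds are config defaults typical for
    retrotransposition scars.
    """
    start, end = insert_interval
    if not (1 < start <= end < len(host)):
        raise ValueError("insert interval must lie strictly inside the host")
    for length in range(max_len, min_len - 1, -1):
        if start - 1 - length < 0 or end + length > len(host):
            continue
        left = host[start - 1 - length: start - 1]
        right = host[end: end + length]
        mm = sum(1 for a, b in zip(left, right) if a != b)
        if mm <= max_mismatch:
            return TSD(sequence=left, length=length, mismatches=mm)
    return None


def measure_polyA_tail(insert: str, min_run: int = 8,
                       max_interruptions: int = 1) -> int:
    """Length of the maximal qualifying A-rich suffix of ``insert``.

    A qualifying suffix starts and ends with A, contains at most
    ``max_interruptions`` non-A bases, and at least ``min_run`` A's in
    total.  Returns 0 when no suffix qualifies.
    """
    if not insert:
        return 0
    best = 0
    n_a = 0
    interruptions = 0
    n = len(insert)
    if insert[-1] != "A":
        return 0
    for span, ch in enumerate(reversed(insert), start=1):
        if ch == "A":
            n_a += 1
            if n_a >= min_run:
                best = span
        else:
            interruptions += 1
            if interruptions > max_interruptions:
                break
    return best


def compare_to_consensus(insert: str, consensus: SequenceRecord,
                         params: AlignParams | None = None,
                         region: str = "consensus") -> SubstitutionSpectrum:
    """Divergence spectrum of an insert against a consensus element.

    The two sequences are globally aligned with free end gaps so that
    flanking host bases and the oligo(dA) tail fall into unpenalised
    terminal gaps.  With ``region="consensus"`` (default) the spectrum is
    restricted to the consensus-covered span, the convention for reporting
    element divergence; ``region="full"`` counts the whole alignment.
    """
    if not insert or not consensus.residues:
        raise ValueError("insert and consensus must be non-empty")
    if params is None:
        params = AlignParams()
    if params.mode != "global":
        raise ValueError("consensus comparison uses global free-end-gaps mode")
    aln = align(insert, consensus.residues, params)
    if region == "full":
        return substitution_spectrum(aln)
    if region != "consensus":
        raise ValueError(f"unknown region {region!r}")
    cols_b = [c != "-" for c in aln.aligned_b]
    first = cols_b.index(True)
    last = len(cols_b) - 1 - cols_b[::-1].index(True)
    trimmed = PairwiseAlignment(aln.aligned_a[first:last + 1],
                                aln.aligned_b[first:last + 1], aln.score)
    return substitution_spectrum(trimmed)


def characterize_insertion(host: str, insert_interval: tuple[int, int],
                           consensus: Optional[SequenceRecord] = None,
                           signal_end: Optional[int] = None,
                           tsd_min_len: int = 5, tsd_max_len: int = 25,
                           tsd_max_mismatch: int = 1,
                           tail_min_run: int = 8,
                           tail_max_interruptions: int = 1) -> InsertionCall:
    """Full characterization of one candidate insertion on a host sequence.

    ``signal_end`` is the 1-based end of an upstream polyA signal on the
    same coordinate system; the reported distance is the number of host
    nucleotides strictly between the signal end and the 5' TSD start (the
    TSD start being ``insert_interval.start - tsd_length``).
    """
    tsd = detect_tsd(host, insert_interval, min_len=tsd_min_len,
                     max_len=tsd_max_len, max_mismatch=tsd_max_mismatch)
    insert = host[insert_interval[0] - 1: insert_interval[1]]
    tail = measure_polyA_tail(insert, min_run=tail_min_run,
                              max_interruptions=tail_max_interruptions)
    distance = None
    if signal_end is not None and tsd is not None:
        tsd5_start = insert_interval[0] - tsd.length
        distance = tsd5_start - signal_end - 1
    spectrum = full = None
    if consensus is not None:
        core = insert[: len(insert) - tail] if tail else insert
        spectrum = compare_to_consensus(core, consensus, region="consensus")
        full = compare_to_consensus(core, consensus, region="full")
    return InsertionCall(insert_interval=insert_interval, tsd=tsd,
                         polyA_tail_length=tail,
                         signal_to_tsd_distance=distance,
                         consensus_spectrum=spectrum, full_spectrum=full)
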