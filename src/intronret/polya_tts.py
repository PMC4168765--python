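"""Polyadenylation-signal scanning and transcription-termination calling.

A retained intron that becomes the 3' end of a transcript needs its own
polyadenylation signal.  This module scans for signal hexamers (AATAAA by
default; variant hexamers are opt-in), and calls a transcription
termination site (TTS) either from EST/cDNA evidence — the 3'-most intron
position covered by the EST after trimming its oligo(dA) tail — or, with no
EST, as a signal-anchored interval (cleavage typically occurs a short,
variable distance downstream of the hexamer, so no point estimate is
invented).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .orf_truncation import TruncationReport
from .pairwise_align import AlignParams, align
from .repeat_insert import measure_polyA_tail
from .seq_io import SequenceRecord

__all__ = [
    "DEFAULT_MOTIFS",
    "PolyASignal",
    "TTSCall",
    "ESTSupport",
    "ThreePrimeSummary",
    "find_polya_signals",
    "est_support",
    "characterize_3prime_region",
    "signals_to_bed",
]

DEFAULT_MOTIFS = frozenset({"AATAAA"})


@dataclass(frozen=True)
class PolyASignal:
    motif: str
    position: int  # 1-based start on the scanned sequence (intron-relative here)
    conserved: Optional[bool] = None  # set by the comparative module

    @property
    def end(self) -> int:
        return self.position + len(self.motif) - 1


@dataclass(frozen=True)
class TTSCall:
    """A termination-site call, either a point (EST evidence) or an interval."""

    position: int                    # 1-based intron-relative 3' limit
    evidence: str                    # "est" | "signal-only"
    supporting_est_id: Optional[str] = None
    window_end: Optional[int] = None  # set for signal-only interval calls


@dataclass(frozen=True)
class ESTSupport:
    supported: bool
    covered_interval: Optional[tuple[int, int]] = None  # 1-based on the intron
    tts: Optional[TTSCall] = None
    trimmed_tail_length: int = 0


@dataclass(frozen=True)
class ThreePrimeSummary:
    stop_to_signal: Optional[int]
    signal_to_tts: Optional[int]
    utr_length: Optional[int]   # stop codon end to TTS, inclusive
    atypical_ordering: bool


def find_polya_signals(seq: str,
                       motifs: Iterable[str] = DEFAULT_MOTIFS) -> list[PolyASignal]:
    """All exact occurrences of the signal hexamers, ascending positions."""
    motifs = sorted(set(m.upper() for m in motifs))
    for m in motifs:
        if len(m) != 6:
            raise ValueError(f"polyA signal motifs are hexamers; got {m!r}")
    hits = []
    for m in motifs:
        start = 0
        while True:
            i = seq.find(m, start)
            if i < 0:
                break
            hits.append(PolyASignal(motif=m, position=i + 1))
            start = i + 1
    hits.sort(key=lambda s: s.position)
    return hits


def _trim_polya_tail(seq: str, min_run: int, max_interruptions: int) -> tuple[str, int]:
    tail = measure_polyA_tail(seq, min_run=min_run,
                              max_interruptions=max_interruptions)
    return seq[: len(seq) - tail], tail


def est_support(est: SequenceRecord, intron: SequenceRecord,
                min_tail_run: int = 8, max_tail_interruptions: int = 1,
                min_score: float = 50.0,
                params: AlignParams | None = None) -> ESTSupport:
    """Map an EST onto a retained intron and call the TTS at its 3' limit.

    The EST's trailing oligo(dA) run (template-independent polyadenylation)
    is trimmed first; the remainder is locally aligned to the intron.  The
    covered interval is the aligned intron span, and the TTS is its 3' end.
    A sub-threshold alignment returns ``supported=False`` rather than raising.
    """
    if params is None:
        params = AlignParams.local_defaults()
    trimmed, tail = _trim_polya_tail(est.residues, min_tail_run,
                                     max_tail_interruptions)
    if not trimmed:
        return ESTSupport(supported=False, trimmed_tail_length=tail)
    aln = align(trimmed, intron.residues, params)
    if aln.score < min_score or not aln.aligned_b:
        return ESTSupport(supported=False, trimmed_tail_length=tail)
    # intron span of the local alignment: locate the aligned (degapped)
    # intron substring
    intron_part = aln.aligned_b.replace("-", "")
    start0 = intron.residues.find(intron_part)
    if start0 < 0:  # pragma: no cover - local alignment is a substring by construction
        return ESTSupport(supported=False, trimmed_tail_length=tail)
    interval = (start0 + 1, start0 + len(intron_part))
    tts = TTSCall(position=interval[1], evidence="est",
                  supporting_est_id=est.id)
    return ESTSupport(supported=True, covered_interval=interval, tts=tts,
                      trimmed_tail_length=tail)


def signal_only_tts(signal: PolyASignal, window: int = 40) -> TTSCall:
    """Interval TTS call downstream of a signal when no EST is available."""
    return TTSCall(position=signal.end, evidence="signal-only",
                   window_end=signal.end + window)


def characterize_3prime_region(truncation: TruncationReport,
                               signals: Sequence[PolyASignal],
                               tts: Optional[TTSCall]) -> ThreePrimeSummary:
    """Distances stop->signal and signal->TTS on intron-relative coordinates.

    Distances are differences of 1-based start positions (signal start minus
    stop-codon start; TTS minus signal start).  A misordered arrangement
    (TTS upstream of the signal, or signal upstream of the stop) is flagged
    ``atypical_ordering`` rather than treated as an error.
    """
    stop = truncation.stop_codon
    signal = signals[0] if signals else None
    stop_to_signal = signal_to_tts = utr = None
    atypical = False
    if stop is not None and signal is not None:
        stop_to_signal = signal.position - stop.intron_relative_position
        if stop_to_signal < 0:
            atypical = True
    if signal is not None and tts is not None:
        signal_to_tts = tts.position - signal.position
        if signal_to_tts < 0:
            atypical = True
    if stop is not None and tts is not None:
        utr = tts.position - (stop.intron_relative_position + 3) + 1
    return ThreePrimeSummary(stop_to_signal=stop_to_signal,
                             signal_to_tts=signal_to_tts, utr_length=utr,
                             atypical_ordering=atypical)


def signals_to_bed(signals: Sequence[PolyASignal], chrom: str,
                   offset: int = 0) -> str:
    """Render signals as BED lines (0-based half-open).

    ``offset`` shifts intron-relative positions onto another coordinate
    system (e.g. genomic: pass intron genomic start - 1).
    """
    lines = []
    for s in signals:
        start0 = s.position - 1 + offset
        lines.append(f"{chrom}\t{start0}\t{start0 + len(s.motif)}\t{s.motif}")
    return "\n".join(lines) + ("\n" if lines else "")
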