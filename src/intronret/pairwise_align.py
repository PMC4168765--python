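"""Deterministic pairwise alignment with identity/positive/gap statistics.

Two modes are exposed, matching how truncated-transcript evidence is usually
assessed:

* ``global`` — global alignment with *free end gaps* under an affine gap
  model (a gap of length L costs ``gap_open + (L-1) * gap_extend``; terminal
  gaps are unpenalised).  Suitable for aligning a sequencing read against a
  longer predicted transcript.
* ``local`` — best-scoring local alignment (Smith-Waterman semantics, empty
  alignment with score 0 allowed).

The engine is Biopython's :class:`Bio.Align.PairwiseAligner`; this module
fixes the parameterisation, extracts gapped strings, and adds the summary
statistics (identities / IUPAC-compatible positives / gaps) and the
transition/transversion/gap-event spectrum used for repeat-element
divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "AlignParams",
    "AlignmentStats",
    "PairwiseAlignment",
    "SubstitutionSpectrum",
    "align",
    "alignment_stats",
    "substitution_spectrum",
    "format_alignment",
]

# IUPAC letter -> set of unambiguous bases it stands for
_IUPAC_SETS = {code: set(bases) for code, bases in ambiguous_dna_values.items()}
_IUPAC_SETS["N"] = set("ACGT")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for :func:`align`.

    Defaults follow common nucleotide practice (match +5 / mismatch -4) with
    the gap penalties used for read-vs-prediction comparison (open 12,
    extend 3).  ``local_defaults`` gives the EMBOSS-Water-style setting
    (open 10, extend 0.5) conventionally used for local DNA alignment.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 12.0
    gap_extend: float = 3.0
    mode: str = "global"  # "global" (free end gaps) | "local"

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")

    @staticmethod
    def local_defaults() -> "AlignParams":
        return AlignParams(match=5.0, mismatch=-4.0, gap_open=10.0,
                           gap_extend=0.5, mode="local")


@dataclass(frozen=True)
class AlignmentStats:
    identities: int
    positives: int
    gaps: int
    length: int

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.identities / self.length if self.length else 0.0

    @property
    def pct_positives(self) -> float:
        return 100.0 * self.positives / self.length if self.length else 0.0

    @property
    def pct_gaps(self) -> float:
        return 100.0 * self.gaps / self.length if self.length else 0.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A computed alignment: equal-length gapped strings plus the score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def degapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Mismatch/gap composition of a nucleotide alignment."""

    transitions: int
    transversions: int
    gap_events: int  # maximal gap runs (either strand)
    gap_nt: int      # total gapped columns

    def __iter__(self):
        return iter((self.transitions, self.transversions, self.gap_events, self.gap_nt))


_VALID_CHARS = frozenset("ABCDEFGHIKLMNPQRSTVWXYZU*")


def _check_alphabets(a: str, b: str) -> None:
    # DNA and protein alphabets overlap (every ACGT string is a valid
    # peptide), so only clearly invalid characters are rejected.
    bad = (set(a) | set(b)) - _VALID_CHARS
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # first gapped residue costs gap_open, each further one gap_extend
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if params.mode == "global":
        aligner.mode = "global"
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:
        aligner.mode = "local"
    return aligner


def align(a: str, b: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimally align ``a`` and ``b`` under ``params`` (default global mode).

    Deterministic: among co-optimal tracebacks the engine's first (a fixed,
    input-determined order) is returned.  In local mode two sequences with no
    positive-scoring subpath yield an empty alignment with score 0.
    """
    if params is None:
        params = AlignParams()
    if not a or not b:
        if params.mode == "local":
            return PairwiseAlignment("", "", 0.0)
        raise ValueError("global alignment requires non-empty sequences")
    _check_alphabets(a, b)
    aligner = _make_aligner(params)
    try:
        result = aligner.align(a, b)
        aln = result[0]
    except (ValueError, IndexError):
        # local mode with nothing positive to align
        return PairwiseAlignment("", "", 0.0)
    score = float(aln.score)
    if params.mode == "local" and score <= 0:
        return PairwiseAlignment("", "", 0.0)
    return PairwiseAlignment(str(aln[0]), str(aln[1]), score)


def _compatible(x: str, y: str) -> bool:
    sx = _IUPAC_SETS.get(x, {x})
    sy = _IUPAC_SETS.get(y, {y})
    return bool(sx & sy)


def alignment_stats(aln: PairwiseAlignment,
                    positive_rule: str = "iupac") -> AlignmentStats:
    """Identities / positives / gaps over the alignment length.

    ``positives`` counts identical columns plus columns whose IUPAC ambiguity
    sets intersect (e.g. R vs A); with ``positive_rule="identity"`` positives
    equal identities.
    """
    ident = pos = gaps = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y:
            ident += 1
            pos += 1
        elif positive_rule == "iupac" and _compatible(x, y):
            pos += 1
    return AlignmentStats(identities=ident, positives=pos, gaps=gaps,
                          length=aln.length)


def substitution_spectrum(aln: PairwiseAlignment) -> SubstitutionSpectrum:
    """Transition/transversion counts and gap run statistics of a DNA alignment."""
    ts = tv = gap_nt = gap_events = 0
    in_gap = False
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            gap_nt += 1
            if not in_gap:
                gap_events += 1
                in_gap = True
            continue
        in_gap = False
        if x == y:
            continue
        both_pur = x in _PURINES and y in _PURINES
        both_pyr = x in _PYRIMIDINES and y in _PYRIMIDINES
        if both_pur or both_pyr:
            ts += 1
        else:
            tv += 1
    return SubstitutionSpectrum(transitions=ts, transversions=tv,
                                gap_events=gap_events, gap_nt=gap_nt)


def format_alignment(aln: PairwiseAlignment, name_a: str = "a", name_b: str = "b",
                     width: int = 60) -> str:
    """Simple EMBOSS-style text rendering of an alignment."""
    stats = alignment_stats(aln)
    lines = [
        f"# Length: {aln.length}",
        f"# Score: {aln.score:g}",
        f"# Identity: {stats.identities}/{stats.length} ({stats.pct_identity:.1f}%)",
        f"# Similarity: {stats.positives}/{stats.length} ({stats.pct_positives:.1f}%)",
        f"# Gaps: {stats.gaps}/{stats.length} ({stats.pct_gaps:.1f}%)",
        "",
    ]
    for i in range(0, aln.length, width):
        xa = aln.aligned_a[i:i + width]
        xb = aln.aligned_b[i:i + width]
        marks = "".join(
            "|" if p == q and p != "-" else
            (":" if p != "-" and q != "-" and _compatible(p, q) else " ")
            for p, q in zip(xa, xb)
        )
        lines += [f"{name_a:<10} {xa}", f"{'':<10} {marks}", f"{name_b:<10} {xb}", ""]
    return "\n".join(lines)
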