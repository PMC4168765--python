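"""In-silico PCR: primer binding sites and amplicon size prediction.

The discriminative design at the heart of splice-variant RT-PCR places the
reverse primer inside the retained intron: the primer pair then yields a
product on the intron-retained transcript but none on the spliced
transcript, excluding amplification of the reference mRNA (genomic DNA is
excluded separately by spanning splice junctions).  This module predicts
binding sites (exact by default, with a hard 3'-terminal match requirement
reflecting polymerase extension chemistry), computes expected product
sizes, and adapts a primer across species by projecting its footprint
through an alignment of homologous contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .gene_models import TranscriptBuild
from .pairwise_align import AlignParams, align
from .seq_io import SequenceRecord, reverse_complement

__all__ = [
    "Primer",
    "BindingSite",
    "AmpliconPrediction",
    "GeometryError",
    "find_binding_sites",
    "predict_amplicon",
    "predict_amplicons",
    "adapt_primer",
    "read_primer_tsv",
]


class GeometryError(ValueError):
    """Primer sites overlapping, misordered, or wrongly oriented."""


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3' as synthesised."""

    name: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be forward/reverse, got {self.role!r}")
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r}: length must be >= 10")
        if set(seq) - set("ACGT"):
            raise ValueError(f"primer {self.name!r}: unambiguous bases only")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on a template, 1-based inclusive."""

    start: int
    end: int
    orientation: str  # "forward" | "reverse"
    mismatches: int = 0

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    product_length: int
    spans_retained_intron: bool = False


def find_binding_sites(template: SequenceRecord, primer: Primer,
                       max_mismatch: int = 0,
                       require_three_prime_match: bool = True) -> list[BindingSite]:
    """All binding sites of ``primer`` on ``template``, ascending.

    Forward primers are matched against the template as written; reverse
    primers as their reverse complement.  Sites with more than
    ``max_mismatch`` mismatches, or any mismatch at the primer's 3'-terminal
    base (extension-blocking), are excluded.
    """
    seq = template.residues
    probe = (primer.sequence if primer.role == "forward"
             else reverse_complement(primer.sequence))
    # index (within probe) of the base pairing the primer's 3' terminus
    three_prime_idx = len(probe) - 1 if primer.role == "forward" else 0
    m = len(probe)
    sites = []
    for i in range(len(seq) - m + 1):
        window = seq[i:i + m]
        mismatches = sum(1 for x, y in zip(window, probe) if x != y)
        if mismatches > max_mismatch:
            continue
        if require_three_prime_match and window[three_prime_idx] != probe[three_prime_idx]:
            continue
        sites.append(BindingSite(start=i + 1, end=i + m,
                                 orientation=primer.role,
                                 mismatches=mismatches))
    return sites


def predict_amplicon(template: SequenceRecord, forward_site: BindingSite,
                     reverse_site: BindingSite,
                     build: Optional[TranscriptBuild] = None) -> AmpliconPrediction:
    """Product length for a correctly ordered forward/reverse site pair.

    ``product_length = reverse_site.end - forward_site.start + 1``.  When the
    template is a transcript build, ``spans_retained_intron`` reports whether
    the amplicon interval overlaps the intron-labelled segment.
    """
    if forward_site.orientation != "forward" or reverse_site.orientation != "reverse":
        raise GeometryError("need one forward and one reverse site, in that order")
    if forward_site.end >= reverse_site.start:
        raise GeometryError(
            f"forward site ends at {forward_site.end}, reverse starts at "
            f"{reverse_site.start}: overlapping or misordered")
    spans = False
    if build is not None:
        for s in build.segments:
            if s.is_intron and not (s.t_end < forward_site.start
                                    or s.t_start > reverse_site.end):
                spans = True
    return AmpliconPrediction(
        template_id=template.id,
        forward_site=forward_site,
        reverse_site=reverse_site,
        product_length=reverse_site.end - forward_site.start + 1,
        spans_retained_intron=spans,
    )


def predict_amplicons(template: SequenceRecord, forward: Primer, reverse: Primer,
                      max_mismatch: int = 0,
                      build: Optional[TranscriptBuild] = None) -> list[AmpliconPrediction]:
    """All products from every correctly ordered pair of binding sites."""
    fw_sites = find_binding_sites(template, forward, max_mismatch)
    rv_sites = find_binding_sites(template, reverse, max_mismatch)
    out = []
    for f in fw_sites:
        for r in rv_sites:
            if f.end < r.start:
                out.append(predict_amplicon(template, f, r, build))
    return out


def adapt_primer(primer: Primer, source_context: str, target_context: str,
                 params: AlignParams | None = None) -> tuple[Primer, int, bool]:
    """Port a primer to a homologous context in another species.

    The primer must bind ``source_context`` exactly (as written for forward
    primers, as reverse complement for reverse primers).  The two contexts
    are globally aligned (free end gaps) and the primer footprint projected
    onto the target; the adapted primer takes the target bases over the
    footprint.  Returns ``(adapted, n_substitutions, ok)``; ``ok`` is False
    when the footprint hits an alignment gap (adaptation failure), in which
    case the original primer is returned.
    """
    probe = (primer.sequence if primer.role == "forward"
             else reverse_complement(primer.sequence))
    pos = source_context.upper().find(probe)
    if pos < 0:
        raise ValueError(f"primer {primer.name!r} does not bind the source context")
    if source_context.upper().find(probe, pos + 1) >= 0:
        raise ValueError(f"primer {primer.name!r} binds the source context twice")
    footprint = set(range(pos, pos + len(probe)))

    if params is None:
        params = AlignParams()
    aln = align(source_context.upper(), target_context.upper(), params)
    projected: list[str] = []
    si = 0  # index into source_context
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            if si in footprint:
                projected.append(y)  # may be '-' (deletion in target)
            si += 1
    if "-" in projected or len(projected) != len(probe):
        return primer, 0, False
    adapted_probe = "".join(projected)
    n_subs = sum(1 for a, b in zip(probe, adapted_probe) if a != b)
    adapted_seq = (adapted_probe if primer.role == "forward"
                   else reverse_complement(adapted_probe))
    adapted = Primer(name=f"{primer.name}_adapted", sequence=adapted_seq,
                     role=primer.role)
    return adapted, n_subs, True


def read_primer_tsv(path: str | Path) -> list[Primer]:
    """Read primers from a 3-column TSV: name, role, sequence."""
    primers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            name, role, seq = parts
            primers.append(Primer(name=name, role=role, sequence=seq))
    return primers
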