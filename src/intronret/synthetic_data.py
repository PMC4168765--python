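"""Synthetic loci with ground-truth manifests for end-to-end testing.

The generator emulates the structures an intron-retention analysis must
detect: a multi-exon gene with one designated retained intron; an in-frame
stop codon planted a configurable number of codons into that intron (with a
configurable exon/intron boundary phase); a downstream AATAAA signal and a
nominal termination site; optionally an inserted element flanked by a
target-site duplication and an oligo(dA) tail; and primer pairs placed so
the spliced and intron-retained templates are discriminable by product
presence/size.

Everything planted is recorded in a truth manifest and re-detected with the
pipeline's own detectors before the locus is returned (rejection sampling
with bounded retries), so parameter-recovery tests are exact rather than
statistical.  Background sequence is i.i.d. uniform over {A,C,G,T}; no
global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .gene_models import (GeneModel, GenomicInterval, build_intron_retained,
                          build_spliced, write_gff3)
from .insilico_pcr import Primer, find_binding_sites
from .orf_truncation import STOP_CODONS, predict_truncation
from .polya_tts import find_polya_signals
from .repeat_insert import compare_to_consensus, detect_tsd, measure_polyA_tail
from .seq_io import SequenceRecord, write_fasta

__all__ = [
    "GenerationError",
    "InsertSpec",
    "LocusParams",
    "SyntheticLocus",
    "generate_locus",
    "generate_species_panel",
    "generate_noisy_reads",
    "random_dna",
]

MAX_RETRIES = 50

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class GenerationError(RuntimeError):
    """Planted features could not be made self-consistent within the retry budget."""


def random_dna(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_nonstop_codons(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


@dataclass(frozen=True)
class InsertSpec:
    """A planted mobile-element-like insertion inside the retained intron."""

    tsd_length: int = 12
    tail_length: int = 15
    transitions: int = 0
    transversions: int = 0
    deletion_lengths: tuple[int, ...] = ()   # one planted deletion per entry
    consensus_length: int = 300
    signal_to_tsd_distance: int = 79         # nt between signal end and 5' TSD start

    def __post_init__(self) -> None:
        if self.tsd_length < 0 or self.tail_length < 0:
            raise ValueError("tsd/tail lengths must be >= 0")
        if self.consensus_length < 50:
            raise ValueError("consensus too short to be meaningful")


@dataclass(frozen=True)
class LocusParams:
    """Parameters of one synthetic locus.

    ``boundary_phase`` is the number of *exonic* nucleotides in the codon
    spanning the exon/intron boundary (0 means the exon ends exactly on a
    codon boundary).  ``novel_length`` is the number of residues encoded by
    codons containing intronic bases before the planted stop (0 plants the
    stop as the first such codon).
    """

    exon_lengths: tuple[int, ...] = (150, 120, 90)
    intron_lengths: tuple[int, ...] = (80, 500)
    retained_intron: int = 2
    cds_start: int = 1
    boundary_phase: int = 1
    novel_length: int = 5
    polya_signal_pos: Optional[int] = 290
    tts_pos: Optional[int] = 357
    insert: Optional[InsertSpec] = None
    with_primers: bool = True
    primer_length: int = 22
    strand: str = "+"
    flank: int = 100
    chrom: str = "chrS"
    gene_id: str = "synthetic_gene"

    def __post_init__(self) -> None:
        if len(self.exon_lengths) < 2:
            raise ValueError("need at least 2 exons")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly n_exons - 1 intron lengths")
        if not 1 <= self.retained_intron <= len(self.intron_lengths):
            raise ValueError("retained_intron out of range")
        if self.boundary_phase not in (0, 1, 2):
            raise ValueError("boundary_phase must be 0, 1 or 2")
        if self.novel_length < 0:
            raise ValueError("novel_length must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SyntheticLocus:
    """A generated locus plus its ground-truth manifest."""

    genome: dict[str, SequenceRecord]
    gene: GeneModel
    primers: list[Primer]
    truth: dict
    params: LocusParams
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.values(), outdir / "genome.fasta")
        write_gff3(self.gene, outdir / "gene.gff3")
        with open(outdir / "primers.tsv", "w") as fh:
            fh.write("name\trole\tsequence\n")
            for p in self.primers:
                fh.write(f"{p.name}\t{p.role}\t{p.sequence}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# intron construction


def _boundary_and_novel(rng: np.random.Generator, phase: int,
                        novel_length: int) -> tuple[str, str, str]:
    """(exon suffix override, intron coding prefix, stop triplet).

    The exon suffix override replaces the last ``phase`` exonic bases when a
    stop must straddle the boundary (novel_length == 0 with phase > 0).
    """
    if phase == 0:
        if novel_length == 0:
            return "", "", "TAA"
        return "", _random_nonstop_codons(rng, novel_length), "TAA"
    if novel_length == 0:
        # the boundary codon itself is the stop
        if phase == 1:
            return "T", "", str(rng.choice(["TAA", "TAG", "TGA"]))
        return "TA", "", str(rng.choice(["TAA", "TAG"]))
    # boundary codon is novel residue #1 and must not be a stop; choosing a
    # C as the first intronic base rules out TAA/TAG/TGA for any prefix
    completion = "C" + random_dna(rng, 2 - phase)
    body = _random_nonstop_codons(rng, novel_length - 1)
    return "", completion + body, "TAA"


def _build_insert(rng: np.random.Generator, spec: InsertSpec,
                  consensus: str) -> tuple[str, dict]:
    """Mutate the consensus per spec and append the oligo(dA) tail."""
    seq = list(consensus)
    n = len(seq)
    # keep mutated/deleted positions spaced so the alignment recovers the
    # planted spectrum unambiguously
    used: set[int] = set()

    def _pick(span: int = 1) -> int:
        for _ in range(200):
            i = int(rng.integers(5, n - 5 - span))
            window = set(range(i - 2, i + span + 2))
            if not (window & used):
                used.update(range(i, i + span))
                return i
        raise GenerationError("could not place planted mutations")

    subs = []
    for _ in range(spec.transitions):
        i = _pick()
        seq[i] = _TRANSITION[seq[i]]
        subs.append(("ts", i + 1))
    for _ in range(spec.transversions):
        i = _pick()
        seq[i] = rng.choice(list(_TRANSVERSIONS[seq[i]]))
        subs.append(("tv", i + 1))
    deletions = []
    for dlen in spec.deletion_lengths:
        i = _pick(dlen)
        deletions.append((i + 1, dlen))
    # apply deletions high-to-low
    for i1, dlen in sorted(deletions, reverse=True):
        del seq[i1 - 1: i1 - 1 + dlen]
    body = "".join(seq)
    # the tail measure tolerates one interruption, so an A within the last
    # two core bases would inflate the measured tail
    if "A" in body[-2:]:
        raise GenerationError("consensus must end with two non-A bases "
                              "for unambiguous tail planting")
    body += "A" * spec.tail_length
    return body, {"substitutions": subs, "deletions": deletions}


def _make_intron(rng: np.random.Generator, params: LocusParams,
                 consensus: Optional[str]) -> tuple[str, str, dict]:
    """Build the retained intron; returns (exon suffix override, intron, truth)."""
    spec = params.insert
    phase = params.boundary_phase
    exon_suffix, coding_prefix, stop = _boundary_and_novel(
        rng, phase, params.novel_length)
    head = coding_prefix + stop if phase == 0 or params.novel_length > 0 else (
        stop[phase:])  # boundary stop: only its intronic part enters the intron
    intron_len = params.intron_lengths[params.retained_intron - 1]

    consumed = len(head)
    stop_intron_pos = (consumed - 2 if params.novel_length > 0 or phase == 0
                       else 1 - phase)

    truth: dict = {
        "boundary_phase": phase,
        "novel_length": params.novel_length,
        "stop_intron_position": stop_intron_pos,
    }

    body = ""
    insert_truth = None
    if spec is not None:
        if params.polya_signal_pos is None:
            raise GenerationError("insert placement requires a polyA signal")
        body, insert_truth = _build_insert(rng, spec, consensus)

    sig = params.polya_signal_pos
    if sig is not None:
        if sig <= consumed:
            raise GenerationError(
                f"polyA signal position {sig} collides with the planted "
                f"coding region (first {consumed} nt of the intron)")
        if sig + 5 > intron_len:
            raise GenerationError("polyA signal does not fit in the intron")

    # assemble: head, random gap, signal, random, [TSD+insert+TSD], random
    pieces = [head]
    pos = consumed
    if sig is not None:
        pieces.append(random_dna(rng, sig - 1 - pos))
        pieces.append("AATAAA")
        pos = sig + 5
        truth["polya_signal_pos"] = sig
    if spec is not None:
        tsd5_start = sig + 5 + 1 + spec.signal_to_tsd_distance
        L = spec.tsd_length
        pre_len = tsd5_start - 1 - pos + L
        if pre_len < 0:
            raise GenerationError("insert overlaps the polyA signal")
        pieces.append(random_dna(rng, pre_len))  # includes the TSD site itself
        pos = tsd5_start - 1 + L
        pieces.append(body)
        head_so_far = "".join(pieces)
        tsd_site = head_so_far[tsd5_start - 1: tsd5_start - 1 + L]
        pieces.append(tsd_site)  # the 3' duplicate copy
        pos += len(body) + L
        insert_start = tsd5_start + L          # body begins after the 5' TSD copy
        insert_end = insert_start + len(body) - 1
        truth["insert"] = {
            "interval": [insert_start, insert_end],
            "tsd_length": L,
            "tsd_sequence": tsd_site,
            "tail_length": spec.tail_length,
            "transitions": spec.transitions,
            "transversions": spec.transversions,
            "deletion_lengths": list(spec.deletion_lengths),
            "signal_to_tsd_distance": spec.signal_to_tsd_distance,
            **insert_truth,
        }
    if pos > intron_len:
        raise GenerationError(
            f"planted intron features need {pos} nt but the intron is only "
            f"{intron_len} nt long")
    pieces.append(random_dna(rng, intron_len - pos))
    intron = "".join(pieces)
    if params.tts_pos is not None:
        if params.tts_pos > intron_len:
            raise GenerationError("TTS position beyond the intron end")
        truth["tts_pos"] = params.tts_pos
    return exon_suffix, intron, truth


# ---------------------------------------------------------------------------
# locus assembly and self-validation


def _plant(seq: str, pos0: int, sub: str) -> str:
    return seq[:pos0] + sub + seq[pos0 + len(sub):]


def _reverse_strand(genome_seq: str, exons: Sequence[tuple[int, int]]
                    ) -> tuple[str, list[tuple[int, int]]]:
    from .seq_io import reverse_complement

    n = len(genome_seq)
    rc = reverse_complement(genome_seq)
    flipped = [(n - e + 1, n - s + 1) for s, e in exons]
    return rc, flipped


def _attempt(params: LocusParams, rng: np.random.Generator,
             consensus: Optional[str]) -> SyntheticLocus:
    k = params.retained_intron
    exon_lengths = list(params.exon_lengths)
    cum_k = sum(exon_lengths[:k])
    r = (cum_k - (params.cds_start - 1)) % 3
    delta = (params.boundary_phase - r) % 3
    exon_lengths[k - 1] += delta  # minimal adjustment to hit the requested phase
    cum_k += delta

    # spliced transcript: random 5' UTR then non-stop codons to the end
    total = sum(exon_lengths)
    n_codons = (total - params.cds_start + 1) // 3
    remainder = (total - params.cds_start + 1) - 3 * n_codons
    spliced = (random_dna(rng, params.cds_start - 1)
               + _random_nonstop_codons(rng, n_codons)
               + random_dna(rng, remainder))

    exon_suffix, intron_seq, intron_truth = _make_intron(rng, params, consensus)
    if exon_suffix:
        # a boundary-straddling stop constrains the last exonic bases
        spliced = _plant(spliced, cum_k - len(exon_suffix), exon_suffix)
        # keep the *spliced* junction codon non-stop after the override
        codon_start = cum_k - params.boundary_phase  # 0-based
        while spliced[codon_start:codon_start + 3] in STOP_CODONS:
            repl = _random_nonstop_codons(rng, 1)[params.boundary_phase:]
            spliced = _plant(spliced, cum_k, repl)

    # cut the spliced transcript into exons
    exons_seq = []
    pos = 0
    for L in exon_lengths:
        exons_seq.append(spliced[pos:pos + L])
        pos += L

    # other introns: random
    introns_seq = [
        intron_seq if i == k else random_dna(rng, L)
        for i, L in enumerate(params.intron_lengths, start=1)
    ]

    # primers
    primers: list[Primer] = []
    primer_truth = {}
    if params.with_primers:
        from .seq_io import reverse_complement

        m = params.primer_length
        fwd_start = max(1, params.cds_start + 3)       # transcript coords
        fwd_seq_site = (fwd_start, fwd_start + m - 1)
        last_exon_start = total - exon_lengths[-1] + 1
        rev_ex_end = total - 5
        rev_ex_site = (rev_ex_end - m + 1, rev_ex_end)
        if fwd_seq_site[1] > cum_k - 6:
            raise GenerationError(
                "forward primer must sit upstream of the retained intron")
        if rev_ex_site[0] < last_exon_start:
            raise GenerationError("reverse exon primer does not fit in the last exon")
        stop_end = intron_truth["stop_intron_position"] + 2
        rev_in_start = max(stop_end + 8, 1)
        rev_in_site = (rev_in_start, rev_in_start + m - 1)
        sig = params.polya_signal_pos
        if sig is not None and rev_in_site[1] >= sig:
            raise GenerationError("intron reverse primer collides with the signal")
        if rev_in_site[1] > len(intron_seq):
            raise GenerationError("intron reverse primer does not fit")

        fwd = random_dna(rng, m)
        spliced = _plant(spliced, fwd_seq_site[0] - 1, fwd)
        rev_ex_template = random_dna(rng, m)
        spliced = _plant(spliced, rev_ex_site[0] - 1, rev_ex_template)
        # re-cut exons after planting
        exons_seq = []
        pos = 0
        for L in exon_lengths:
            exons_seq.append(spliced[pos:pos + L])
            pos += L
        rev_in_template = random_dna(rng, m)
        introns_seq[k - 1] = _plant(introns_seq[k - 1], rev_in_site[0] - 1,
                                    rev_in_template)

        primers = [
            Primer("fwd_exon", fwd, "forward"),
            Primer("rev_exon", reverse_complement(rev_ex_template), "reverse"),
            Primer("rev_intron", reverse_complement(rev_in_template), "reverse"),
        ]
        intron_len_k = params.intron_lengths[k - 1]
        primer_truth = {
            "forward_site_spliced": list(fwd_seq_site),
            "reverse_exon_site_spliced": list(rev_ex_site),
            "reverse_intron_site_intron": list(rev_in_site),
            "product_spliced": rev_ex_site[1] - fwd_seq_site[0] + 1,
            "product_retained_exon_pair":
                rev_ex_site[1] + intron_len_k - fwd_seq_site[0] + 1,
            "product_retained_intron_pair":
                cum_k + rev_in_site[1] - fwd_seq_site[0] + 1,
        }

    # genome assembly (plus strand first)
    flank5 = random_dna(rng, params.flank)
    flank3 = random_dna(rng, params.flank)
    parts = [flank5]
    exon_coords = []
    gpos = params.flank
    for i, ex in enumerate(exons_seq):
        exon_coords.append((gpos + 1, gpos + len(ex)))
        parts.append(ex)
        gpos += len(ex)
        if i < len(introns_seq):
            parts.append(introns_seq[i])
            gpos += len(introns_seq[i])
    parts.append(flank3)
    genome_seq = "".join(parts)

    strand = params.strand
    if strand == "-":
        genome_seq, exon_coords = _reverse_strand(genome_seq, exon_coords)
        # exon list stays in transcript order: genomically descending now
    ivs = tuple(GenomicInterval(params.chrom, s, e, strand)
                for s, e in exon_coords)
    gene = GeneModel(gene_id=params.gene_id, chrom=params.chrom, strand=strand,
                     exons=ivs, cds_start_in_transcript=params.cds_start)
    genome = {params.chrom: SequenceRecord(id=params.chrom, residues=genome_seq)}

    truth = {
        "exon_lengths": exon_lengths,
        "intron_lengths": list(params.intron_lengths),
        "retained_intron": k,
        "cds_start": params.cds_start,
        "strand": strand,
        "spliced_length": total,
        "retained_length": total + params.intron_lengths[k - 1],
        **intron_truth,
        "primers": primer_truth,
    }
    locus = SyntheticLocus(genome=genome, gene=gene, primers=primers,
                           truth=truth, params=replace(
                               params, exon_lengths=tuple(exon_lengths)),
                           seed=-1)
    _validate(locus, consensus)
    return locus


def _validate(locus: SyntheticLocus, consensus: Optional[str]) -> None:
    """Re-detect every planted feature; raise GenerationError on any mismatch."""
    p = locus.params
    truth = locus.truth
    spliced = build_spliced(locus.gene, locus.genome)
    retained = build_intron_retained(locus.gene, locus.genome, p.retained_intron)
    if len(spliced) != truth["spliced_length"]:
        raise GenerationError("spliced length mismatch")
    if len(retained) != truth["retained_length"]:
        raise GenerationError("retained length mismatch")

    from .orf_truncation import translate

    protein = translate(spliced.sequence, (p.cds_start - 1) % 3)
    start_codon_idx = (p.cds_start - 1) // 3
    if "*" in protein[start_codon_idx:]:
        raise GenerationError("accidental in-frame stop in the spliced CDS")

    report = predict_truncation(retained, p.cds_start)
    if report.novel_length != truth["novel_length"]:
        raise GenerationError(
            f"novel length {report.novel_length} != planted {truth['novel_length']}")
    if report.stop_codon is None or (
            report.stop_codon.intron_relative_position
            != truth["stop_intron_position"]):
        raise GenerationError("stop codon not recovered at the planted position")

    intron = retained.retained_segment
    intron_seq = retained.sequence[intron.t_start - 1: intron.t_end]
    if "polya_signal_pos" in truth:
        hits = find_polya_signals(intron_seq)
        if [h.position for h in hits] != [truth["polya_signal_pos"]]:
            raise GenerationError("polyA signal not unique at the planted position")

    if "insert" in truth:
        it = truth["insert"]
        interval = tuple(it["interval"])
        tsd = detect_tsd(intron_seq, interval)
        if it["tsd_length"] == 0:
            if tsd is not None:
                raise GenerationError("spurious TSD detected")
        else:
            if tsd is None or tsd.length != it["tsd_length"] or tsd.mismatches:
                raise GenerationError("TSD not recovered as planted")
        insert_seq = intron_seq[interval[0] - 1: interval[1]]
        measured = measure_polyA_tail(insert_seq)
        expected_tail = it["tail_length"] if (it["tail_length"] == 0
                                              or it["tail_length"] >= 8) else 0
        if measured != expected_tail:
            raise GenerationError("oligo(dA) tail not recovered as planted")
        if consensus is not None and (it["transitions"] or it["transversions"]
                                      or it["deletion_lengths"]):
            core = insert_seq[: len(insert_seq) - it["tail_length"]] \
                if it["tail_length"] else insert_seq
            spec = compare_to_consensus(
                core, SequenceRecord(id="consensus", residues=consensus))
            if (spec.transitions != it["transitions"]
                    or spec.transversions != it["transversions"]
                    or spec.gap_events != len(it["deletion_lengths"])
                    or spec.gap_nt != sum(it["deletion_lengths"])):
                raise GenerationError("consensus spectrum not recovered as planted")

    if locus.primers:
        pt = truth["primers"]
        by_name = {pr.name: pr for pr in locus.primers}
        s_rec = spliced.to_record()
        r_rec = retained.to_record()
        fw_s = find_binding_sites(s_rec, by_name["fwd_exon"])
        fw_r = find_binding_sites(r_rec, by_name["fwd_exon"])
        rv_ex_s = find_binding_sites(s_rec, by_name["rev_exon"])
        rv_in_s = find_binding_sites(s_rec, by_name["rev_intron"])
        rv_in_r = find_binding_sites(r_rec, by_name["rev_intron"])
        if len(fw_s) != 1 or len(fw_r) != 1 or len(rv_ex_s) != 1:
            raise GenerationError("exon primers must bind exactly once")
        if rv_in_s:
            raise GenerationError("intron primer must not bind the spliced template")
        if len(rv_in_r) != 1:
            raise GenerationError("intron primer must bind the retained template once")
        got = rv_ex_s[0].end - fw_s[0].start + 1
        if got != pt["product_spliced"]:
            raise GenerationError("spliced product size mismatch")
        got = rv_in_r[0].end - fw_r[0].start + 1
        if got != pt["product_retained_intron_pair"]:
            raise GenerationError("retained product size mismatch")


def generate_locus(params: LocusParams, seed: int,
                   consensus: Optional[SequenceRecord] = None) -> SyntheticLocus:
    """Generate a locus, self-validate it, and return it with its manifest.

    Deterministic for fixed ``(params, seed)``.  If the insert spec is set
    and no consensus is given, a synthetic consensus element is generated
    from the same seed stream (and recorded in the truth manifest).
    Infeasible parameter combinations raise :class:`GenerationError`.
    """
    root = np.random.SeedSequence(seed)
    consensus_seq: Optional[str] = consensus.residues if consensus else None
    if params.insert is not None and consensus_seq is None:
        crng = np.random.default_rng(root.spawn(1)[0])
        consensus_seq = random_dna(crng, params.insert.consensus_length)
        tail_safe = consensus_seq[:-2] + consensus_seq[-2:].replace("A", "G")
        consensus_seq = tail_safe
    last_error: Optional[Exception] = None
    for attempt in range(MAX_RETRIES):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(1000 + attempt,)))
        try:
            locus = _attempt(params, rng, consensus_seq)
        except GenerationError as exc:
            last_error = exc
            continue
        locus.seed = seed
        locus.truth["seed"] = seed
        locus.truth["attempt"] = attempt
        if consensus_seq is not None and params.insert is not None:
            locus.truth["consensus"] = consensus_seq
        return locus
    raise GenerationError(
        f"no self-consistent locus after {MAX_RETRIES} attempts "
        f"(params likely infeasible): {last_error}")


# ---------------------------------------------------------------------------
# species panels and noisy reads


def _protected_intervals(locus: SyntheticLocus) -> list[tuple[int, int]]:
    """Genomic intervals (1-based) whose bases carry planted features."""
    p = locus.params
    retained = build_intron_retained(locus.gene, locus.genome, p.retained_intron)
    seg = retained.retained_segment
    g0 = seg.genomic.start  # plus-strand panels only
    out = []
    stop_end = locus.truth["stop_intron_position"] + 2
    out.append((g0 - 12, g0 + max(stop_end, 0) + 2))  # boundary + coding head
    if "polya_signal_pos" in locus.truth:
        s = locus.truth["polya_signal_pos"]
        out.append((g0 + s - 1, g0 + s + 4))
    if "insert" in locus.truth:
        a, b = locus.truth["insert"]["interval"]
        L = locus.truth["insert"]["tsd_length"]
        out.append((g0 + a - 2 - L, g0 + b + L))
    # primer binding sites must survive divergence
    if locus.primers:
        from .gene_models import map_transcript_to_genomic

        pt = locus.truth["primers"]
        spliced = build_spliced(locus.gene, locus.genome)
        for key in ("forward_site_spliced", "reverse_exon_site_spliced"):
            s, e = pt[key]
            gs = map_transcript_to_genomic(spliced, s).start
            ge = map_transcript_to_genomic(spliced, e).start
            out.append((min(gs, ge), max(gs, ge)))
        s, e = pt["reverse_intron_site_intron"]
        out.append((g0 + s - 1, g0 + e - 1))
    return out


def generate_species_panel(base_params: LocusParams, n_species: int,
                           divergences: Sequence[float], seed: int,
                           knockout_stop: Sequence[int] = ()) -> list[SyntheticLocus]:
    """Derive a panel of diverged species loci from one base locus.

    Species ``i`` is the base genome with substitutions at rate
    ``divergences[i]`` outside planted-feature cores (JC-style uniform).
    Species listed in ``knockout_stop`` additionally have the planted stop
    codon mutated away, to exercise loss-of-feature rows.  Species 0 with
    divergence 0 is the conventional reference.
    """
    if len(divergences) != n_species:
        raise ValueError("need one divergence per species")
    if any(not 0 <= d <= 0.5 for d in divergences):
        raise ValueError("divergences must be in [0, 0.5]")
    if base_params.strand != "+":
        raise ValueError("species panels are generated on the + strand")
    base = generate_locus(base_params, seed)
    protected = _protected_intervals(base)
    prot_mask = np.zeros(len(base.genome[base_params.chrom].residues), bool)
    for a, b in protected:
        prot_mask[max(0, a - 1): b] = True
    # exon/intron boundaries must stay put: protect 2 nt around each junction
    for ex in base.gene.exons:
        for g in (ex.start, ex.end):
            prot_mask[max(0, g - 2): g + 2] = True

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    base_seq = np.array(list(base.genome[base_params.chrom].residues))
    stop_pos_intron = base.truth["stop_intron_position"]
    retained = build_intron_retained(base.gene, base.genome,
                                     base_params.retained_intron)
    g_intron_start = retained.retained_segment.genomic.start

    panel = []
    for i in range(n_species):
        seq = base_seq.copy()
        d = divergences[i]
        if d > 0:
            hit = (rng.random(len(seq)) < d) & ~prot_mask
            idx = np.flatnonzero(hit)
            for j in idx:
                alts = [b for b in "ACGT" if b != seq[j]]
                seq[j] = alts[int(rng.integers(0, 3))]
        knocked = i in knockout_stop
        if knocked:
            # 0-based index of the stop codon's first base on the genome
            g = g_intron_start + stop_pos_intron - 2
            seq[g] = "C"  # no stop codon starts with C
        genome = {base_params.chrom: SequenceRecord(
            id=base_params.chrom, residues="".join(seq))}
        truth = dict(base.truth)
        truth.update({"species_index": i, "divergence": float(d),
                      "stop_knocked_out": knocked})
        panel.append(SyntheticLocus(
            genome=genome,
            gene=replace(base.gene, gene_id=f"species_{i}"),
            primers=base.primers, truth=truth,
            params=base.params, seed=seed))
    return panel


def generate_noisy_reads(template: SequenceRecord, error_rate: float, n: int,
                         seed: int,
                         deletion: Optional[tuple[int, int]] = None
                         ) -> tuple[list[SequenceRecord], list[dict]]:
    """Simulate single-pass reads of a template with substitution errors.

    ``deletion=(pos, length)`` additionally removes that 1-based span from
    every read (a planted indel).  Returns (reads, per-read truth) where
    truth lists the substituted template positions.
    """
    if not 0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    reads = []
    truths = []
    tpl = template.residues
    for i in range(n):
        arr = np.array(list(tpl))
        hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for j in hit:
            alts = [b for b in "ACGT" if b != arr[j]]
            arr[j] = alts[int(rng.integers(0, 3))]
        seq = "".join(arr)
        if deletion is not None:
            pos, dlen = deletion
            seq = seq[: pos - 1] + seq[pos - 1 + dlen:]
        reads.append(SequenceRecord(id=f"{template.id}_read{i}", residues=seq))
        truths.append({"substitution_positions": [int(j) + 1 for j in hit],
                       "deletion": list(deletion) if deletion else None})
    return reads, truths
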