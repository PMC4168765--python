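# Methods

This note records the models, conventions and design choices behind
`intronret`, in the spirit of a package vignette: what is computed, under
what assumptions, and what the synthetic validation does and does not show.

## Coordinates and transcript models

All user-facing coordinates are 1-based inclusive (NCBI style); internals
convert to 0-based half-open only at the point of slicing. A
`SequenceRecord` may carry an `origin`, the 1-based coordinate of its first
base on the parent molecule, so a chromosome window can be used without
materialising the chromosome — the packaged human demonstration locus is an
hg19-anchored chr2 slice of ~6.6 kb.

A `GeneModel` lists exons 5'→3' in transcript orientation plus a frame
anchor (`cds_start_in_transcript`): a transcript position known to be the
first base of a codon. Frame is anchored this way, rather than by GFF phase
columns, because published variant descriptions anchor frame by transcript
position and protein residue, which is unambiguous under re-annotation.
Introns are indexed by the exon they follow (intron *k* lies between exons
*k* and *k*+1), so "intron 8-9" is intron index 8.

`build_spliced` and `build_intron_retained` return the transcript sequence
plus a segment map (transcript interval ↔ genomic interval per exon/intron
segment). The map is exact and bidirectional; a property test checks the
round trip on 10⁴ random positions. Minus-strand genes are handled by
reverse-complementing extracted segments; strand correctness is covered by
a symmetry test (a locus and its reverse-complemented mirror build
identical transcripts) rather than by a curated minus-strand fixture.

## Truncation prediction

The *novel C-terminal peptide* is defined operationally as the residues
encoded by codons containing at least one intronic nucleotide, up to but
excluding the first in-frame stop. A codon split across the exon/intron
boundary therefore contributes the first novel residue; when the exon ends
exactly on a codon boundary the report's `boundary_codon` is absent. This
definition is stated explicitly so that peptide counts are reproducible;
for the human locus it yields 22 residues with the boundary codon
(1 exonic + 2 intronic nt) as residue 1.

Translation uses the standard nuclear code only. A codon containing any
base outside {A,C,G,T} translates to `X` and is never treated as a stop —
conservative for ambiguous assembly bases, and deliberately different from
ambiguity-resolving translators (which would render e.g. `GGN` as `G`).
If no in-frame stop exists before the transcript end, the report is
flagged `no_stop` and the peptide runs to the last complete codon.

## Polyadenylation and termination

The default signal motif set is `{AATAAA}` only; variant hexamers
(`ATTAAA`, …) are opt-in configuration, since the canonical hexamer is the
only signal reported for this locus class. Termination-site calls come in
two strengths:

* **EST-supported** — the EST's trailing oligo(dA) run (≥8 A with at most
  one interruption, both configurable) is trimmed as template-independent
  polyadenylation, the remainder is locally aligned to the intron, and the
  TTS is the 3' end of the covered interval. A sub-threshold alignment
  yields a no-support result, not an error.
* **Signal-only** — with no EST, no cleavage-offset formula is invented:
  the call is an interval from the signal end to a configurable window
  (default 40 nt) downstream, labelled `signal-only`. The window default is
  arbitrary and documented as such.

Reported 3'-region distances are differences of 1-based start positions
(signal start − stop-codon start; TTS − signal start); misordered features
are flagged `atypical_ordering` rather than rejected.

## In-silico PCR

Binding-site search is exact by default (`max_mismatch 0`) with a hard
3'-terminal-match requirement reflecting extension chemistry; both are
configurable. Reverse primers are matched as reverse complements; a
reverse primer's 3' terminus pairs the 5'-most template base of its site.
Product length is `reverse_site.end − forward_site.start + 1`. When both
transcript and genomic coordinates are available for a primer, the
transcript-space value through the segment map is authoritative; for the
human type II pair this yields 874 bp deterministically (the value
consistent with the printed binding coordinates; a conflicting 847 bp
figure appears in one caption and is not adopted). Cross-species primer
adaptation aligns the two homologous contexts (global, free end gaps),
projects the primer footprint, and reports the substitution count; a gap
inside the footprint flags adaptation failure.

## Pairwise alignment

Two modes: global with free end gaps (for reads or predicted transcripts
of unequal extent) and local. Affine gap model: a gap of length *L* costs
`gap_open + (L−1)·gap_extend`; terminal gaps are unpenalised in global
mode. Defaults are match +5 / mismatch −4 with gap open 12 / extend 3
(global) and open 10 / extend 0.5 (local); all are configurable. The
nucleotide match/mismatch scores are ordinary practice values — the
"65% similarity" matrix named by some GUI tools is not publicly
documented, so identity percentages from such tools are treated as
approximate calibration, not a bit-exact contract.

The engine is Biopython's `PairwiseAligner`, parameterised behind this
module's surface. Determinism holds (same inputs → same alignment); among
co-optimal tracebacks the engine's fixed internal order decides, which we
document rather than re-derive. Correctness is checked against an
independent dynamic-programming oracle written for the test suite (and
that oracle in turn against exhaustive path enumeration at tiny lengths);
engine and oracle agree on thousands of seeded random pairs in both modes.

"Positives" counts identical columns plus IUPAC-compatible columns (e.g.
`R` vs `A`); the substitution spectrum classifies mismatches into
transitions (A↔G, C↔T) and transversions and counts maximal gap runs as
events with their total gapped length.

## Repeat-insert characterization

Target-site duplications are searched as the longest direct repeat
(5–25 nt, ≤1 mismatch; configurable — typical retrotransposition scar
bounds) with one copy ending immediately 5' of the insert and one starting
immediately 3' of it. The oligo(dA) tail measure takes the maximal A-rich
suffix starting and ending with A, with ≤1 interruption and ≥8 A total.
The distance from an upstream polyA signal to the 5' TSD is the count of
bases strictly between signal end and TSD start. Divergence from a
consensus element is reported both restricted to the consensus-covered
alignment span (the convention for element divergence, and the default)
and over the full alignment, since published counts do not always state
which convention they use.

## Comparative analysis

The progressive aligner is deliberately simple and fully deterministic:
fractional-common-6-mer distances, UPGMA guide tree (scipy average
linkage), profile–profile Needleman–Wunsch with affine gaps and tie order
diagonal > up > left, no iterative refinement. It reproduces structural
properties exactly (row reconstruction, planted-indel recovery,
conserved-column support counts) and tracks a production aligner closely
on substitution-only panels (cross-checked against MAFFT in the tests),
but figure-grade per-species identity percentages from refined aligners
are reproduced only approximately — they are not asserted anywhere.

Conserved stop detection requires the stop to be in frame per row (frame
offsets supplied per species), not merely column-coincident. Percent
identity to a reference row is computed over the reference's non-gap
columns. The cross-species truncation table runs the truncation predictor
per species locus, marks frame conservation by the net indel balance
(mod 3) of aligned preceding-exon tails, and orders rows by descending
identity to the designated reference ("anthropocentrically" when the
reference is human). Species-set curation is out of scope: the table
consumes user-supplied loci.

## Synthetic data and what the tests show

The generator plants, in one locus: a designated retained intron; a stop a
configurable number of codons into it at a configurable boundary phase; an
`AATAAA` at a configurable position (unique in the intron by rejection
sampling); optionally an element insertion with TSD, tail and a planted
transition/transversion/deletion spectrum against a generated consensus;
and three primers (exonic forward, exonic reverse, intronic reverse) that
bind uniquely. Defaults are a 3-exon gene (150/120/90 nt exons, 80/500 nt
introns), phase 1, a 5-codon novel tail mirroring the rodent-style
variant, signal at intron position 290 and a nominal TTS at 357 mirroring
the human intron layout; the demonstration locus plants the human-style
22-codon tail. Every generated locus is self-validated: the pipeline's own
detectors must recover every planted integer exactly before the locus is
returned (bounded retries, then an error). Random background is i.i.d.
uniform {A,C,G,T}; substitution divergence in species panels is JC-style
uniform outside planted-feature cores.

Consequently, passing tests demonstrate exact parameter recovery and
internal consistency under idealised conditions — uniform base
composition, no sequencing noise beyond the simulated substitution/indel
rates, unique primer sites, single retained introns. They do not
demonstrate performance on repetitive genomes, degraded chromatograms, or
multi-isoform loci.

Test problem sizes were chosen to keep the default suite fast while still
covering the stated grids: the recovery grid runs ≥100 seeded fixtures
(boundary phases × novel lengths {0,1,5,22,50} × replicate seeds), the
alignment oracle check 2,000 random pairs of length ≤8 per mode, and the
coordinate round trip 10⁴ positions on the 5.6 kb retained transcript.

## The packaged demonstration locus

Only ~362 nt of the human locus plus a handful of coordinates are printable
text; the demo locus embeds those verbatim (the 362 nt query as exons 7–8
plus intron start; primer sites at transcript nt 545–568, 1209–1231 and
chr2:103,006,939–103,006,960; intron 8-9 at chr2:103,006,678–103,010,928
with exon 8 ending at transcript nt 1135) and fills everything else with
seeded synthetic sequence: exon boundaries upstream of exon 7, the intron
continuation beyond nt 60 (planting the 22-codon tail, the stop at intron
66–68, the signal at 290, and a synthetic Alu-like element with a 12 nt
TSD, 15 nt tail and a 14-transition/2-transversion/one-2-nt-gap spectrum
against a synthetic consensus, 79 nt downstream of the signal). All
coordinate arithmetic (687/874/649 bp products, the 4,251 nt intron, the
transcript↔genomic maps) follows from the printed values alone; peptide
residues 21–22 and all sequence content outside the printed segments are
synthetic and labelled as such.

## Known limitations

* One retained intron per build; no multi-intron retention or
  trans-splicing.
* Standard nuclear genetic code only.
* No thermodynamic primer scoring (binding is string matching with a 3'
  rule), no primer design.
* The progressive aligner has no refinement and a single configurable
  scoring scheme; it is not a MUSCLE/MAFFT replacement for hard cases.
* EST-based TTS calling assumes the EST aligns contiguously to the intron;
  spliced ESTs are out of scope.
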