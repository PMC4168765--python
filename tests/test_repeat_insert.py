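import pytest

from intronret.gene_models import build_intron_retained
from intronret.repeat_insert import (characterize_insertion,
                                     compare_to_consensus, detect_tsd,
                                     measure_polyA_tail)
from intronret.seq_io import SequenceRecord
from intronret.synthetic_data import (InsertSpec, LocusParams, generate_locus,
                                      random_dna)


def _intron_of(locus):
    build = build_intron_retained(locus.gene, locus.genome, 2)
    seg = build.retained_segment
    return build.sequence[seg.t_start - 1: seg.t_end]


class TestDetectTSD:
    @pytest.mark.parametrize("tsd_len", [7, 12, 20])
    def test_planted_tsd_recovered_exactly(self, tsd_len, rng):
        host = random_dna(rng, 60)
        insert = random_dna(rng, 80)
        tsd = host[20: 20 + tsd_len]
        full = host[:20 + tsd_len] + insert + tsd + host[20 + tsd_len:]
        interval = (20 + tsd_len + 1, 20 + tsd_len + len(insert))
        found = detect_tsd(full, interval)
        assert found is not None
        assert (found.length, found.mismatches) == (tsd_len, 0)
        assert found.sequence == tsd

    def test_one_mismatch_tsd_recovered_with_mismatch_count(self, rng):
        host = random_dna(rng, 60)
        insert = random_dna(rng, 80)
        tsd = host[20:32]
        mutated = ("A" if tsd[5] != "A" else "C").join([tsd[:5], tsd[6:]])
        full = host[:32] + insert + mutated + host[32:]
        found = detect_tsd(full, (33, 32 + len(insert)))
        assert found is not None and found.mismatches == 1

    def test_absence_of_flanking_repeat_gives_none(self):
        # deterministic host with no direct repeat around the insert
        host = "ACGTACGTACGTACGTACGT" + "G" * 40 + "TTTTCCCCTTTTCCCC"
        assert detect_tsd(host, (21, 60)) is None

    def test_insert_interval_must_be_interior(self):
        with pytest.raises(ValueError):
            detect_tsd("ACGT" * 10, (1, 40))

    @pytest.mark.parametrize("tsd_len,tail_len", [(0, 0), (7, 8), (12, 15)])
    def test_generator_grid_recovery(self, tsd_len, tail_len):
        spec = InsertSpec(tsd_length=tsd_len, tail_length=tail_len)
        locus = generate_locus(
            LocusParams(intron_lengths=(80, 900), insert=spec),
            seed=31 * tsd_len + tail_len)
        intron = _intron_of(locus)
        truth = locus.truth["insert"]
        found = detect_tsd(intron, tuple(truth["interval"]))
        if tsd_len == 0:
            assert found is None
        else:
            assert found.length == tsd_len and found.mismatches == 0
        insert_seq = intron[truth["interval"][0] - 1: truth["interval"][1]]
        assert measure_polyA_tail(insert_seq) == tail_len

    def test_removing_insert_and_one_tsd_copy_leaves_no_signal(self, rng):
        host = random_dna(rng, 60)
        insert = random_dna(rng, 80)
        tsd = host[20:32]
        full = host[:32] + insert + tsd + host[32:]
        # reconstruct the pre-insertion state
        restored = full[:32] + full[32 + len(insert) + len(tsd):]
        assert restored == host
        assert detect_tsd(restored, (21, 40)) is None


class TestPolyATail:
    def test_pure_a_suffix(self):
        assert measure_polyA_tail("GCGC" + "A" * 15) == 15

    def test_single_interruption_included(self):
        assert measure_polyA_tail("GCGC" + "AAAAAGAAAAA") == 11

    def test_non_a_end_gives_zero(self):
        assert measure_polyA_tail("AAAAAAAAACGT") == 0

    def test_short_run_below_minimum_gives_zero(self):
        assert measure_polyA_tail("GCGCAAAAA") == 0
        assert measure_polyA_tail("GCGCAAAAA", min_run=5) == 5

    def test_two_interruptions_stop_the_run(self):
        assert measure_polyA_tail("AAAAGAAAAGAAAA", max_interruptions=1) == 9

    def test_empty_input(self):
        assert measure_polyA_tail("") == 0


class TestConsensusSpectrum:
    def test_identical_insert_has_empty_spectrum(self, rng):
        consensus = random_dna(rng, 300)
        spectrum = compare_to_consensus(
            consensus, SequenceRecord(id="c", residues=consensus))
        assert tuple(spectrum) == (0, 0, 0, 0)

    def test_planted_transitions_and_deletion_recovered(self, rng):
        consensus = random_dna(rng, 300)
        seq = list(consensus)
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for i in (30, 80, 130, 180, 230):
            seq[i] = transition[seq[i]]
        # one 2-nt deletion at a site whose neighbours differ (unambiguous gap)
        j = 150
        while consensus[j - 1] == consensus[j] or consensus[j + 1] == consensus[j + 2]:
            j += 1
        del seq[j: j + 2]
        spectrum = compare_to_consensus(
            "".join(seq), SequenceRecord(id="c", residues=consensus))
        assert spectrum.transitions == 5
        assert spectrum.transversions == 0
        assert (spectrum.gap_events, spectrum.gap_nt) == (1, 2)

    def test_flanking_host_sequence_is_excluded_from_consensus_span(self, rng):
        consensus = random_dna(rng, 200)
        padded = random_dna(rng, 50) + consensus + "A" * 20
        spectrum = compare_to_consensus(
            padded, SequenceRecord(id="c", residues=consensus))
        assert tuple(spectrum) == (0, 0, 0, 0)
        full = compare_to_consensus(
            padded, SequenceRecord(id="c", residues=consensus), region="full")
        assert full.gap_nt == 70  # the padding shows up only in full mode


class TestCharacterizeInsertion:
    def test_full_call_on_generated_locus(self):
        spec = InsertSpec(tsd_length=12, tail_length=15, transitions=14,
                          transversions=2, deletion_lengths=(2,))
        locus = generate_locus(LocusParams(intron_lengths=(80, 900),
                                           insert=spec), seed=55)
        intron = _intron_of(locus)
        truth = locus.truth["insert"]
        call = characterize_insertion(
            intron, tuple(truth["interval"]),
            consensus=SequenceRecord(id="c", residues=locus.truth["consensus"]),
            signal_end=locus.truth["polya_signal_pos"] + 5)
        assert call.tsd.length == 12
        assert call.polyA_tail_length == 15
        assert call.signal_to_tsd_distance == spec.signal_to_tsd_distance
        assert tuple(call.consensus_spectrum) == (14, 2, 1, 2)

    def test_demo_locus_alu_like_scar(self, demo_locus, demo_builds):
        _, retained = demo_builds
        seg = retained.retained_segment
        intron = retained.sequence[seg.t_start - 1: seg.t_end]
        truth = demo_locus.truth["insert"]
        call = characterize_insertion(
            intron, tuple(truth["interval"]),
            consensus=SequenceRecord(id="c",
                                     residues=demo_locus.truth["consensus"]),
            signal_end=295)
        assert call.tsd.length == 12
        assert call.polyA_tail_length == 15
        assert call.signal_to_tsd_distance == 79
        assert tuple(call.consensus_spectrum) == (14, 2, 1, 2)
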