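import pytest

from intronret.gene_models import build_intron_retained, build_spliced
from intronret.insilico_pcr import (BindingSite, GeometryError, Primer,
                                    adapt_primer, find_binding_sites,
                                    predict_amplicon, predict_amplicons,
                                    read_primer_tsv)
from intronret.seq_io import SequenceRecord, reverse_complement
from intronret.synthetic_data import LocusParams, generate_locus, random_dna


def _rec(seq):
    return SequenceRecord(id="t", residues=seq)


class TestBindingSites:
    def test_forward_primer_at_template_prefix(self, rng):
        tpl = random_dna(rng, 100)
        primer = Primer("f", tpl[:20], "forward")
        sites = find_binding_sites(_rec(tpl), primer)
        assert BindingSite(1, 20, "forward") in sites

    def test_reverse_primer_site_is_revcomp_footprint(self, rng):
        tpl = random_dna(rng, 60)
        primer = Primer("r", reverse_complement(tpl[9:30]), "reverse")
        sites = find_binding_sites(_rec(tpl), primer)
        assert BindingSite(10, 30, "reverse") in sites

    def test_internal_mismatch_tolerance(self, rng):
        tpl = random_dna(rng, 60)
        probe = tpl[10:30]
        mutated = probe[:5] + ("A" if probe[5] != "A" else "C") + probe[6:]
        primer = Primer("f", mutated, "forward")
        assert find_binding_sites(_rec(tpl), primer, max_mismatch=0) == []
        sites = find_binding_sites(_rec(tpl), primer, max_mismatch=1)
        assert [(s.start, s.end, s.mismatches) for s in sites] == [(11, 30, 1)]

    def test_three_prime_terminal_mismatch_always_blocks(self, rng):
        tpl = random_dna(rng, 60)
        probe = tpl[10:30]
        bad_end = probe[:-1] + ("A" if probe[-1] != "A" else "C")
        primer = Primer("f", bad_end, "forward")
        assert find_binding_sites(_rec(tpl), primer, max_mismatch=2) == []
        relaxed = find_binding_sites(_rec(tpl), primer, max_mismatch=2,
                                     require_three_prime_match=False)
        assert len(relaxed) == 1


class TestAmplicons:
    def test_printed_reference_coordinates_give_687(self):
        f = BindingSite(545, 568, "forward")
        r = BindingSite(1209, 1231, "reverse")
        tpl = _rec("A" * 1300)
        assert predict_amplicon(tpl, f, r).product_length == 687

    def test_full_template_amplicon_has_template_length(self, rng):
        tpl = random_dna(rng, 200)
        f = BindingSite(1, 20, "forward")
        r = BindingSite(181, 200, "reverse")
        assert predict_amplicon(_rec(tpl), f, r).product_length == 200

    def test_overlapping_sites_rejected(self):
        f = BindingSite(10, 40, "forward")
        r = BindingSite(30, 60, "reverse")
        with pytest.raises(GeometryError):
            predict_amplicon(_rec("A" * 100), f, r)

    def test_wrong_orientation_rejected(self):
        f = BindingSite(1, 20, "forward")
        with pytest.raises(GeometryError):
            predict_amplicon(_rec("A" * 100), f, f)

    def test_strand_symmetry_of_product_length(self, rng):
        tpl = random_dna(rng, 300)
        fwd = Primer("f", tpl[20:42], "forward")
        rev = Primer("r", reverse_complement(tpl[250:272]), "reverse")
        amps = predict_amplicons(_rec(tpl), fwd, rev)
        # reverse-complement the template and swap the primer roles
        rc = reverse_complement(tpl)
        fwd2 = Primer("f2", rev.sequence, "forward")
        rev2 = Primer("r2", fwd.sequence, "reverse")
        amps_rc = predict_amplicons(_rec(rc), fwd2, rev2)
        assert [a.product_length for a in amps] == \
            [a.product_length for a in amps_rc] == [252]

    def test_segment_map_product_matches_string_arithmetic(self, basic_locus):
        retained = build_intron_retained(basic_locus.gene, basic_locus.genome, 2)
        rec = retained.to_record()
        by_name = {p.name: p for p in basic_locus.primers}
        f = find_binding_sites(rec, by_name["fwd_exon"])[0]
        r = find_binding_sites(rec, by_name["rev_intron"])[0]
        amp = predict_amplicon(rec, f, r, build=retained)
        assert amp.product_length == \
            basic_locus.truth["primers"]["product_retained_intron_pair"]
        assert amp.spans_retained_intron
        # direct string-position check: the amplicon is the substring between
        # the forward site start and reverse site end
        assert amp.product_length == len(
            retained.sequence[f.start - 1: r.end])

    @pytest.mark.parametrize("seed", range(4))
    def test_intron_primer_discriminates_templates(self, seed):
        locus = generate_locus(LocusParams(), seed=200 + seed)
        spliced = build_spliced(locus.gene, locus.genome)
        retained = build_intron_retained(locus.gene, locus.genome, 2)
        by_name = {p.name: p for p in locus.primers}
        fwd, rev = by_name["fwd_exon"], by_name["rev_intron"]
        assert predict_amplicons(spliced.to_record(), fwd, rev) == []
        retained_products = predict_amplicons(retained.to_record(), fwd, rev,
                                              build=retained)
        assert len(retained_products) == 1
        assert retained_products[0].spans_retained_intron


class TestAdaptPrimer:
    def test_identical_contexts_change_nothing(self, rng):
        ctx = random_dna(rng, 120)
        primer = Primer("f", ctx[40:62], "forward")
        adapted, n, ok = adapt_primer(primer, ctx, ctx)
        assert ok and n == 0
        assert adapted.sequence == primer.sequence

    def test_three_substitutions_inside_footprint_recovered(self, rng):
        ctx = random_dna(rng, 120)
        primer = Primer("f", ctx[40:62], "forward")
        target = list(ctx)
        for i in (45, 50, 55):
            target[i] = "A" if ctx[i] != "A" else "C"
        adapted, n, ok = adapt_primer(primer, ctx, "".join(target))
        assert ok and n == 3
        assert adapted.sequence == "".join(target)[40:62]

    def test_substitution_outside_footprint_ignored(self, rng):
        ctx = random_dna(rng, 120)
        primer = Primer("f", ctx[40:62], "forward")
        target = list(ctx)
        target[10] = "A" if ctx[10] != "A" else "C"
        _, n, ok = adapt_primer(primer, ctx, "".join(target))
        assert ok and n == 0

    def test_reverse_primer_adaptation_projects_through_revcomp(self, rng):
        ctx = random_dna(rng, 120)
        primer = Primer("r", reverse_complement(ctx[40:62]), "reverse")
        target = list(ctx)
        target[50] = "A" if ctx[50] != "A" else "C"
        adapted, n, ok = adapt_primer(primer, ctx, "".join(target))
        assert ok and n == 1
        assert adapted.sequence == reverse_complement("".join(target)[40:62])

    def test_unbound_primer_raises(self, rng):
        ctx = random_dna(rng, 120)
        with pytest.raises(ValueError, match="does not bind"):
            adapt_primer(Primer("f", "ACGT" * 5, "forward"), ctx, ctx)

    def test_deletion_in_footprint_flags_failure(self, rng):
        ctx = random_dna(rng, 120)
        primer = Primer("f", ctx[40:62], "forward")
        target = ctx[:50] + ctx[53:]  # 3 nt deleted inside the footprint
        original, n, ok = adapt_primer(primer, ctx, target)
        assert not ok
        assert original.sequence == primer.sequence


def test_primer_tsv_reader(tmp_path):
    p = tmp_path / "primers.tsv"
    p.write_text("name\trole\tsequence\nf1\tforward\tACGTACGTACGT\n")
    primers = read_primer_tsv(p)
    assert primers == [Primer("f1", "ACGTACGTACGT", "forward")]


def test_primer_validation():
    with pytest.raises(ValueError, match="length"):
        Primer("x", "ACGT", "forward")
    with pytest.raises(ValueError, match="unambiguous"):
        Primer("x", "ACGTNACGTNAC", "forward")
    with pytest.raises(ValueError, match="role"):
        Primer("x", "ACGTACGTACGT", "fwd")
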