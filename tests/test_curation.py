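"""Mitogenome vetting, motif widening and subclade detection."""

import itertools

import numpy as np
import pytest

from mitomotif.curation import (
    MAX_AMBIGUOUS,
    MIN_VETTED_LENGTH,
    detect_subclades,
    subclade_motif_rows,
    vet_batch,
    vet_mitogenome,
    widen_motif,
)
from mitomotif.motifs import Motif
from mitomotif.notation import (
    NotationError,
    RCRS_LENGTH,
    ReadingRange,
    Variant,
    make_haplotype,
    parse_haplotype,
)
from mitomotif.search import neighbor_cost


class TestVetting:
    def test_standard_length_clean_sequence_passes(self):
        r = vet_mitogenome("A" * 16569, "s1")
        assert r.passed and r.reasons == ()

    def test_length_just_below_threshold_fails(self):
        r = vet_mitogenome("A" * (MIN_VETTED_LENGTH - 1), "s2")
        assert not r.passed and "length" in r.reasons[0]

    def test_ten_ambiguous_symbols_fail(self):
        seq = "N" * (MAX_AMBIGUOUS + 1) + "A" * (16569 - MAX_AMBIGUOUS - 1)
        r = vet_mitogenome(seq, "s3")
        assert not r.passed and r.ambiguous_count == 10

    def test_nine_ambiguous_symbols_pass(self):
        seq = "Y" * MAX_AMBIGUOUS + "A" * (16569 - MAX_AMBIGUOUS)
        assert vet_mitogenome(seq, "s4").passed

    def test_both_rules_reported_together(self):
        r = vet_mitogenome("N" * 100, "s5")
        assert len(r.reasons) == 2

    def test_non_iupac_symbol_rejected(self):
        with pytest.raises(NotationError):
            vet_mitogenome("AX" * 10, "s6")

    def test_batch_is_order_independent(self):
        records = [("a", "A" * 16569), ("b", "A" * 100), ("c", "N" * 16569)]
        fwd = {r.sample_id: r for r in vet_batch(records)}
        rev = {r.sample_id: r for r in vet_batch(records[::-1])}
        assert fwd == rev


def _full(tokens, sid="m", ref_length=RCRS_LENGTH):
    return parse_haplotype(tokens, ReadingRange(1, ref_length), sid, ref_length)


class TestWidening:
    def test_frequent_alternative_becomes_iupac_code(self, rcrs):
        """4 of 7 members carrying 12613A on a G background widen the motif
        position to 12613R."""
        motif = Motif("W1b1", None, _full("73G"))
        members = [_full("73G 12613A", f"c{i}") for i in range(4)]
        members += [_full("73G", f"r{i}") for i in range(3)]
        widened = widen_motif(motif, members, rcrs, min_freq=0.25)
        assert "12613R" in widened.haplotype.tokens()

    def test_rare_alternative_is_ignored(self, rcrs):
        motif = Motif("X", None, _full("73G"))
        members = [_full("73G 12613A", "c0")] + \
            [_full("73G", f"r{i}") for i in range(6)]
        widened = widen_motif(motif, members, rcrs, min_freq=0.25)
        assert widened.haplotype == motif.haplotype

    def test_no_member_variation_leaves_motif_unchanged(self, rcrs):
        motif = Motif("X", None, _full("73G 263G"))
        members = [_full("73G 263G", f"m{i}") for i in range(5)]
        assert widen_motif(motif, members, rcrs).haplotype == motif.haplotype

    def test_widening_never_increases_member_cost(self, rcrs):
        motif = Motif("W1b1", None, _full("73G"))
        members = [_full("73G 12613A", f"c{i}") for i in range(4)]
        members += [_full("73G", f"r{i}") for i in range(3)]
        widened = widen_motif(motif, members, rcrs, min_freq=0.25)
        for m in members:
            before = neighbor_cost(m, motif.haplotype, rcrs).cost
            after = neighbor_cost(m, widened.haplotype, rcrs).cost
            assert after <= before


class TestSubcladeDetection:
    def test_planted_three_variant_subclade(self, rcrs):
        """Three members all carrying {16248T, 146C, 5460A} over the HV
        motif yield exactly one starred candidate."""
        base = Motif("HV", None, _full("14766T"))
        members = [_full("14766T 16248T 146C 5460A", f"m{i}") for i in range(3)]
        cands = detect_subclades(base, members, rcrs)
        assert len(cands) == 1
        c = cands[0]
        assert c.proposed_name == "HV*"
        assert set(c.variant_tokens()) == {"16248T", "146C", "5460A"}
        assert len(c.carriers) == 3

    def test_no_shared_extras_yields_nothing(self, rcrs):
        base = Motif("X", None, _full("73G"))
        members = [_full("73G 1000G", "a"), _full("73G 2000T", "b")]
        assert detect_subclades(base, members, rcrs) == []

    def test_heteroplasmies_and_length_variants_do_not_count(self, rcrs):
        base = Motif("X", None, _full("73G"))
        members = [_full("73G 16093Y 309.1C 150C 1000G", f"m{i}")
                   for i in range(2)]
        cands = detect_subclades(base, members, rcrs, min_variants=2)
        assert len(cands) == 1
        assert set(cands[0].variant_tokens()) == {"150C", "1000G"}

    def test_nested_sub_subclade_naming_and_containment(self, rcrs):
        base = Motif("L2a5", None, _full("73G"))
        inner = "73G 1000G 2000T 3000A"
        outer = inner + " 4000G 5000T 6000A"
        members = [_full(inner, "a"), _full(inner, "b"),
                   _full(outer, "c"), _full(outer, "d")]
        cands = detect_subclades(base, members, rcrs)
        by_name = {c.proposed_name: c for c in cands}
        assert set(by_name) == {"L2a5*", "L2a5*1"}
        parent, child = by_name["L2a5*"], by_name["L2a5*1"]
        assert set(parent.extra_variants) < set(child.extra_variants)
        assert set(child.carriers) < set(parent.carriers)

    def test_single_carrier_needs_override(self, rcrs):
        base = Motif("C1c+195", None, _full("73G"))
        members = [_full("73G 16176T 203A 204C", "only")]
        assert detect_subclades(base, members, rcrs) == []
        cands = detect_subclades(base, members, rcrs,
                                 allow_single_carrier=True)
        assert len(cands) == 1 and cands[0].carriers == ("only",)

    def test_matches_brute_force_enumeration(self, toy_ref):
        """Candidates equal the brute-force closed-subset enumeration on
        randomized small member sets."""
        rng = np.random.default_rng(17)
        rr = ReadingRange(1, toy_ref.length)
        pool = [Variant("sub", p, 0, "T" if toy_ref.base(p) != "T" else "A")
                for p in range(10, 26, 2)]
        base = Motif("B", None, make_haplotype("B", rr, [], toy_ref.length))
        for _ in range(20):
            members = []
            extras = []
            for i in range(5):
                chosen = frozenset(
                    v for v in pool if rng.random() < 0.5)
                extras.append(chosen)
                members.append(make_haplotype(f"m{i}", rr, sorted(
                    chosen, key=lambda v: v.position), toy_ref.length))
            expected = set()
            for r in range(2, 6):
                for group in itertools.combinations(range(5), r):
                    inter = frozenset.intersection(*(extras[i] for i in group))
                    if len(inter) < 3:
                        continue
                    carriers = frozenset(
                        i for i in range(5) if inter <= extras[i])
                    full_inter = frozenset.intersection(
                        *(extras[i] for i in carriers))
                    if inter == full_inter:
                        expected.add(inter)
            got = {frozenset(c.extra_variants)
                   for c in detect_subclades(base, members, toy_ref,
                                             lv_regions=())}
            assert got == expected

    def test_candidate_rows_use_motif_dialect(self, rcrs):
        base = Motif("HV", None, _full("14766T"))
        members = [_full("14766T 16248T 146C 5460A", f"m{i}") for i in range(2)]
        rows = subclade_motif_rows(base, detect_subclades(base, members, rcrs))
        assert rows[0]["haplogroup"] == "HV*"
        assert rows[0]["parent"] == "HV"
        assert rows[0]["variants"] == "146C 5460A 14766T 16248T"
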