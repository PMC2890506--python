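"""Binding-site scan, extension classes, product pairing, specificity."""

import random

import pytest

from helpers import (
    brute_force_amplicons,
    brute_force_binding_sites,
    classify_oracle,
    revcomp,
    specificity_oracle,
)
from polyprime.insilico_pcr import (
    NONE,
    STRONG,
    WEAK,
    DuplexProfile,
    InsilicoParams,
    classify_primer_binding,
    insilico_pcr,
    is_genome_specific,
    scan_binding_sites,
)


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestScanBindingSites:
    def test_exact_substring_single_zero_mismatch_hit(self):
        rng = random.Random(0)
        template = _rand_seq(rng, 200)
        primer = template[50:70]
        hits = [h for h in scan_binding_sites(primer, template, 0)]
        assert len(hits) == 1
        h = hits[0]
        assert h.template_interval == (50, 70)
        assert h.strand == "+"
        assert h.mismatch_positions_from_3prime == []

    def test_single_3prime_terminal_mismatch_reported_as_position_1(self):
        rng = random.Random(1)
        template = _rand_seq(rng, 120)
        site = template[40:60]
        # primer differs from the template only at its 3'-terminal base
        last = site[-1]
        primer = site[:-1] + {"A": "G", "G": "A", "C": "T", "T": "C"}[last]
        hits = [
            h
            for h in scan_binding_sites(primer, template, 3)
            if h.template_interval == (40, 60) and h.strand == "+"
        ]
        assert len(hits) == 1
        assert hits[0].mismatch_positions_from_3prime == [1]

    def test_equals_brute_force_oracle_on_random_templates(self):
        rng = random.Random(2)
        for _ in range(20):
            template = _rand_seq(rng, 500)
            primer = _rand_seq(rng, 18) if rng.random() < 0.5 else template[100:118]
            got = {
                (h.template_interval[0], h.template_interval[1], h.strand,
                 tuple(h.mismatch_positions_from_3prime))
                for h in scan_binding_sites(primer, template, 3)
            }
            expect = {
                (s, e, st, tuple(mm))
                for s, e, st, mm in brute_force_binding_sites(primer, template, 3)
            }
            assert got == expect

    def test_primer_longer_than_template_gives_empty(self):
        assert scan_binding_sites("ACGTACGTACGT", "ACGT", 3) == []


class TestClassification:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([1], NONE),
            ([5], WEAK),
            ([], STRONG),
            ([9, 14], STRONG),
            ([2], WEAK),
            ([1, 9], NONE),
            ([6], STRONG),
            ([2, 6, 9, 12], NONE),  # 4 mismatches exceed the cap
        ],
    )
    def test_rule_table(self, positions, expected):
        profile = DuplexProfile((0, 20), "+", positions)
        assert classify_primer_binding(profile) == expected

    def test_gap_in_3prime_hexamer_blocks_extension(self):
        profile = DuplexProfile((0, 20), "+", [], gap_in_3prime_hexamer=True)
        assert classify_primer_binding(profile) == NONE

    def test_adding_mismatches_never_upgrades_class(self):
        order = {NONE: 0, WEAK: 1, STRONG: 2}
        rng = random.Random(3)
        for _ in range(200):
            base = sorted(rng.sample(range(1, 21), rng.randint(0, 3)))
            extra = rng.choice([p for p in range(1, 21) if p not in base])
            c0 = classify_primer_binding(DuplexProfile((0, 21), "+", base))
            c1 = classify_primer_binding(DuplexProfile((0, 21), "+", sorted(base + [extra])))
            assert order[c1] <= order[c0]

    def test_matches_independent_rule_oracle(self):
        rng = random.Random(4)
        for _ in range(200):
            pos = sorted(rng.sample(range(1, 21), rng.randint(0, 5)))
            got = classify_primer_binding(DuplexProfile((0, 21), "+", pos))
            assert got == classify_oracle(pos)


class TestInsilicoPcr:
    def test_absent_primers_give_no_products(self):
        rng = random.Random(5)
        template = _rand_seq(rng, 300)
        amps = insilico_pcr("G" * 20, "C" * 20, {"t": template})
        assert amps == []

    def test_two_forward_sites_one_reverse_site(self):
        rng = random.Random(6)
        fwd = _rand_seq(rng, 20)
        rev = _rand_seq(rng, 20)
        spacer1 = _rand_seq(rng, 150)
        spacer2 = _rand_seq(rng, 150)
        template = fwd + spacer1 + fwd + spacer2 + revcomp(rev)
        amps = insilico_pcr(fwd, rev, {"t": template})
        sizes = sorted(a.size_bp for a in amps)
        assert sizes == [190, 360]
        assert {(s, e, c) for a in amps for s, e, c in [(*a.interval, a.amp_class)]} == set(
            brute_force_amplicons(fwd, rev, template)
        )

    def test_strand_symmetry(self):
        rng = random.Random(7)
        fwd, rev = _rand_seq(rng, 19), _rand_seq(rng, 21)
        template = fwd + _rand_seq(rng, 400) + revcomp(rev)
        fwd_amps = insilico_pcr(fwd, rev, {"t": template})
        rc_amps = insilico_pcr(fwd, rev, {"t": revcomp(template)})
        n = len(template)
        assert sorted(a.size_bp for a in fwd_amps) == sorted(a.size_bp for a in rc_amps)
        mirrored = sorted((n - e, n - s) for a in rc_amps for s, e in [a.interval])
        assert mirrored == sorted(a.interval for a in fwd_amps)


class TestGenomeSpecificity:
    def _triplet(self, rng):
        """Target plus two off-targets with sparse substitutions."""
        target = _rand_seq(rng, 400)
        def mutate(seq):
            s = list(seq)
            for _ in range(rng.randint(3, 12)):
                p = rng.randrange(len(s))
                s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
            return "".join(s)
        return target, mutate(target), mutate(target)

    def test_internal_position5_mismatch_is_not_specific(self):
        rng = random.Random(8)
        target = _rand_seq(rng, 320)
        # off-target identical except one substitution
        p = 250
        off = target[:p] + {"A": "G", "G": "A", "C": "T", "T": "C"}[target[p]] + target[p + 1 :]
        fwd = target[10:30]
        # reverse primer whose 3' end sits 4 bases right of the SNP:
        # off-target mismatch lands at position 5 from the 3' end -> WEAK
        rev = revcomp(target[p - 4 : p + 16])
        rep = is_genome_specific(fwd, rev, ("t", target), {"o": off})
        assert not rep.specific
        assert any("offtarget_weak" in r for r in rep.reasons)

    def test_3prime_terminal_mismatch_is_specific(self):
        rng = random.Random(9)
        target = _rand_seq(rng, 320)
        p = 250
        off = target[:p] + {"A": "G", "G": "A", "C": "T", "T": "C"}[target[p]] + target[p + 1 :]
        fwd = target[10:30]
        # anchor the reverse primer's 3'-terminal base on the SNP -> NONE
        rev = revcomp(target[p : p + 20])
        rep = is_genome_specific(fwd, rev, ("t", target), {"o": off})
        assert rep.specific

    def test_verdicts_match_brute_force_oracle(self):
        rng = random.Random(10)
        agree = 0
        for _ in range(100):
            target, off1, off2 = self._triplet(rng)
            s = rng.randrange(0, 150)
            fwd = target[s : s + 18]
            e = rng.randrange(250, 380)
            rev = revcomp(target[e - 18 : e])
            rep = is_genome_specific(fwd, rev, ("t", target), {"o1": off1, "o2": off2})
            expect = specificity_oracle(fwd, rev, target, [off1, off2])
            assert rep.specific == expect
            agree += 1
        assert agree == 100
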