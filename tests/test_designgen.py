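"""First/second-generation designers, triggers and CTS construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isbh.designgen import (
    DesignError,
    FIRST_GEN_MISMATCHES,
    design_first_gen,
    design_second_gen,
    design_trigger,
    make_cts,
    make_extension,
    make_spacer_star,
)
from isbh.fold import structure_probability
from isbh.seqcore import LEGAL_PAIRS, NucSeq, gc_content, revcomp

FIRST_GEN_TARGET = "((((((((((..(((..(((" + "." * 14 + ")))..)))..))))))))))"

spacer_strategy = st.text(alphabet="ACGU", min_size=20, max_size=20).map(
    lambda t: NucSeq("sp", t)
)


class TestSpacerStar:
    def test_poly_a_example(self):
        star = make_spacer_star(NucSeq("a", "A" * 20))
        assert str(star) == "UUUUUUUUUUAAUUUAAUUU"

    def test_no_positions_gives_exact_revcomp(self, spacer):
        assert str(make_spacer_star(spacer, set())) == str(revcomp(spacer))

    def test_differs_from_revcomp_at_exactly_default_positions(self, spacer):
        star = str(make_spacer_star(spacer))
        rc = str(revcomp(spacer))
        diffs = {i + 1 for i, (a, b) in enumerate(zip(star, rc)) if a != b}
        assert diffs == FIRST_GEN_MISMATCHES

    def test_position_out_of_range_rejected(self, spacer):
        with pytest.raises(DesignError, match="21"):
            make_spacer_star(spacer, {21})

    @settings(derandomize=True, max_examples=50)
    @given(spacer_strategy)
    def test_mismatches_never_pair(self, sp):
        """Identical-base substitutions can form neither WC nor wobble."""
        star = str(make_spacer_star(sp))
        for p in FIRST_GEN_MISMATCHES:
            partner = str(sp)[20 - p]  # spacer base paired with star pos p
            assert (star[p - 1], partner) not in LEGAL_PAIRS


class TestExtension:
    def test_length_and_gc_bounds(self):
        for seed in range(50):
            ext = make_extension(seed)
            assert len(ext) == 10
            assert 0.40 <= gc_content(ext) <= 0.60

    def test_deterministic_for_fixed_seed(self):
        assert str(make_extension(7)) == str(make_extension(7))

    def test_unattainable_bounds_rejected(self):
        with pytest.raises(DesignError, match="unattainable"):
            make_extension(0, length=10, gc_bounds=(0.45, 0.451))


class TestFirstGeneration:
    def test_cassette_geometry(self, spacer):
        d = design_first_gen(spacer, rng_seed=0)
        assert len(d.cassette) == 54  # 20 + 14 + 20
        assert len(d.backfold) == 20
        assert d.engineered_addition_len == 36

    def test_target_matches_printed_fold_string(self, spacer):
        d = design_first_gen(spacer, rng_seed=0)
        assert d.target.text == FIRST_GEN_TARGET
        assert len(d.target) == 54

    def test_gc_clamp_at_five_prime_end(self, spacer):
        d = design_first_gen(spacer, rng_seed=0)
        assert str(d.full_sequence)[:2] == "GC"

    def test_scaffold_appended(self, spacer):
        d = design_first_gen(spacer, rng_seed=0)
        assert str(d.full_sequence).endswith(str(d.scaffold))

    def test_invalid_spacer_length_rejected(self):
        with pytest.raises(DesignError, match="20 nt"):
            design_first_gen(NucSeq("bad", "ACGU"))

    def test_target_structure_is_legal_for_cassette(self, spacer):
        d = design_first_gen(spacer, rng_seed=0)
        assert structure_probability(d.cassette, d.target) > 0


class TestSecondGeneration:
    def test_backfold_thirty(self, spacer):
        d = design_second_gen(spacer, rng_seed=1)
        assert len(d.backfold) == 30
        assert len(d.cassette) == 74  # 30 + 14 + 10 + 20
        assert d.engineered_addition_len == 56

    def test_extension_star_mismatch_positions(self, spacer):
        d = design_second_gen(spacer, rng_seed=1)
        ext_star = str(d.backfold)[20:]
        rc = str(revcomp(d.extension))
        diffs = {i + 1 for i, (a, b) in enumerate(zip(ext_star, rc)) if a != b}
        assert diffs == {1, 2, 6, 7}

    def test_extension_gc_bounds(self, spacer):
        d = design_second_gen(spacer, rng_seed=1)
        assert 0.40 <= gc_content(d.extension) <= 0.60

    def test_deterministic(self, spacer):
        d1 = design_second_gen(spacer, rng_seed=3)
        d2 = design_second_gen(spacer, rng_seed=3)
        assert str(d1.full_sequence) == str(d2.full_sequence)


class TestTrigger:
    def test_first_gen_core_34(self, spacer):
        d = design_first_gen(spacer, rng_seed=0)
        t = design_trigger(d)
        assert len(t.core) == 34
        assert len(t) == 34

    def test_second_gen_core_44(self, spacer):
        d = design_second_gen(spacer, rng_seed=0)
        t = design_trigger(d)
        assert len(t.core) == 44

    def test_flanked_lengths_and_window(self, spacer):
        d = design_second_gen(spacer, rng_seed=0)
        t = design_trigger(d, flank5_len=100, flank3_len=100, rng_seed=0)
        assert len(t) == 244
        assert t.window == (101, 144)
        t3 = design_trigger(d, flank3_len=100, rng_seed=0)
        assert len(t3) == 144

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(spacer_strategy)
    def test_core_exactly_complementary_to_sensing_region(self, sp):
        d = design_second_gen(sp, rng_seed=2)
        t = design_trigger(d, rng_seed=2)
        assert str(t.core) == str(revcomp(d.sensing_region))

    def test_negative_flank_rejected(self, spacer):
        d = design_first_gen(spacer, rng_seed=0)
        with pytest.raises(DesignError):
            design_trigger(d, flank5_len=-1)


class TestCts:
    def test_length_and_pam(self, spacer):
        cts = make_cts(spacer)
        dna = cts.as_dna()
        assert len(dna) == 23
        assert dna[20] in "ACGT" and dna[21:] == "GG"

    def test_protospacer_matches_spacer_rna(self, spacer):
        cts = make_cts(spacer)
        assert cts.residues[:20] == str(spacer)
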