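"""Folding engine vs the exhaustive enumeration oracle, plus dot-bracket."""

import math

import numpy as np
import pytest

from isbh.designgen import design_first_gen
from isbh.fixtures import make_spacer
from isbh.fold import (
    enumerate_structures,
    get_engine,
    mfe,
    oracle_summary,
    parse_dotbracket,
    partition,
    structure_probability,
    unpaired_profile,
)
from isbh.fold.dotbracket import StructureError, from_pairs, write_ct
from isbh.fold.model import EnergyModel, ModelError, structure_energy
from isbh.fold.oracle import OracleGuardError
from isbh.seqcore import NucSeq


class TestDotBracket:
    def test_hairpin_pairs_outermost_first(self):
        db = parse_dotbracket("(((...)))")
        assert db.pair_map == ((1, 9), (2, 8), (3, 7))

    def test_all_dots_empty_pair_map(self):
        assert parse_dotbracket("....").pair_map == ()

    def test_unbalanced_reports_position(self):
        with pytest.raises(StructureError, match="position 1"):
            parse_dotbracket("(()")
        with pytest.raises(StructureError, match="position 3"):
            parse_dotbracket("())")

    def test_illegal_symbol_reports_position(self):
        with pytest.raises(StructureError, match="position 2"):
            parse_dotbracket(".[.]")

    def test_render_round_trip(self):
        text = "((..((...))..)).."
        db = parse_dotbracket(text)
        assert str(from_pairs(len(text), db.pairs0())) == text

    def test_ct_export_partners(self):
        ct = write_ct("GGGAAACCC", parse_dotbracket("(((...)))"))
        lines = ct.splitlines()
        assert lines[1].split()[4] == "9"   # 1 pairs 9
        assert lines[4].split()[4] == "0"   # loop base unpaired


class TestEnumeration:
    def test_unpairable_sequence_has_only_empty_structure(self, model):
        structures = enumerate_structures("AAAA", model)
        assert len(structures) == 1
        assert structures[0][0].text == "...."
        assert structures[0][1] == 0.0

    def test_hairpin_candidates_present(self, model):
        texts = {db.text for db, _ in enumerate_structures("GGGAAACCC", model)}
        assert "(((...)))" in texts
        assert "........." in texts

    def test_count_matches_independent_recursion(self, model):
        # independent oracle: Nussinov-style structure counting
        s = "GCGAAACGC"

        def count(i, j):
            if j - i < 4:
                return 1
            total = count(i + 1, j)
            for k in range(i + 4, j + 1):
                if model.can_pair(s[i], s[k]):
                    total += count(i + 1, k - 1) * count(k + 1, j)
            return total

        assert len(enumerate_structures(s, model)) == count(0, len(s) - 1)

    def test_guard_rejects_long_sequences(self, model):
        with pytest.raises(OracleGuardError):
            enumerate_structures("A" * 19, model)


class TestOracleEquivalence:
    """DP partition, MFE and unpaired profiles against brute force."""

    def test_random_sequences_match_enumeration(self, model):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = int(rng.integers(5, 15))
            s = "".join(rng.choice(list("ACGU"), n))
            summ = oracle_summary(s, model)
            assert partition(s, model).log_partition == pytest.approx(
                summ["log_partition"], abs=1e-9
            )
            assert mfe(s, model).mfe_energy == pytest.approx(
                summ["mfe_energy"], abs=1e-9
            )
            np.testing.assert_allclose(
                unpaired_profile(s, model), summ["unpaired_prob"], atol=1e-9
            )

    def test_gc_rich_multiloop_lengths_match(self, model):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(15, 19))
            s = "".join(rng.choice(list("GC"), n))
            summ = oracle_summary(s, model)
            assert partition(s, model).log_partition == pytest.approx(
                summ["log_partition"], abs=1e-9
            )
            assert mfe(s, model).mfe_energy == pytest.approx(
                summ["mfe_energy"], abs=1e-9
            )

    def test_structure_probabilities_sum_to_one(self, model):
        summ = oracle_summary("GGGAAACCC", model)
        total = sum(
            structure_probability("GGGAAACCC", db, model)
            for db in summ["structures"]
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestPartition:
    def test_unpairable_sequence_lnz_zero(self, model):
        assert partition("AAAA", model).log_partition == pytest.approx(0.0)

    def test_z_bounds_single_term(self, model):
        s = "GGGCAAAGCCC"
        lnz = partition(s, model).log_partition
        emfe = mfe(s, model).mfe_energy
        assert lnz >= -emfe / model.RT - 1e-12  # Z >= exp(-E_mfe/RT)


class TestMfe:
    def test_unpairable_sequence_empty_structure(self, model):
        res = mfe("AAAAAA", model)
        assert res.mfe_structure.text == "......"
        assert res.mfe_energy == 0.0

    def test_simple_hairpin(self, model):
        assert mfe("GGGAAACCC", model).mfe_structure.text == "(((...)))"

    def test_traceback_energy_consistent(self, model):
        rng = np.random.default_rng(55)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGU"), 40))
            res = mfe(s, model)
            recomputed = structure_energy(s, res.mfe_structure.pairs0(), model)
            assert recomputed == pytest.approx(res.mfe_energy, abs=1e-9)

    def test_first_gen_cassettes_mostly_fold_to_target(self, model):
        # Diagnostic of energy-model quality: the designed hairpin should
        # usually be the MFE structure of its own cassette.
        rng = np.random.default_rng(42)
        hits = 0
        n_designs = 30
        for i in range(n_designs):
            d = design_first_gen(make_spacer(rng, f"s{i}"), rng_seed=rng)
            if mfe(d.cassette, model).mfe_structure.text == d.target.text:
                hits += 1
        assert hits / n_designs >= 0.5


class TestStructureProbability:
    def test_empty_structure_of_unpairable_seq(self, model):
        db = parse_dotbracket("....")
        assert structure_probability("AAAA", db, model) == pytest.approx(1.0)

    def test_mfe_structure_is_modal(self, model):
        s = "GGGAAACCC"
        best = mfe(s, model).mfe_structure
        p_best = structure_probability(s, best, model)
        for db, _ in enumerate_structures(s, model):
            assert p_best >= structure_probability(s, db, model) - 1e-12

    def test_non_pairable_pair_rejected(self, model):
        with pytest.raises(ModelError, match="positions 1-9"):
            structure_probability("AGGAAACCC", parse_dotbracket("(((...)))"), model)


class TestUnpairedProfile:
    def test_unpairable_sequence_all_one(self, model):
        np.testing.assert_allclose(unpaired_profile("AAAA", model), 1.0)

    def test_bounded_in_unit_interval(self, model):
        prof = unpaired_profile("GGGCGCAAAGCGCCC", model)
        assert np.all(prof >= 0.0) and np.all(prof <= 1.0)


class TestExternalAdapter:
    """The ViennaRNA adapter satisfies the same narrow contract."""

    def test_vienna_agrees_on_simple_hairpin(self):
        eng = get_engine("external:vienna")
        res = eng.mfe("GGGGAAAACCCC")
        assert res.mfe_structure.text.startswith("((((")
        assert res.mfe_energy < 0

    def test_vienna_probabilities_well_formed(self):
        eng = get_engine("external:vienna")
        s = "GGGAGCAAAGCUCCC"
        lnz = eng.log_partition(s)
        assert lnz > 0
        prof = eng.unpaired_profile(s)
        assert len(prof) == len(s)
        assert np.all(prof >= 0) and np.all(prof <= 1)

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError, match="unknown fold engine"):
            get_engine("external:nupack")
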