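"""MODesign pipeline: windows, assembly, scoring, ranking, decoupling."""

import numpy as np
import pytest

from isbh.designgen import make_cts
from isbh.fixtures import make_trigger
from isbh.fold import structure_probability
from isbh.modesign import (
    ModesignConfig,
    ModesignError,
    ScoreBreakdown,
    assemble_modular,
    candidates_table,
    enumerate_windows,
    run_modesign,
)
from isbh.seqcore import NucSeq, revcomp


@pytest.fixture(scope="module")
def trigger146():
    return make_trigger(146, seed=3, name="trigD")


@pytest.fixture(scope="module")
def cfg():
    return ModesignConfig(loop_size=14)


@pytest.fixture(scope="module")
def ranked(trigger146, spacer, cfg):
    """One full MODesign run shared across tests (keep all candidates)."""
    open_cfg = ModesignConfig(loop_size=14, fold_probability_floor=0.0)
    return run_modesign(trigger146, spacer, open_cfg)


class TestWindows:
    def test_count_for_146nt_trigger(self, trigger146, cfg):
        windows = enumerate_windows(trigger146, cfg)
        assert len(windows) == 118  # 146 - 29 + 1
        assert windows[0].start == 1
        assert windows[-1].start == 118

    def test_minimum_length_single_window(self, cfg):
        t = NucSeq("t", "ACGU" * 7 + "A")  # exactly one 29 nt window
        assert len(enumerate_windows(t, cfg)) == 1

    def test_too_short_rejected_with_minimum(self, cfg):
        t = NucSeq("t", "ACGU" * 7)  # 28 nt, one short of a window
        with pytest.raises(ModesignError, match="minimum length is 29"):
            enumerate_windows(t, cfg)


class TestAssembly:
    def test_geometry_and_sensing(self, trigger146, spacer, cfg):
        window = enumerate_windows(trigger146, cfg)[30]
        d = assemble_modular(window, spacer, make_cts(spacer), cfg)
        assert len(d.backfold) == 30
        assert len(d.sensing_region) == 15 + cfg.loop_size
        assert str(revcomp(d.sensing_region)) == str(window.seq)

    def test_enforced_cts_complementarity_is_17(self, trigger146, spacer, cfg):
        window = enumerate_windows(trigger146, cfg)[10]
        d = assemble_modular(window, spacer, make_cts(spacer), cfg)
        assert str(d.spacer)[3:] == str(spacer)[3:]  # positions 4..20

    def test_target_structure_legal(self, trigger146, spacer, cfg):
        window = enumerate_windows(trigger146, cfg)[5]
        d = assemble_modular(window, spacer, make_cts(spacer), cfg)
        assert structure_probability(d.cassette, d.target) > 0

    def test_wrong_window_size_rejected(self, spacer, cfg):
        with pytest.raises(ModesignError, match="29 nt"):
            assemble_modular(
                NucSeq("w", "ACGU" * 5), spacer, make_cts(spacer), cfg
            )


class TestScore:
    def test_all_ones_gives_total_one(self):
        assert ScoreBreakdown(1, 1, 1, 1).total == 1.0

    def test_cubed_fold_probability(self):
        assert ScoreBreakdown(0.5, 1, 1, 1).total == 0.125

    def test_enforced_q_floor(self):
        assert ScoreBreakdown(1, 1, 1, 17 / 20).total == pytest.approx(0.85)

    def test_factor_bounds_enforced(self):
        with pytest.raises(ModesignError, match="outside"):
            ScoreBreakdown(1.2, 1, 1, 1)

    def test_monotone_in_each_factor(self):
        base = ScoreBreakdown(0.6, 0.7, 0.8, 0.9)
        for label in "NMPQ":
            kwargs = {k: getattr(base, k) for k in "NMPQ"}
            kwargs[label] = kwargs[label] * 0.5
            assert ScoreBreakdown(**kwargs).total < base.total


class TestPipeline:
    def test_ranked_candidates_bounded_and_sorted(self, ranked):
        assert 0 < len(ranked) <= 118
        totals = [c.score.total for c in ranked]
        assert totals == sorted(totals, reverse=True)
        for c in ranked:
            for label in "NMPQ":
                assert 0.0 <= getattr(c.score, label) <= 1.0

    def test_q_at_least_enforced_floor(self, ranked):
        for c in ranked:
            assert c.score.Q >= 17 / 20

    def test_p_at_least_seed_duplex(self, ranked):
        # 15 sensing nt of the backfold always pair with the window
        full_inside = [c for c in ranked if c.window_start <= 118 - 15]
        for c in full_inside:
            assert c.score.P >= 0.5

    def test_deterministic(self, trigger146, spacer):
        cfg = ModesignConfig(loop_size=14, fold_probability_floor=0.0,
                             max_outputs=5)
        a = run_modesign(trigger146, spacer, cfg)
        b = run_modesign(trigger146, spacer, cfg)
        assert [(c.window_start, c.score.total) for c in a] == [
            (c.window_start, c.score.total) for c in b
        ]

    def test_impossible_floor_warns_and_returns_empty(self, spacer):
        t = make_trigger(40, seed=2)
        cfg = ModesignConfig(loop_size=14, fold_probability_floor=1.0)
        with pytest.warns(UserWarning, match="no candidates"):
            assert run_modesign(t, spacer, cfg) == []

    def test_window_round_trip(self, ranked, trigger146):
        for c in ranked[:10]:
            assert str(revcomp(c.design.sensing_region)) == str(c.window)
            start = c.window_start - 1
            assert str(trigger146)[start: start + 29] == str(c.window)

    def test_table_columns(self, ranked):
        df = candidates_table(ranked)
        assert list(df.columns[:6]) == ["window_start", "N", "M", "P", "Q", "total"]
        assert len(df) == len(ranked)


class TestDecoupling:
    def test_changing_spacer_keeps_sensing_region(self, trigger146, cfg):
        sp1 = NucSeq("a", "GACUGGAGCAGCUCUUCGGA")
        sp2 = NucSeq("b", "AUCGAUCGAUCGGCCGAUAU")
        window = enumerate_windows(trigger146, cfg)[20]
        d1 = assemble_modular(window, sp1, make_cts(sp1), cfg)
        d2 = assemble_modular(window, sp2, make_cts(sp2), cfg)
        assert str(d1.sensing_region) == str(d2.sensing_region)

    def test_changing_trigger_keeps_cts_matching_spacer(self, spacer, cfg):
        t1 = make_trigger(60, seed=1)
        t2 = make_trigger(60, seed=9)
        w1 = enumerate_windows(t1, cfg)[0]
        w2 = enumerate_windows(t2, cfg)[0]
        d1 = assemble_modular(w1, spacer, make_cts(spacer), cfg)
        d2 = assemble_modular(w2, spacer, make_cts(spacer), cfg)
        assert str(d1.spacer)[3:] == str(d2.spacer)[3:] == str(spacer)[3:]
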