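"""MODesign: modular iSBH-sgRNAs that decouple spacer and trigger choice.

In first/second-generation designs the trigger must be complementary to
the whole backfold, which is itself derived from the spacer — so the
trigger sequence is constrained by the CRISPR target. Modular designs cut
that link: the trigger hybridises only to the loop plus the loop-proximal
15 nt of the 30 nt backfold, and the spacer keeps 17 nt (positions 4-20)
of complementarity with the CRISPR-targeting sequence (CTS). The three
5'-most spacer nucleotides instead complete the stem against
trigger-determined backfold positions, which is what occasionally yields
designs with more than 17 nt of CTS complementarity "for free".

The pipeline slides a window of size loop+15 along the trigger, assembles
one candidate hairpin per window, verifies the fold, and ranks candidates
by the composite score N^3 * M * P * Q:

    N  probability that the cassette adopts its target structure
    M  mean openness (unpaired probability) of the trigger window
    P  fraction of the 30 backfold nt complementary to the trigger
    Q  fraction of the 20 spacer nt matching the CTS protospacer
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .designgen import (
    FIRST_GEN_MISMATCHES,
    DesignError,
    HairpinDesign,
    build_target_structure,
    make_cts,
    make_spacer_star,
    mismatched_revcomp,
)
from .fold.adapter import BuiltinEngine, FoldEngine
from .seqcore import NucSeq, WC_PAIRS, complement_base, revcomp

SENSING_PAIR_LEN = 15   # backfold nt paired with the trigger
CTS_COMPLEMENT_LEN = 17  # enforced spacer-CTS matches (spacer 4..20)
BACKFOLD_LEN = 30

#: backfold mismatch (bulge) positions shared by second-gen and modular
#: cassettes: 11-12, 16-17 from the spacer* convention, 21-22, 26-27 from
#: the extension* convention.
MODULAR_MISMATCHES = frozenset({11, 12, 16, 17, 21, 22, 26, 27})


class ModesignError(ValueError):
    """Raised for invalid MODesign inputs."""


@dataclass(frozen=True)
class ModesignConfig:
    loop_size: int = 14
    sensing_pair_len: int = SENSING_PAIR_LEN
    cts_complement_len: int = CTS_COMPLEMENT_LEN
    fold_probability_floor: float = 0.10
    rng_seed: int = 0
    max_outputs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.loop_size < 4:
            raise ModesignError("loop_size must be >= 4")

    @property
    def window_size(self) -> int:
        return self.loop_size + self.sensing_pair_len


@dataclass(frozen=True)
class Window:
    start: int  # 1-based on the trigger
    seq: NucSeq


@dataclass(frozen=True)
class ScoreBreakdown:
    N: float
    M: float
    P: float
    Q: float

    def __post_init__(self) -> None:
        for label in "NMPQ":
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise ModesignError(f"score factor {label}={v} outside [0, 1]")

    @property
    def total(self) -> float:
        return self.N ** 3 * self.M * self.P * self.Q


@dataclass(frozen=True)
class ModularCandidate:
    window_start: int
    window: NucSeq
    design: HairpinDesign
    score: ScoreBreakdown
    bonus_flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def enumerate_windows(trigger: NucSeq, cfg: ModesignConfig) -> List[Window]:
    """All contiguous trigger sub-sequences of the sensing size, 5'->3'.

    Count is len(trigger) - (loop+15) + 1; triggers shorter than one
    window are rejected.
    """
    w = cfg.window_size
    n = len(trigger)
    if n < w:
        raise ModesignError(
            f"trigger ({n} nt) shorter than the sensing window; "
            f"minimum length is {w} nt for loop size {cfg.loop_size}"
        )
    return [
        Window(start + 1, NucSeq(f"{trigger.name}_w{start + 1}",
                                 str(trigger)[start: start + w]))
        for start in range(n - w + 1)
    ]


def assemble_modular(
    window: NucSeq | Window,
    spacer: NucSeq,
    cts: NucSeq,
    cfg: ModesignConfig,
    name: Optional[str] = None,
) -> HairpinDesign:
    """Assemble one modular iSBH-sgRNA for a trigger window.

    Cassette, 5'->3': backfold(30) - loop(L) - extension(10) - spacer(20).

    * backfold 16..30 + loop = reverse complement of the window (the
      contiguous trigger-sensing stretch);
    * backfold 1..15 = mismatched reverse complement of spacer 6..20
      (spacer* convention, mismatches 11-12 in range);
    * extension = mismatched reverse complement of backfold 21..30
      (extension* convention: backfold bulges at 21-22, 26-27);
    * spacer 4..20 matches the CTS protospacer (17 nt enforced); spacer
      1..3 pair with their trigger-determined backfold partners 18..20
      (backfold 16..17 stay unpaired, freeing spacer 4..5 for the CTS).
    """
    win = window.seq if isinstance(window, Window) else window
    L = cfg.loop_size
    if len(win) != cfg.window_size:
        raise ModesignError(
            f"window must be {cfg.window_size} nt for loop size {L}, "
            f"got {len(win)}"
        )
    if len(spacer) != 20:
        raise ModesignError("spacer must be 20 nt")

    rc_win = str(revcomp(win))
    prox = rc_win[: cfg.sensing_pair_len]   # backfold 16..30
    loop = rc_win[cfg.sensing_pair_len:]    # loop (L nt)

    # spacer 1..3 pair with backfold 18..20 (= prox[2], prox[3], prox[4])
    new_spacer = NucSeq(
        spacer.name,
        complement_base(prox[4]) + complement_base(prox[3])
        + complement_base(prox[2]) + str(spacer)[3:],
    )
    distal = str(make_spacer_star(new_spacer, FIRST_GEN_MISMATCHES))[:15]
    backfold = NucSeq("backfold", distal + prox)
    extension = mismatched_revcomp(
        NucSeq("bf_prox10", str(backfold)[20:30]), {4, 5, 9, 10},
        name="extension",
    )
    target = build_target_structure(BACKFOLD_LEN, L, MODULAR_MISMATCHES)
    return HairpinDesign(
        generation="modular",
        spacer=new_spacer,
        backfold=backfold,
        loop=NucSeq("loop", loop),
        extension=extension,
        mismatch_positions=MODULAR_MISMATCHES,
        target=target,
        name=name or f"mod_{spacer.name}_{win.name}",
    )


def _backfold_trigger_matches(
    design: HairpinDesign, trigger: NucSeq, window_start: int, loop_size: int
) -> Tuple[int, int]:
    """(total, distal-extra) backfold positions whose ungapped antiparallel
    trigger partner — extending the seed duplex both ways — is
    WC-complementary."""
    t = str(trigger)
    bf = str(design.backfold)
    total = 0
    extra_distal = 0
    for i in range(1, BACKFOLD_LEN + 1):  # 1-based backfold position
        tpos = window_start + loop_size + BACKFOLD_LEN - i  # 1-based
        if not 1 <= tpos <= len(t):
            continue
        if (bf[i - 1], t[tpos - 1]) in WC_PAIRS:
            total += 1
            if i <= 15:
                extra_distal += 1
    return total, extra_distal


def score_candidate(
    design: HairpinDesign,
    trigger: NucSeq,
    cts: NucSeq,
    window_start: int,
    cfg: ModesignConfig,
    engine: Optional[FoldEngine] = None,
    trigger_unpaired: Optional[np.ndarray] = None,
    N: Optional[float] = None,
) -> ScoreBreakdown:
    """Score one assembled candidate with the N^3*M*P*Q decomposition."""
    engine = engine or BuiltinEngine()
    if N is None:
        N = engine.structure_probability(design.cassette, design.target)
    if trigger_unpaired is None:
        trigger_unpaired = engine.unpaired_profile(trigger)
    w = cfg.window_size
    M = float(np.mean(trigger_unpaired[window_start - 1: window_start - 1 + w]))
    total, _ = _backfold_trigger_matches(design, trigger, window_start, cfg.loop_size)
    P = total / BACKFOLD_LEN
    protospacer = NucSeq("proto", cts.residues[:20])  # RNA form of CTS 1..20
    Q = sum(a == b for a, b in zip(str(design.spacer), str(protospacer))) / 20
    return ScoreBreakdown(N=float(N), M=M, P=P, Q=Q)


def run_modesign(
    trigger: NucSeq,
    spacer: NucSeq,
    cfg: Optional[ModesignConfig] = None,
    engine: Optional[FoldEngine] = None,
    cts: Optional[NucSeq] = None,
) -> List[ModularCandidate]:
    """Enumerate, assemble, fold-check, score and rank modular designs.

    Candidates whose cassette folds into the target structure with
    probability below ``cfg.fold_probability_floor`` are dropped. Output
    is sorted by composite score (descending), ties broken by window
    start; deterministic for identical inputs. An empty survivor set
    returns an empty list with a warning, not an error.
    """
    cfg = cfg or ModesignConfig()
    engine = engine or BuiltinEngine()
    cts = cts or make_cts(spacer)
    profile = engine.unpaired_profile(trigger)
    candidates: List[ModularCandidate] = []
    for window in enumerate_windows(trigger, cfg):
        try:
            design = assemble_modular(window, spacer, cts, cfg)
        except (ModesignError, DesignError):
            continue
        N = engine.structure_probability(design.cassette, design.target)
        if N < cfg.fold_probability_floor:
            continue
        score = score_candidate(
            design, trigger, cts, window.start, cfg,
            engine=engine, trigger_unpaired=profile, N=N,
        )
        total, extra_distal = _backfold_trigger_matches(
            design, trigger, window.start, cfg.loop_size
        )
        cts_matches = round(score.Q * 20)
        candidates.append(
            ModularCandidate(
                window_start=window.start,
                window=window.seq,
                design=design,
                score=score,
                bonus_flags={
                    "extra_backfold_complementarity": extra_distal > 0,
                    "extra_cts_complementarity": cts_matches > cfg.cts_complement_len,
                },
            )
        )
    if not candidates:
        warnings.warn(
            "MODesign produced no candidates above the fold-probability "
            f"floor {cfg.fold_probability_floor}; consider lowering the "
            "floor or changing the loop size",
            stacklevel=2,
        )
        return []
    candidates.sort(key=lambda c: (-c.score.total, c.window_start))
    if cfg.max_outputs is not None:
        candidates = candidates[: cfg.max_outputs]
    return candidates


def candidates_table(candidates: Sequence[ModularCandidate]) -> pd.DataFrame:
    """Ranked TSV-ready summary of a MODesign run."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "window_start": c.window_start,
                "N": c.score.N,
                "M": c.score.M,
                "P": c.score.P,
                "Q": c.score.Q,
                "total": c.score.total,
                "extra_backfold_complementarity":
                    c.bonus_flags["extra_backfold_complementarity"],
                "extra_cts_complementarity":
                    c.bonus_flags["extra_cts_complementarity"],
                "cassette": str(c.design.cassette),
            }
        )
    return pd.DataFrame(rows)
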