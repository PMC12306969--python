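"""Cross-activation pre-screen for panels of designs and triggers.

The wet-lab orthogonality experiment transfects every design against every
trigger and reads out reporter activation; here the analogous screen is a
sequence-complementarity surrogate. The pair score is the longest
contiguous antiparallel Watson-Crick duplex a trigger can form with a
design's sensing region, normalised by sensing-region length: a cognate
trigger scores exactly 1.0, unrelated pairs score near the expected
longest complementary run of random sequences (well below 0.5 for
34-44 nt sensing regions). The score is a hybridisation-potential screen,
not a quantitative activation model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .designgen import HairpinDesign, TriggerSpec
from .seqcore import NucSeq, revcomp


class PanelError(ValueError):
    """Raised for empty design/trigger panels."""


def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring (dynamic programming)."""
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    best = 0
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    for ch in a.encode():
        cur = np.zeros(len(b) + 1, dtype=np.int64)
        match = b_arr == ch
        cur[1:][match] = prev[:-1][match] + 1
        run = int(cur.max())
        if run > best:
            best = run
        prev = cur
    return best


def pair_score(design: HairpinDesign, trigger: NucSeq | TriggerSpec) -> float:
    """Longest contiguous antiparallel WC-complementary run between the
    trigger and the design's sensing region, over sensing length.

    A contiguous antiparallel duplex corresponds to a common substring of
    the sensing region and the reverse complement of the trigger.
    """
    t = trigger.assembled if isinstance(trigger, TriggerSpec) else trigger
    sensing = str(design.sensing_region)
    run = _longest_common_substring(sensing, str(revcomp(t)))
    return run / len(sensing)


@dataclass(frozen=True)
class CrossMatrix:
    design_names: List[str]
    trigger_names: List[str]
    scores: np.ndarray          # |designs| x |triggers|, unit-bounded
    calls: np.ndarray           # "activate" / "silent"
    threshold: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.design_names, columns=self.trigger_names
        )

    def calls_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.design_names, columns=self.trigger_names
        )


def cross_matrix(
    designs: Sequence[HairpinDesign],
    triggers: Sequence[NucSeq | TriggerSpec],
    threshold: float = 0.5,
) -> CrossMatrix:
    """Full pair-score matrix with activate/silent calls by threshold."""
    if not designs or not triggers:
        raise PanelError("design and trigger panels must be non-empty")
    scores = np.zeros((len(designs), len(triggers)))
    for i, d in enumerate(designs):
        for j, t in enumerate(triggers):
            scores[i, j] = pair_score(d, t)
    calls = np.where(scores >= threshold, "activate", "silent")
    trigger_names = [
        t.name if isinstance(t, (NucSeq, TriggerSpec)) else str(j)
        for j, t in enumerate(triggers)
    ]
    return CrossMatrix(
        design_names=[d.name for d in designs],
        trigger_names=trigger_names,
        scores=scores,
        calls=calls,
        threshold=threshold,
    )
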