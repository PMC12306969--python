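"""Seeded synthetic data: spacers, triggers, panels, cytometry tables.

Everything here is generated programmatically so the whole toolkit is
testable offline. Trigger fixtures emulate only the *shapes* of real
inputs — lengths around 146/267/268 nt and the contrast between
unstructured and self-complementary (structured) transcripts — not any
biological sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .cytoquant import EventTable, archetypes, simulate_events
from .designgen import (
    HairpinDesign,
    TriggerSpec,
    design_second_gen,
    design_trigger,
    make_extension,
)
from .seqcore import NucSeq, gc_content, revcomp


class FixtureError(ValueError):
    """Raised for invalid fixture specifications."""


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_spacers: int = 5
    trigger_lengths: Tuple[int, ...] = (146, 267, 268)
    gc_bounds: Tuple[float, float] = (0.40, 0.60)
    # cytometry population parameters
    n_events: int = 100_000
    on_fraction: float = 0.25
    transfection_rate: float = 0.60


def make_spacer(rng: np.random.Generator | int, name: str = "spacer") -> NucSeq:
    """Random 20 nt spacer with GC content in 40-60%."""
    return make_extension(rng, length=20, name=name)


def make_trigger(
    length: int,
    structure_bias: str = "none",
    seed: int | np.random.Generator = 0,
    name: str = "trigger",
) -> NucSeq:
    """Random trigger RNA of the requested length.

    ``structure_bias="high"`` plants self-complementary GC-rich segments
    (each 16 nt arm mirrored by its reverse complement downstream),
    creating stable hairpins and hence low-openness windows; ``"none"``
    leaves the sequence unstructured on average.
    """
    if length < 30:
        raise FixtureError("trigger length must be >= 30 nt")
    if structure_bias not in ("none", "high"):
        raise FixtureError(f"unknown structure_bias {structure_bias!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    seq = list(rng.choice(bases, size=length))
    if structure_bias == "high":
        stem = 16
        n_hairpins = max(1, length // 40)
        segment = length // n_hairpins
        for h in range(n_hairpins):
            start = h * segment
            i = start + int(rng.integers(0, 4))
            j = i + stem + 4 + int(rng.integers(0, 4))  # >= 4 nt apex
            if j + stem > min(start + segment, length):
                continue
            # GC-rich stem arms pair stably
            arm = "".join(rng.choice(bases, size=stem,
                                     p=[0.15, 0.35, 0.35, 0.15]))
            seq[i: i + stem] = list(arm)
            seq[j: j + stem] = list(str(revcomp(NucSeq("arm", arm))))
    return NucSeq(name, "".join(seq))


def make_panel(
    spec: FixtureSpec,
) -> Tuple[List[HairpinDesign], List[TriggerSpec]]:
    """Independent second-generation designs with cognate triggers.

    Spacers are drawn independently, so off-diagonal design/trigger pairs
    share no designed complementarity and an orthogonality screen shows a
    clean diagonal.
    """
    rng = np.random.default_rng(spec.seed)
    designs, triggers = [], []
    for i in range(spec.n_spacers):
        spacer = make_spacer(rng, name=f"sp{i + 1}")
        design = design_second_gen(spacer, rng_seed=rng, name=f"isbh_{i + 1}")
        designs.append(design)
        triggers.append(design_trigger(design, rng_seed=rng))
    return designs, triggers


def make_cytometry_tables(
    spec: FixtureSpec,
) -> Tuple[EventTable, EventTable, EventTable]:
    """(untransfected control, reporter control, ON-condition sample).

    The sample plants ``spec.on_fraction`` of transfected cells in the
    active archetype; the reporter control is a transfected-OFF mixture
    used to calibrate the ECFP gate.
    """
    rng = np.random.default_rng(spec.seed)
    untransfected = simulate_events(
        archetypes(on_fraction=0.0, transfection_rate=0.0),
        n=spec.n_events, seed=rng,
    )
    reporter = simulate_events(
        archetypes(on_fraction=0.0, transfection_rate=spec.transfection_rate),
        n=spec.n_events, seed=rng,
    )
    sample = simulate_events(
        archetypes(
            on_fraction=spec.on_fraction,
            transfection_rate=spec.transfection_rate,
        ),
        n=spec.n_events, seed=rng,
    )
    return untransfected, reporter, sample
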