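"""Simplified nearest-neighbour RNA free-energy model.

The model assigns a free energy (kcal/mol, 37 degC reference) to any
pseudoknot-free secondary structure by decomposing it into loops, the way
Turner-style models do:

* helix stacks: tabulated nearest-neighbour stack energies for adjacent
  pairs, Watson-Crick and G.U wobble;
* hairpin loops: logarithmic length penalty;
* internal loops / bulges: affine penalty in total loop size plus an
  asymmetry term; loops with more than ``max_internal_loop`` unpaired
  nucleotides are disallowed (infinite energy);
* multibranch loops: affine in branch count and unpaired length;
* exterior (unfolded) nucleotides: zero.

Stack values follow published nearest-neighbour measurements to two
decimals; loop parameters are deliberately coarse. The model is meant to
capture hairpin-design thermodynamics well enough for ranking and fold
verification while remaining fully self-contained; an external engine can
be substituted through the adapter for production-grade parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

from ..seqcore import LEGAL_PAIRS, NucSeq

KCAL_MOL_GAS_CONSTANT = 0.0019872  # kcal / (mol K)

#: Nearest-neighbour stack free energies, kcal/mol at 37 degC.
#: Key (XY, WZ) is the stack of outer pair X.Y on inner pair W.Z, i.e. the
#: dinucleotide step 5'-XW-3' paired with 3'-YZ-5'.
STACK_ENERGIES: Dict[Tuple[str, str], float] = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "CG"): -2.24,
    ("AU", "GC"): -2.08, ("AU", "GU"): -0.55, ("AU", "UG"): -1.36,
    ("UA", "AU"): -1.33, ("UA", "UA"): -0.93, ("UA", "CG"): -2.35,
    ("UA", "GC"): -2.11, ("UA", "GU"): -1.00, ("UA", "UG"): -0.99,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("CG", "CG"): -3.26,
    ("CG", "GC"): -2.36, ("CG", "GU"): -1.41, ("CG", "UG"): -2.11,
    ("GC", "AU"): -2.35, ("GC", "UA"): -2.24, ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26, ("GC", "GU"): -1.53, ("GC", "UG"): -2.51,
    ("GU", "AU"): -0.99, ("GU", "UA"): -1.36, ("GU", "CG"): -2.51,
    ("GU", "GC"): -2.11, ("GU", "GU"): -0.50, ("GU", "UG"): +1.30,
    ("UG", "AU"): -1.00, ("UG", "UA"): -0.55, ("UG", "CG"): -1.53,
    ("UG", "GC"): -1.41, ("UG", "GU"): +0.30, ("UG", "UG"): -0.50,
}


class ModelError(ValueError):
    """Raised for energies requested on illegal structural elements."""


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the built-in folding model.

    All energies in kcal/mol at the model temperature (Celsius).
    """

    stack_energies: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(STACK_ENERGIES)
    )
    hairpin_base: float = 5.40        # hairpin loop of 3 nt
    hairpin_log_slope: float = 1.08   # * ln(L/3) for longer loops
    internal_base: float = 1.70
    internal_per_nt: float = 0.35
    internal_asymmetry: float = 0.30
    max_internal_loop: int = 30       # total unpaired nt; larger: disallowed
    multiloop_offset: float = 3.40    # "a": closing a multibranch loop
    multiloop_branch: float = 0.40    # "b": per branch helix
    multiloop_unpaired: float = 0.10  # "c": per unpaired nt in the loop
    min_hairpin_loop: int = 3
    temperature: float = 37.0
    allow_wobble: bool = True

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 3:
            raise ModelError("min_hairpin_loop must be >= 3")
        if self.temperature <= -273.15:
            raise ModelError("temperature below absolute zero")

    @property
    def RT(self) -> float:
        """kcal/mol at the model temperature."""
        return KCAL_MOL_GAS_CONSTANT * (self.temperature + 273.15)

    # -- loop energies -----------------------------------------------------

    def can_pair(self, a: str, b: str) -> bool:
        pair = (a, b)
        if pair in LEGAL_PAIRS:
            return self.allow_wobble or pair not in {("G", "U"), ("U", "G")}
        return False

    def stack(self, outer: str, inner: str) -> float:
        """Stack of outer pair string (e.g. "CG") on inner pair string."""
        return self.stack_energies[(outer, inner)]

    def hairpin(self, loop_len: int) -> float:
        if loop_len < self.min_hairpin_loop:
            return math.inf
        return self.hairpin_base + self.hairpin_log_slope * math.log(
            loop_len / self.min_hairpin_loop
        )

    def internal(self, n1: int, n2: int) -> float:
        """Internal loop / bulge with n1 and n2 unpaired nt on each side."""
        total = n1 + n2
        if total == 0:
            raise ModelError("zero-size internal loop is a stack")
        if total > self.max_internal_loop:
            return math.inf
        return (
            self.internal_base
            + self.internal_per_nt * total
            + self.internal_asymmetry * abs(n1 - n2)
        )

    def multiloop(self, branches: int, unpaired: int) -> float:
        return (
            self.multiloop_offset
            + self.multiloop_branch * branches
            + self.multiloop_unpaired * unpaired
        )


def structure_energy(
    seq: NucSeq | str,
    pairs0: Sequence[Tuple[int, int]],
    model: EnergyModel,
    validate: bool = True,
) -> float:
    """Free energy of a structure given as 0-based nested pairs.

    Returns ``math.inf`` for structures the model disallows (oversized
    internal loops, too-short hairpins). With ``validate``, non-pairable
    pairs raise :class:`ModelError` identifying the pair in 1-based
    coordinates.
    """
    s = str(seq)
    pairs = sorted(pairs0)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
        if validate and not model.can_pair(s[i], s[j]):
            raise ModelError(
                f"bases {s[i]}{s[j]} at positions {i + 1}-{j + 1} cannot pair"
            )

    energy = 0.0
    for i, j in pairs:
        # children: pairs directly enclosed by (i, j)
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            energy += model.hairpin(j - i - 1)
        elif len(children) == 1:
            k1, l1 = children[0]
            n1, n2 = k1 - i - 1, j - l1 - 1
            if n1 == 0 and n2 == 0:
                energy += model.stack(s[i] + s[j], s[k1] + s[l1])
            else:
                energy += model.internal(n1, n2)
        else:
            energy += model.multiloop(len(children), unpaired)
    return energy
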