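"""Exhaustive structure enumeration — the independent folding oracle.

Enumerates every pseudoknot-free structure of a short sequence (legal
pairs, hairpin loops at or above the model minimum) by brute-force
recursion, together with its model energy. Used to validate the dynamic
programmes; guarded to short lengths because the structure count grows
exponentially.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np

from ..seqcore import NucSeq
from .dotbracket import DotBracket, from_pairs
from .model import EnergyModel, structure_energy

MAX_ORACLE_LENGTH = 18


class OracleGuardError(ValueError):
    """Raised when a sequence is too long for exhaustive enumeration."""


def enumerate_structures(
    seq: NucSeq | str, model: Optional[EnergyModel] = None
) -> List[Tuple[DotBracket, float]]:
    """All legal structures of ``seq`` with their energies.

    Includes the empty structure (energy 0). Structures the model
    disallows (oversized internal loops) appear with infinite energy.
    """
    model = model or EnergyModel()
    s = str(seq)
    n = len(s)
    if n > MAX_ORACLE_LENGTH:
        raise OracleGuardError(
            f"sequence length {n} exceeds oracle guard {MAX_ORACLE_LENGTH}"
        )
    minhp = model.min_hairpin_loop

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> Tuple[Tuple[Tuple[int, int], ...], ...]:
        """All pair sets for region [i, j] (0-based inclusive)."""
        if i >= j:
            return ((),)
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + minhp + 1, j + 1):
            if model.can_pair(s[i], s[k]):
                for inner in region(i + 1, k - 1):
                    for rest in region(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return tuple(out)

    results = []
    for pairs in region(0, n - 1):
        db = from_pairs(n, pairs)
        results.append((db, structure_energy(s, pairs, model, validate=False)))
    return results


def oracle_summary(
    seq: NucSeq | str, model: Optional[EnergyModel] = None
) -> dict:
    """MFE energy, ln Z, and unpaired profile by direct enumeration."""
    model = model or EnergyModel()
    s = str(seq)
    n = len(s)
    structures = enumerate_structures(s, model)
    energies = np.array([e for _, e in structures])
    finite = np.isfinite(energies)
    weights = np.where(finite, np.exp(-energies / model.RT), 0.0)
    Z = float(weights.sum())
    unpaired = np.zeros(n)
    for (db, _), w in zip(structures, weights):
        for pos in range(n):
            if db.text[pos] == ".":
                unpaired[pos] += w
    return {
        "mfe_energy": float(energies[finite].min()) if finite.any() else 0.0,
        "log_partition": math.log(Z),
        "unpaired_prob": unpaired / Z,
        "n_structures": len(structures),
        "weights": weights,
        "structures": [db for db, _ in structures],
    }
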