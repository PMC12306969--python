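"""Built-in RNA folding engine: MFE, partition function, probabilities.

Minimum-free-energy structures come from a Zuker-style O(n^3) dynamic
programme; ensemble quantities (partition function, base-pair and unpaired
probabilities, structure probabilities) come from McCaskill-style
inside-outside recursions over the same loop decomposition. The grammar is
unambiguous — every structure is generated exactly once — so the
sum-product (partition) and min-plus (MFE) evaluations are guaranteed
consistent with the exhaustive enumeration oracle on short sequences.

Recursion sketch (1-based, region [i..j]):

    V(i,j)   pair (i,j) closes a hairpin, a stack/internal loop with one
             inner pair, or a multibranch loop with >= 2 branches
    M1(i,j)  multiloop segment whose leftmost base i starts a branch,
             trailing unpaired bases absorbed
    M(i,j)   multiloop segment holding >= 1 branch, split at the start of
             its last branch
    F(i)     exterior suffix; P(k) exterior prefix (for outside weights)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ..seqcore import NucSeq
from .dotbracket import DotBracket, from_pairs
from .model import EnergyModel, ModelError, structure_energy


class FoldError(ValueError):
    """Raised for folding requests the engine cannot honour."""


@dataclass
class FoldResult:
    """Bundle of folding outputs; fields unused by an operation are None."""

    sequence: str
    mfe_structure: Optional[DotBracket] = None
    mfe_energy: Optional[float] = None
    log_partition: Optional[float] = None
    structure_probability: Optional[float] = None
    unpaired_prob: Optional[np.ndarray] = None


def _pair_matrix(s: str, model: EnergyModel) -> np.ndarray:
    n = len(s)
    bp = np.zeros((n + 2, n + 2), dtype=bool)
    for i in range(1, n + 1):
        for j in range(i + model.min_hairpin_loop + 1, n + 1):
            bp[i, j] = model.can_pair(s[i - 1], s[j - 1])
    return bp


def _internal_weight_matrix(model: EnergyModel, boltz: bool) -> np.ndarray:
    """(cap+1)^2 matrix over (n1, n2); stack cell (0,0) excluded."""
    cap = model.max_internal_loop
    out = np.full((cap + 1, cap + 1), 0.0 if boltz else math.inf)
    for n1 in range(cap + 1):
        for n2 in range(cap + 1):
            if n1 + n2 == 0 or n1 + n2 > cap:
                continue
            e = model.internal(n1, n2)
            out[n1, n2] = math.exp(-e / model.RT) if boltz else e
    return out


# ---------------------------------------------------------------------------
# inside (sum-product) recursions
# ---------------------------------------------------------------------------

class _Inside:
    """Inside arrays for the Boltzmann ensemble of one sequence."""

    def __init__(self, seq: NucSeq | str, model: EnergyModel):
        s = str(seq)
        n = len(s)
        self.s, self.n, self.model = s, n, model
        RT = model.RT
        minhp = model.min_hairpin_loop
        self.bp = _pair_matrix(s, model)
        self.Wil = _internal_weight_matrix(model, boltz=True)
        cap = model.max_internal_loop

        self.eb = math.exp(-model.multiloop_branch / RT)
        self.ea = math.exp(-model.multiloop_offset / RT)
        self.xpow = np.exp(
            -model.multiloop_unpaired * np.arange(n + 2) / RT
        )
        hair = np.zeros(n + 1)
        for L in range(minhp, n + 1):
            hair[L] = math.exp(-model.hairpin(L) / RT)

        Vb = np.zeros((n + 2, n + 2))
        Qm1 = np.zeros((n + 2, n + 2))
        Qm = np.zeros((n + 2, n + 2))

        for d in range(0, n):
            for i in range(1, n - d + 1):
                j = i + d
                if d >= minhp + 1 and self.bp[i, j]:
                    val = hair[d - 1]
                    if self.bp[i + 1, j - 1]:
                        st = model.stack(s[i - 1] + s[j - 1], s[i] + s[j - 2])
                        val += Vb[i + 1, j - 1] * math.exp(-st / RT)
                    klim = min(cap, d - minhp - 3)
                    if klim >= 1:
                        sub = Vb[i + 1: i + 2 + klim, j - 1: j - 2 - klim: -1]
                        val += float(
                            np.sum(self.Wil[: klim + 1, : klim + 1] * sub)
                        )
                    if d >= 2 * minhp + 4:
                        val += self.ea * float(
                            np.dot(Qm[i + 1, i + 1: j - 2], Qm1[i + 2: j - 1, j - 1])
                        )
                    Vb[i, j] = val
                # multiloop segment arrays (any span)
                lo = i + minhp + 1
                if lo <= j:
                    Qm1[i, j] = self.eb * float(
                        np.dot(Vb[i, lo: j + 1], self.xpow[: j - lo + 1][::-1])
                    )
                Qm[i, j] = float(
                    np.dot(
                        self.xpow[: d + 1] + Qm[i, i - 1: j],
                        Qm1[i: j + 1, j],
                    )
                )

        F = np.ones(n + 2)
        for i in range(n, 0, -1):
            F[i] = F[i + 1] + float(np.dot(Vb[i, i + 1: n + 1], F[i + 2: n + 2]))
        P = np.ones(n + 2)
        for k in range(1, n + 1):
            P[k] = P[k - 1] + float(np.dot(Vb[1:k, k], P[0: k - 1]))

        if not np.isfinite(F[1]):
            raise FoldError(
                "partition function overflowed double precision; "
                "sequence too long/stable for the built-in engine"
            )
        self.Vb, self.Qm1, self.Qm, self.F, self.P = Vb, Qm1, Qm, F, P
        self.Z = float(F[1])

    # -- outside ----------------------------------------------------------

    def pair_probabilities(self) -> np.ndarray:
        """(n+1)x(n+1) matrix (1-based) of base-pair probabilities."""
        s, n, model = self.s, self.n, self.model
        RT = model.RT
        cap = model.max_internal_loop
        Vb, Qm1, Qm, F, P = self.Vb, self.Qm1, self.Qm, self.F, self.P
        OV = np.zeros((n + 2, n + 2))
        OQm = np.zeros((n + 2, n + 2))
        OQm1 = np.zeros((n + 2, n + 2))

        for d in range(n - 1, -1, -1):
            for i in range(1, n - d + 1):
                j = i + d
                # OQm: region [i..j] as the ">=1 branch" part of a multiloop
                val = float(np.dot(OQm[i, j + 1: n + 1], Qm1[j + 1, j + 1: n + 1]))
                if i >= 2 and j + 2 <= n:
                    val += self.ea * float(
                        np.dot(OV[i - 1, j + 2: n + 1], Qm1[j + 1, j + 1: n])
                    )
                OQm[i, j] = val
            for i in range(1, n - d + 1):
                j = i + d
                # OQm1: region [i..j] as a last-branch segment
                val = float(
                    np.dot(
                        OQm[1: i + 1, j],
                        self.xpow[:i][::-1] + Qm[1: i + 1, i - 1],
                    )
                )
                if i >= 3 and j + 1 <= n:
                    val += self.ea * float(
                        np.dot(OV[1: i - 1, j + 1], Qm[2:i, i - 1])
                    )
                OQm1[i, j] = val
            for i in range(1, n - d + 1):
                j = i + d
                if not self.bp[i, j]:
                    continue
                val = float(P[i - 1] * F[j + 1])
                if i >= 2 and j + 1 <= n and self.bp[i - 1, j + 1]:
                    st = model.stack(s[i - 2] + s[j], s[i - 1] + s[j - 1])
                    val += OV[i - 1, j + 1] * math.exp(-st / RT)
                k1 = min(cap, i - 2)
                k2 = min(cap, n - j - 1)
                if k1 >= 0 and k2 >= 0 and k1 + k2 >= 1:
                    rows = OV[i - 1 - k1: i, j + 1: j + 2 + k2][::-1]
                    val += float(np.sum(self.Wil[: k1 + 1, : k2 + 1] * rows))
                val += self.eb * float(
                    np.dot(OQm1[i, j: n + 1], self.xpow[: n + 1 - j])
                )
                OV[i, j] = val

        prob = np.zeros((n + 1, n + 1))
        upper = Vb[1: n + 1, 1: n + 1] * OV[1: n + 1, 1: n + 1] / self.Z
        prob[1:, 1:] = np.triu(upper, k=1)
        return prob


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def partition(seq: NucSeq | str, model: Optional[EnergyModel] = None) -> FoldResult:
    """Log partition function ln Z over all legal structures."""
    model = model or EnergyModel()
    inside = _Inside(seq, model)
    return FoldResult(sequence=str(seq), log_partition=math.log(inside.Z))


def structure_probability(
    seq: NucSeq | str,
    structure: DotBracket,
    model: Optional[EnergyModel] = None,
) -> float:
    """Boltzmann probability exp(-E(s)/RT) / Z of one structure.

    The structure must be legal for the sequence: pairable bases and
    hairpin loops at or above the model minimum; illegal pairs raise
    :class:`ModelError` identifying the pair.
    """
    model = model or EnergyModel()
    s = str(seq)
    if len(structure) != len(s):
        raise FoldError(
            f"structure length {len(structure)} != sequence length {len(s)}"
        )
    e = structure_energy(s, structure.pairs0(), model, validate=True)
    if math.isinf(e):
        return 0.0
    lnz = partition(s, model).log_partition
    return min(1.0, math.exp(-e / model.RT - lnz))


def unpaired_profile(
    seq: NucSeq | str, model: Optional[EnergyModel] = None
) -> np.ndarray:
    """Per-position Boltzmann probability of being unpaired."""
    model = model or EnergyModel()
    s = str(seq)
    n = len(s)
    inside = _Inside(s, model)
    pp = inside.pair_probabilities()
    paired = pp.sum(axis=0)[1:] + pp.sum(axis=1)[1:]
    return np.clip(1.0 - paired, 0.0, 1.0)


def mfe(seq: NucSeq | str, model: Optional[EnergyModel] = None) -> FoldResult:
    """A minimum-free-energy structure and its energy.

    Ties are broken deterministically (first branch found in a fixed
    traceback order).
    """
    model = model or EnergyModel()
    s = str(seq)
    n = len(s)
    if n == 0:
        raise FoldError("empty sequence")
    RT = model.RT
    minhp = model.min_hairpin_loop
    cap = model.max_internal_loop
    bp = _pair_matrix(s, model)
    PenIl = _internal_weight_matrix(model, boltz=False)
    b = model.multiloop_branch
    c = model.multiloop_unpaired
    a = model.multiloop_offset

    INF = math.inf
    EV = np.full((n + 2, n + 2), INF)
    EM1 = np.full((n + 2, n + 2), INF)
    EM = np.full((n + 2, n + 2), INF)
    # padding column i-1 for EM prefix lookups must stay inf (empty = no branch)

    for d in range(0, n):
        for i in range(1, n - d + 1):
            j = i + d
            if d >= minhp + 1 and bp[i, j]:
                best = model.hairpin(d - 1)
                if bp[i + 1, j - 1] and np.isfinite(EV[i + 1, j - 1]):
                    st = model.stack(s[i - 1] + s[j - 1], s[i] + s[j - 2])
                    best = min(best, EV[i + 1, j - 1] + st)
                klim = min(cap, d - minhp - 3)
                if klim >= 1:
                    sub = EV[i + 1: i + 2 + klim, j - 1: j - 2 - klim: -1]
                    with np.errstate(invalid="ignore"):
                        cand = np.min(PenIl[: klim + 1, : klim + 1] + sub)
                    best = min(best, float(cand))
                if d >= 2 * minhp + 4:
                    seg = EM[i + 1, i + 1: j - 2] + EM1[i + 2: j - 1, j - 1]
                    if seg.size:
                        best = min(best, a + float(np.min(seg)))
                EV[i, j] = best
            lo = i + minhp + 1
            if lo <= j:
                ls = np.arange(lo, j + 1)
                EM1[i, j] = float(np.min(EV[i, lo: j + 1] + b + c * (j - ls)))
            ks = np.arange(i, j + 1)
            pref = np.minimum(c * (ks - i), EM[i, i - 1: j])
            seg = pref + EM1[i: j + 1, j]
            if seg.size:
                EM[i, j] = float(np.min(seg))

    EF = np.zeros(n + 2)
    for i in range(n, 0, -1):
        best = EF[i + 1]
        for j in range(i + minhp + 1, n + 1):
            if np.isfinite(EV[i, j]):
                best = min(best, EV[i, j] + EF[j + 1])
        EF[i] = best

    # traceback
    pairs: List[Tuple[int, int]] = []
    TOL = 1e-9

    def close(x: float, y: float) -> bool:
        return abs(x - y) <= TOL

    def trace_V(i: int, j: int) -> None:
        pairs.append((i - 1, j - 1))
        d = j - i
        target = EV[i, j]
        if close(target, model.hairpin(d - 1)):
            return
        if bp[i + 1, j - 1] and np.isfinite(EV[i + 1, j - 1]):
            st = model.stack(s[i - 1] + s[j - 1], s[i] + s[j - 2])
            if close(target, EV[i + 1, j - 1] + st):
                trace_V(i + 1, j - 1)
                return
        klim = min(cap, d - minhp - 3)
        for n1 in range(0, klim + 1):
            for n2 in range(0, klim + 1 - n1):
                if n1 + n2 == 0:
                    continue
                k, l = i + 1 + n1, j - 1 - n2
                if np.isfinite(EV[k, l]) and close(
                    target, EV[k, l] + PenIl[n1, n2]
                ):
                    trace_V(k, l)
                    return
        for k in range(i + 2, j - 1):
            if close(target, a + EM[i + 1, k - 1] + EM1[k, j - 1]):
                trace_M(i + 1, k - 1)
                trace_M1(k, j - 1)
                return
        raise AssertionError("MFE traceback failed in V")

    def trace_M1(i: int, j: int) -> None:
        target = EM1[i, j]
        for l in range(i + minhp + 1, j + 1):
            if np.isfinite(EV[i, l]) and close(target, EV[i, l] + b + c * (j - l)):
                trace_V(i, l)
                return
        raise AssertionError("MFE traceback failed in M1")

    def trace_M(i: int, j: int) -> None:
        target = EM[i, j]
        for k in range(i, j + 1):
            if not np.isfinite(EM1[k, j]):
                continue
            if close(target, c * (k - i) + EM1[k, j]):
                trace_M1(k, j)
                return
            if k > i and np.isfinite(EM[i, k - 1]) and close(
                target, EM[i, k - 1] + EM1[k, j]
            ):
                trace_M(i, k - 1)
                trace_M1(k, j)
                return
        raise AssertionError("MFE traceback failed in M")

    def trace_F(i: int) -> None:
        while i <= n:
            if close(EF[i], EF[i + 1]):
                i += 1
                continue
            for j in range(i + minhp + 1, n + 1):
                if np.isfinite(EV[i, j]) and close(EF[i], EV[i, j] + EF[j + 1]):
                    trace_V(i, j)
                    i = j + 1
                    break
            else:
                raise AssertionError("MFE traceback failed in F")

    trace_F(1)
    return FoldResult(
        sequence=s,
        mfe_structure=from_pairs(n, pairs),
        mfe_energy=float(EF[1]),
    )


def fold(seq: NucSeq | str, model: Optional[EnergyModel] = None) -> FoldResult:
    """Full fold: MFE structure/energy plus ensemble quantities."""
    model = model or EnergyModel()
    res = mfe(seq, model)
    inside = _Inside(str(seq), model)
    res.log_partition = math.log(inside.Z)
    pp = inside.pair_probabilities()
    paired = pp.sum(axis=0)[1:] + pp.sum(axis=1)[1:]
    res.unpaired_prob = np.clip(1.0 - paired, 0.0, 1.0)
    return res
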