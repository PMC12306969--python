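"""First- and second-generation iSBH-sgRNA designers, triggers and CTSs.

An inducible spacer-blocking hairpin sgRNA (iSBH-sgRNA) extends the 5' end
of a normal sgRNA so that a "backfold" arm folds back onto the spacer and
blocks it. The engineered 5' addition, read 5'->3', is:

    clamp (GC) - backfold - loop - [extension] - spacer - scaffold

* first generation: backfold = spacer* (20 nt, the mismatched reverse
  complement of the spacer), loop 14 nt; cassette 54 nt.
* second generation: a random 10 nt extension (GC 40-60%) sits between
  loop and spacer and its mismatched complement (extension*) lengthens the
  backfold to 30 nt; cassette 74 nt.

Designed mismatches keep the blocking stem weak enough for a trigger RNA
(complementary to backfold + loop) to open it by strand invasion. The
mismatch rule replaces the complementary base with the base identical to
its pairing partner (A.A, C.C, G.G, U.U), which can form neither a
Watson-Crick nor a G.U wobble pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Tuple

import numpy as np

from .fold import DotBracket, mfe, parse_dotbracket
from .seqcore import NucSeq, SequenceError, complement_base, gc_content, revcomp

#: Canonical S. pyogenes sgRNA scaffold (tracrRNA-fused), 5'->3' RNA.
DEFAULT_SCAFFOLD = NucSeq(
    "scaffold",
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC",
)

CLAMP = NucSeq("clamp", "GC")

FIRST_GEN_MISMATCHES = frozenset({11, 12, 16, 17})
EXTENSION_MISMATCHES = frozenset({1, 2, 6, 7})
DEFAULT_LOOP_LEN = 14
SPACER_LEN = 20
EXTENSION_LEN = 10


class DesignError(ValueError):
    """Raised for invalid design inputs or unattainable constraints."""


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def mismatched_revcomp(
    seq: NucSeq, positions: FrozenSet[int] | set, name: str = "mm_rc"
) -> NucSeq:
    """Reverse complement with designed mismatches.

    ``positions`` are 1-based indices on the *output* strand. At each such
    position the complementary base is replaced by the base identical to
    its pairing partner, which guarantees a non-WC, non-wobble apposition.
    """
    L = len(seq)
    for p in positions:
        if not 1 <= p <= L:
            raise DesignError(f"mismatch position {p} outside 1..{L}")
    rc = list(str(revcomp(seq)))
    for p in positions:
        rc[p - 1] = seq[L - p]  # partner base itself
    return NucSeq(name, "".join(rc))


def make_spacer_star(
    spacer: NucSeq, mismatch_positions: FrozenSet[int] | set = FIRST_GEN_MISMATCHES
) -> NucSeq:
    """The blocking-arm copy of the spacer (spacer*).

    Reverse complement of the 20 nt spacer carrying identical-base
    mismatches at the configured 1-based positions (default 11-12 and
    16-17, counted along spacer*).
    """
    if len(spacer) != SPACER_LEN:
        raise DesignError(f"spacer must be {SPACER_LEN} nt, got {len(spacer)}")
    return mismatched_revcomp(spacer, mismatch_positions, name=f"{spacer.name}_star")


def make_extension(
    rng: np.random.Generator | int,
    length: int = EXTENSION_LEN,
    gc_bounds: Tuple[float, float] = (0.40, 0.60),
    name: str = "extension",
) -> NucSeq:
    """Random sequence with GC content inside ``gc_bounds`` (inclusive).

    Deterministic for a fixed seed; rejection sampling. Unattainable
    bounds (no integer G+C count inside them) are rejected up front.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    lo, hi = gc_bounds
    if not (0.0 <= lo <= hi <= 1.0):
        raise DesignError(f"GC bounds {gc_bounds} outside [0, 1]")
    attainable = [k for k in range(length + 1) if lo <= k / length <= hi]
    if not attainable:
        raise DesignError(
            f"GC bounds {gc_bounds} unattainable at length {length}: "
            f"GC counts are multiples of 1/{length}"
        )
    bases = np.array(list("ACGU"))
    while True:
        seq = "".join(rng.choice(bases, size=length))
        gc = (seq.count("G") + seq.count("C")) / length
        if lo <= gc <= hi:
            return NucSeq(name, seq)


def make_cts(spacer: NucSeq, pam: str = "NGG", n_base: str = "A") -> NucSeq:
    """CRISPR-targeting sequence: DNA protospacer plus a concrete PAM.

    The ambiguous N of the NGG PAM is instantiated (default A). The
    protospacer strand shown carries the same sequence as the spacer.
    """
    pam_dna = pam.replace("N", n_base).replace("U", "T")
    dna = spacer.as_dna() + pam_dna
    return NucSeq(f"{spacer.name}_cts", dna, "DNA")


# ---------------------------------------------------------------------------
# design containers
# ---------------------------------------------------------------------------

def build_target_structure(
    backfold_len: int, loop_len: int, mismatch_positions: FrozenSet[int]
) -> DotBracket:
    """Programmatic target dot-bracket of a hairpin cassette.

    The cassette is backfold (B nt) - loop (L nt) - 3' arm (B nt, the
    extension+spacer or spacer). Pairing is fully nested, position i with
    position N+1-i, with dots at the designed mismatch positions (1-based
    on the backfold) and their partners; scaffold and GC clamp excluded.
    """
    n = 2 * backfold_len + loop_len
    chars = ["."] * n
    for i in range(1, backfold_len + 1):
        if i in mismatch_positions:
            continue
        chars[i - 1] = "("
        chars[n - i] = ")"
    return parse_dotbracket("".join(chars))


@dataclass(frozen=True)
class HairpinDesign:
    """A fully annotated iSBH-sgRNA."""

    generation: str  # "first" | "second" | "modular"
    spacer: NucSeq
    backfold: NucSeq
    loop: NucSeq
    extension: Optional[NucSeq]
    mismatch_positions: FrozenSet[int]
    target: DotBracket
    clamp: NucSeq = CLAMP
    scaffold: NucSeq = DEFAULT_SCAFFOLD
    name: str = "isbh"

    def __post_init__(self) -> None:
        if self.generation not in ("first", "second", "modular"):
            raise DesignError(f"unknown generation {self.generation!r}")
        if len(self.spacer) != SPACER_LEN:
            raise DesignError("spacer must be 20 nt")
        expected_backfold = 20 if self.generation == "first" else 30
        if len(self.backfold) != expected_backfold:
            raise DesignError(
                f"{self.generation}-generation backfold must be "
                f"{expected_backfold} nt, got {len(self.backfold)}"
            )
        if len(self.target) != len(self.cassette):
            raise DesignError("target structure length != cassette length")

    @property
    def cassette(self) -> NucSeq:
        """backfold-loop-[extension]-spacer; the folded region (no clamp,
        no scaffold)."""
        ext = str(self.extension) if self.extension else ""
        return NucSeq(
            f"{self.name}_cassette",
            str(self.backfold) + str(self.loop) + ext + str(self.spacer),
        )

    @property
    def sensing_region(self) -> NucSeq:
        """The stretch a cognate trigger hybridises to, 5'->3'.

        Whole backfold + loop for first/second generation; loop-proximal
        15 backfold nt + loop for modular designs.
        """
        if self.generation == "modular":
            text = str(self.backfold)[15:] + str(self.loop)
        else:
            text = str(self.backfold) + str(self.loop)
        return NucSeq(f"{self.name}_sensing", text)

    @property
    def full_sequence(self) -> NucSeq:
        return NucSeq(
            self.name,
            str(self.clamp) + str(self.cassette) + str(self.scaffold),
        )

    @property
    def engineered_addition_len(self) -> int:
        """5' nucleotides added relative to a native sgRNA
        (clamp + backfold + loop + extension)."""
        ext = len(self.extension) if self.extension else 0
        return len(self.clamp) + len(self.backfold) + len(self.loop) + ext

    def to_dict(self) -> dict:
        """JSON-ready annotation with 1-based component coordinates on the
        full sequence."""
        comps = [("clamp", self.clamp), ("backfold", self.backfold), ("loop", self.loop)]
        if self.extension:
            comps.append(("extension", self.extension))
        comps += [("spacer", self.spacer), ("scaffold", self.scaffold)]
        coords = {}
        pos = 1
        for label, seq in comps:
            coords[label] = {"start": pos, "end": pos + len(seq) - 1, "sequence": str(seq)}
            pos += len(seq)
        return {
            "name": self.name,
            "generation": self.generation,
            "components": coords,
            "mismatch_positions": sorted(self.mismatch_positions),
            "target_structure": self.target.text,
            "full_sequence": str(self.full_sequence),
        }


@dataclass(frozen=True)
class TriggerSpec:
    """A trigger RNA: sensing core plus optional flanks and protector
    hairpin placeholders."""

    name: str
    core: NucSeq
    flank5: Optional[NucSeq] = None
    flank3: Optional[NucSeq] = None
    protectors: Tuple[str, ...] = ()
    window: Tuple[int, int] = (0, 0)  # 1-based inclusive on assembled RNA

    @property
    def assembled(self) -> NucSeq:
        text = (
            (str(self.flank5) if self.flank5 else "")
            + str(self.core)
            + (str(self.flank3) if self.flank3 else "")
        )
        return NucSeq(self.name, text)

    def __len__(self) -> int:
        return len(self.assembled)


# ---------------------------------------------------------------------------
# designers
# ---------------------------------------------------------------------------

def _loop_unpaired_fraction(design: HairpinDesign) -> float:
    """Fraction of loop positions unpaired in the cassette MFE structure."""
    struct = mfe(design.cassette).mfe_structure
    start = len(design.backfold)  # 0-based loop start on cassette
    loop_chars = struct.text[start: start + len(design.loop)]
    return loop_chars.count(".") / len(design.loop)


def _sample_loop(
    rng: np.random.Generator,
    build,  # loop NucSeq -> HairpinDesign
    length: int = DEFAULT_LOOP_LEN,
    min_unpaired: float = 0.90,
    max_tries: int = 50,
) -> HairpinDesign:
    """Draw GC-bounded loops until the cassette MFE leaves the loop
    >= ``min_unpaired`` unpaired; keeps the best candidate otherwise."""
    best, best_frac = None, -1.0
    for _ in range(max_tries):
        loop = make_extension(rng, length=length, name="loop")
        design = build(loop)
        frac = _loop_unpaired_fraction(design)
        if frac >= min_unpaired:
            return design
        if frac > best_frac:
            best, best_frac = design, frac
    return best


def design_first_gen(
    spacer: NucSeq,
    loop: Optional[NucSeq] = None,
    rng_seed: int | np.random.Generator = 0,
    name: Optional[str] = None,
) -> HairpinDesign:
    """First-generation iSBH-sgRNA: spacer* - loop(14) - spacer cassette.

    With ``loop=None`` a GC-bounded 14 nt loop is sampled (seeded) and
    checked for openness in the cassette MFE structure.
    """
    if len(spacer) != SPACER_LEN:
        raise DesignError(f"spacer must be {SPACER_LEN} nt, got {len(spacer)}")
    name = name or f"isbh1_{spacer.name}"
    star = make_spacer_star(spacer)
    target = build_target_structure(20, DEFAULT_LOOP_LEN, FIRST_GEN_MISMATCHES)

    def build(loop_seq: NucSeq) -> HairpinDesign:
        return HairpinDesign(
            generation="first",
            spacer=spacer,
            backfold=star.rename("backfold"),
            loop=loop_seq,
            extension=None,
            mismatch_positions=FIRST_GEN_MISMATCHES,
            target=target,
            name=name,
        )

    if loop is not None:
        if len(loop) != DEFAULT_LOOP_LEN:
            raise DesignError(f"loop must be {DEFAULT_LOOP_LEN} nt")
        return build(loop)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return _sample_loop(rng, build)


def design_second_gen(
    spacer: NucSeq,
    rng_seed: int | np.random.Generator = 0,
    loop: Optional[NucSeq] = None,
    name: Optional[str] = None,
) -> HairpinDesign:
    """Second-generation iSBH-sgRNA with a 30 nt backfold.

    A random 10 nt extension (GC 40-60%) is inserted between loop and
    spacer; its mismatched reverse complement (extension*, mismatches at
    positions 1-2 and 6-7) extends the backfold to 30 nt.
    """
    if len(spacer) != SPACER_LEN:
        raise DesignError(f"spacer must be {SPACER_LEN} nt, got {len(spacer)}")
    name = name or f"isbh2_{spacer.name}"
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    star = make_spacer_star(spacer)
    extension = make_extension(rng, length=EXTENSION_LEN)
    ext_star = mismatched_revcomp(extension, EXTENSION_MISMATCHES, name="ext_star")
    backfold = NucSeq("backfold", str(star) + str(ext_star))
    mismatches = frozenset(FIRST_GEN_MISMATCHES | {20 + p for p in EXTENSION_MISMATCHES})

    def build(loop_seq: NucSeq) -> HairpinDesign:
        return HairpinDesign(
            generation="second",
            spacer=spacer,
            backfold=backfold,
            loop=loop_seq,
            extension=extension,
            mismatch_positions=mismatches,
            target=build_target_structure(30, len(loop_seq), mismatches),
            name=name,
        )

    if loop is not None:
        return build(loop)
    return _sample_loop(rng, build)


def design_trigger(
    design: HairpinDesign,
    flank5_len: int = 0,
    flank3_len: int = 0,
    rng_seed: int | np.random.Generator = 0,
    protectors: bool = False,
) -> TriggerSpec:
    """Cognate trigger RNA for a design.

    The core is the exact reverse complement of the design's sensing
    region (backfold + loop; 34 nt for first-, 44 nt for second-generation
    designs) — the trigger sees spacer* as-is, with no mismatches. Random
    flanks of the requested lengths emulate embedding in a longer
    transcript. Protector hairpins are stabilising terminal structures on
    the expressed trigger; they ship as placeholder annotations only.
    """
    if flank5_len < 0 or flank3_len < 0:
        raise DesignError("flank lengths must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    core = revcomp(design.sensing_region).rename("core")
    bases = np.array(list("ACGU"))

    def flank(length: int, label: str) -> Optional[NucSeq]:
        if length == 0:
            return None
        return NucSeq(label, "".join(rng.choice(bases, size=length)))

    f5 = flank(flank5_len, "flank5")
    f3 = flank(flank3_len, "flank3")
    window = (flank5_len + 1, flank5_len + len(core))
    return TriggerSpec(
        name=f"trigger_{design.name}",
        core=core,
        flank5=f5,
        flank3=f3,
        protectors=("5' protector hairpin (placeholder)",
                    "3' protector hairpin (placeholder)") if protectors else (),
        window=window,
    )
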