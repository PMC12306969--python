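"""Expected RT-PCR product sizes for the RNA circularisation assay.

The circularisation assay ligates extracted RNA into circles, reverse
transcribes across the junction, and sizes the nested-PCR product. The
primer pairs sit in constant sequence (sgRNA scaffold, or trigger flank),
so the product size for the native/truncated species is an assay
calibration constant, and a full-length engineered species adds exactly
its engineered 5' addition (clamp + backfold + loop + extension) on top.
For the sgRNA assay the native product is 81 bp, so a full-length
second-generation iSBH-sgRNA (56 nt addition) yields 137 bp; trigger
assays use a 220 bp full-length product. A band collapsing from 137 to
81 bp therefore reports removal of the engineered components during
activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import pandas as pd

from .designgen import HairpinDesign

SPECIES = (
    "native_sgRNA",
    "full_isbh",
    "truncated_isbh",
    "full_trigger",
    "truncated_trigger",
)

#: assay preset -> baseline (native/truncated) amplicon size in bp
ASSAY_BASELINES = {"sgRNA": 81, "trigger": 220}


class AssayError(ValueError):
    """Raised for unknown species or assay presets."""


@dataclass(frozen=True)
class AmpliconLayout:
    """One species in one assay preset."""

    species: str
    baseline_amplicon: int
    removable_components: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise AssayError(f"unknown species {self.species!r}")
        if self.baseline_amplicon <= 0:
            raise AssayError("baseline amplicon must be > 0")
        if any(length < 0 for _, length in self.removable_components):
            raise AssayError("removable component lengths must be >= 0")


def engineered_addition(design: HairpinDesign) -> int:
    """Engineered 5' nucleotides removed on activation:
    clamp + backfold + loop + extension."""
    return design.engineered_addition_len


def layout_for(
    species: str, assay: str = "sgRNA", design: Optional[HairpinDesign] = None
) -> AmpliconLayout:
    """Build the amplicon layout for a species under an assay preset."""
    if assay not in ASSAY_BASELINES:
        raise AssayError(f"unknown assay preset {assay!r}")
    removable: Tuple[Tuple[str, int], ...] = ()
    if species == "full_isbh":
        if design is None:
            raise AssayError("full_isbh layout requires a design")
        comps: List[Tuple[str, int]] = [
            ("clamp", len(design.clamp)),
            ("backfold", len(design.backfold)),
            ("loop", len(design.loop)),
        ]
        if design.extension:
            comps.append(("extension", len(design.extension)))
        removable = tuple(comps)
    return AmpliconLayout(
        species=species,
        baseline_amplicon=ASSAY_BASELINES[assay],
        removable_components=removable,
    )


def predict_amplicon(
    layout: AmpliconLayout, design: Optional[HairpinDesign] = None
) -> int:
    """Expected nested-PCR product size in bp.

    Native and truncated species give the baseline; the full-length iSBH
    species adds the engineered 5' addition.
    """
    if layout.species == "full_isbh":
        if design is None:
            raise AssayError("full_isbh prediction requires a design")
        return layout.baseline_amplicon + engineered_addition(design)
    return layout.baseline_amplicon


def amplicon_table(design: HairpinDesign, assay: str = "sgRNA") -> pd.DataFrame:
    """Species -> expected product size for one design under one preset."""
    if assay == "sgRNA":
        species = ["native_sgRNA", "truncated_isbh", "full_isbh"]
    elif assay == "trigger":
        species = ["truncated_trigger", "full_trigger"]
    else:
        raise AssayError(f"unknown assay preset {assay!r}")
    rows = [
        {
            "species": sp,
            "expected_bp": predict_amplicon(layout_for(sp, assay, design), design),
        }
        for sp in species
    ]
    return pd.DataFrame(rows)
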