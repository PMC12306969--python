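"""Pluggable folding-engine interface.

The built-in engine is the default and the test target. An external
thermodynamics package can be dropped in through the same narrow contract
(sequence -> MFE structure, ln Z, structure probability, unpaired profile);
a ViennaRNA adapter ships here and activates when the ``RNA`` bindings are
importable. Engine selection uses the configuration key
``fold.engine = builtin | external:vienna``.
"""

from __future__ import annotations

import math
from typing import Optional, Protocol

import numpy as np

from ..seqcore import NucSeq
from . import engine as _builtin
from .dotbracket import DotBracket
from .model import EnergyModel


class FoldEngine(Protocol):
    def mfe(self, seq: NucSeq | str) -> _builtin.FoldResult: ...
    def log_partition(self, seq: NucSeq | str) -> float: ...
    def structure_probability(
        self, seq: NucSeq | str, structure: DotBracket
    ) -> float: ...
    def unpaired_profile(self, seq: NucSeq | str) -> np.ndarray: ...


class BuiltinEngine:
    """Default engine backed by the package's own energy model."""

    name = "builtin"

    def __init__(self, model: Optional[EnergyModel] = None):
        self.model = model or EnergyModel()

    def mfe(self, seq):
        return _builtin.mfe(seq, self.model)

    def log_partition(self, seq):
        return _builtin.partition(seq, self.model).log_partition

    def structure_probability(self, seq, structure):
        return _builtin.structure_probability(seq, structure, self.model)

    def unpaired_profile(self, seq):
        return _builtin.unpaired_profile(seq, self.model)


class ViennaEngine:
    """Adapter over the ViennaRNA Python bindings (optional dependency).

    Exposes material/temperature/dangles settings; defaults are the
    ViennaRNA defaults (RNA parameters, 37 degC, dangles=2).
    """

    name = "external:vienna"

    def __init__(self, temperature: float = 37.0, dangles: int = 2):
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "ViennaRNA Python bindings are not installed; "
                "use the builtin engine"
            ) from exc
        self._RNA = RNA
        self.md = RNA.md()
        self.md.temperature = temperature
        self.md.dangles = dangles

    def _fc(self, seq):
        return self._RNA.fold_compound(str(seq), self.md)

    def mfe(self, seq):
        from .dotbracket import parse_dotbracket

        ss, e = self._fc(seq).mfe()
        return _builtin.FoldResult(
            sequence=str(seq),
            mfe_structure=parse_dotbracket(ss),
            mfe_energy=float(e),
        )

    def log_partition(self, seq):
        fc = self._fc(seq)
        _, ge = fc.pf()  # ensemble free energy, kcal/mol
        RT = 0.0019872 * (self.md.temperature + 273.15)
        return -float(ge) / RT

    def structure_probability(self, seq, structure):
        fc = self._fc(seq)
        fc.pf()
        return float(fc.pr_structure(structure.text))

    def unpaired_profile(self, seq):
        fc = self._fc(seq)
        fc.pf()
        bpp = np.array(fc.bpp())  # (n+1)x(n+1), 1-based upper triangle
        paired = bpp.sum(axis=0) + bpp.sum(axis=1)
        return np.clip(1.0 - paired[1:], 0.0, 1.0)


def get_engine(
    name: str = "builtin", model: Optional[EnergyModel] = None, **kwargs
) -> FoldEngine:
    """Resolve a ``fold.engine`` configuration value to an engine."""
    if name == "builtin":
        return BuiltinEngine(model)
    if name in ("external:vienna", "vienna"):
        return ViennaEngine(**kwargs)
    raise ValueError(f"unknown fold engine {name!r}")
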