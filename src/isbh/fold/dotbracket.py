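"""Dot-bracket secondary-structure notation and pair-map utilities.

"." marks an unpaired nucleotide; "(" and ")" mark the 5' and 3' halves of
a base pair. Only pseudoknot-free (properly nested) structures are
representable. Positions in :attr:`DotBracket.pair_map` are 1-based to match
user-facing coordinate conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple


class StructureError(ValueError):
    """Raised for unbalanced or ill-formed dot-bracket text."""


@dataclass(frozen=True)
class DotBracket:
    text: str
    pair_map: Tuple[Tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.text)

    def __str__(self) -> str:
        return self.text

    def pairs0(self) -> List[Tuple[int, int]]:
        """Pairs as 0-based (i, j) tuples, i < j."""
        return [(i - 1, j - 1) for i, j in self.pair_map]

    def partner_array(self) -> List[int]:
        """0-based partner index per position, -1 if unpaired."""
        partner = [-1] * len(self.text)
        for i, j in self.pairs0():
            partner[i] = j
            partner[j] = i
        return partner

    def is_unpaired(self, pos1: int) -> bool:
        """Whether 1-based position ``pos1`` is unpaired."""
        return self.text[pos1 - 1] == "."


def parse_dotbracket(text: str) -> DotBracket:
    """Parse dot-bracket text into a :class:`DotBracket`.

    Pairs are listed outermost-first in 5'-to-3' order of the opening
    bracket. Errors report the offending 1-based position.
    """
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for idx, ch in enumerate(text):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"unbalanced ')' at position {idx + 1}"
                )
            pairs.append((stack.pop() + 1, idx + 1))
        elif ch != ".":
            raise StructureError(
                f"illegal symbol {ch!r} at position {idx + 1}"
            )
    if stack:
        raise StructureError(
            f"unmatched '(' at position {stack[-1] + 1}"
        )
    pairs.sort()
    return DotBracket(text, tuple(pairs))


def from_pairs(length: int, pairs0: Iterable[Tuple[int, int]]) -> DotBracket:
    """Build a DotBracket from 0-based pairs; validates nesting."""
    chars = ["."] * length
    for i, j in pairs0:
        if not (0 <= i < j < length):
            raise StructureError(f"pair ({i}, {j}) out of bounds")
        if chars[i] != "." or chars[j] != ".":
            raise StructureError(f"position reused in pair ({i}, {j})")
        chars[i] = "("
        chars[j] = ")"
    return parse_dotbracket("".join(chars))


def write_ct(seq: str, db: DotBracket, name: str = "structure") -> str:
    """Render a connectivity-table (.ct) text block for a structure."""
    partner = db.partner_array()
    n = len(seq)
    lines = [f"{n} {name}"]
    for i in range(n):
        lines.append(
            f"{i + 1} {seq[i]} {i} {i + 2 if i + 1 < n else 0} "
            f"{partner[i] + 1} {i + 1}"
        )
    return "\n".join(lines) + "\n"
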