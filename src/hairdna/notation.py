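"""Forensic mtDNA difference notation.

Mitochondrial haplotypes are conventionally reported as a list of
differences from the rCRS (revised Cambridge Reference Sequence), e.g.
``263G`` for a substitution, ``315.1C`` for the first inserted base after
position 315, and ``16169Y`` for a mixed (point-heteroplasmic) position
rendered with an IUPAC ambiguity code.
"""

from __future__ import annotations

import re
from typing import Iterable, NamedTuple

#: IUPAC ambiguity code for an unordered pair of distinct bases.
IUPAC_TWO = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}

#: Reverse lookup: ambiguity code -> frozenset of the two bases it denotes.
IUPAC_TWO_INV = {v: k for k, v in IUPAC_TWO.items()}

_DIFF_RE = re.compile(r"^(\d+)(?:\.(\d+))?([ACGTMRWSYK-])$")


class Diff(NamedTuple):
    """One difference from the circular reference.

    ``rank`` 0 denotes a substitution (or deletion, base ``-``) at ``pos``;
    ``rank`` >= 1 denotes the rank-th base inserted after ``pos``.
    """

    pos: int
    rank: int
    base: str

    def __str__(self) -> str:
        if self.rank:
            return f"{self.pos}.{self.rank}{self.base}"
        return f"{self.pos}{self.base}"


def parse_diff(text: str) -> Diff:
    """Parse a single difference string such as ``263G`` or ``315.1C``."""
    m = _DIFF_RE.match(text.strip())
    if m is None:
        raise ValueError(f"unparseable haplotype difference: {text!r}")
    pos, rank, base = m.groups()
    return Diff(int(pos), int(rank) if rank else 0, base)


def parse_diffs(texts: Iterable[str]) -> list[Diff]:
    return [parse_diff(t) for t in texts]


def sort_key(diff: Diff) -> tuple[int, int]:
    return (diff.pos, diff.rank)
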