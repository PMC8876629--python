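"""Outward extension (decoration) of the two core stems.

Each core pair is grown into a helix by stacking contiguous complementary
pairs on the outside:

* stem 2 — pairs left-loop bases ``i2-1, i2-2, ...`` with downstream
  bases ``j2+1, j2+2, ...``;
* stem 1 — pairs upstream bases ``i1-1, i1-2, ...`` with right-loop
  bases ``j1+1, j1+2, ...``.

Extension stops at the first non-complementary pair or at a region
boundary (no bulges or interior loops).  The pairing predicate is
Watson-Crick, plus G-U wobble when ``allow_gu`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detect import PseudoknotCandidate, RnaSequence
from .grammar import is_gu, is_wc

Pair = tuple[int, int]


@dataclass(frozen=True)
class DecoratedStructure:
    candidate: PseudoknotCandidate
    #: stem-1 extensions (i1-k, j1+k), innermost first
    stem1_ext: tuple[Pair, ...] = field(default=())
    #: stem-2 extensions (i2-k, j2+k), innermost first
    stem2_ext: tuple[Pair, ...] = field(default=())

    @property
    def pair_count(self) -> int:
        return 2 + len(self.stem1_ext) + len(self.stem2_ext)

    @property
    def stem1_pairs(self) -> tuple[Pair, ...]:
        c = self.candidate
        return ((c.i1, c.j1),) + self.stem1_ext

    @property
    def stem2_pairs(self) -> tuple[Pair, ...]:
        c = self.candidate
        return ((c.i2, c.j2),) + self.stem2_ext

    @property
    def pairs(self) -> tuple[Pair, ...]:
        """All base pairs, stem 2 first (the order they are detected)."""
        return self.stem2_pairs + self.stem1_pairs

    @property
    def paired_positions(self) -> set[int]:
        return {p for pair in self.pairs for p in pair}


def _pairs_ok(a: str, b: str, allow_gu: bool) -> bool:
    return is_wc(a, b) or (allow_gu and is_gu(a, b))


def decorate(
    seq: RnaSequence,
    cand: PseudoknotCandidate,
    allow_gu: bool = False,
    max_dd: int = 2,
    min_loop: int = 0,
) -> DecoratedStructure:
    """Greedily extend both core stems of ``cand`` outward.

    ``min_loop`` reserves that many unpaired bases in each loop (default
    0: loops may be consumed entirely by the extensions).
    """
    cand.validate(seq, max_dd)
    i1, i2, j1, j2 = cand.i1, cand.i2, cand.j1, cand.j2
    n = seq.n

    # stem 2: left halves stay inside the left loop (i1, i2),
    # right halves run past j2 to the end of the sequence
    stem2_ext: list[Pair] = []
    left_budget = (i2 - i1 - 1) - min_loop
    for k in range(1, left_budget + 1):
        lo, hi = i2 - k, j2 + k
        if lo <= i1 or hi > n:
            break
        if not _pairs_ok(seq.base(lo), seq.base(hi), allow_gu):
            break
        stem2_ext.append((lo, hi))

    # stem 1: left halves run before i1, right halves stay inside the
    # right loop (j1, j2)
    stem1_ext: list[Pair] = []
    right_budget = (j2 - j1 - 1) - min_loop
    for k in range(1, right_budget + 1):
        lo, hi = i1 - k, j1 + k
        if lo < 1 or hi >= j2:
            break
        if not _pairs_ok(seq.base(lo), seq.base(hi), allow_gu):
            break
        stem1_ext.append((lo, hi))

    return DecoratedStructure(
        candidate=cand,
        stem1_ext=tuple(stem1_ext),
        stem2_ext=tuple(stem2_ext),
    )


def to_dotbracket(seq: RnaSequence, dec: DecoratedStructure) -> str:
    """Render as extended dot-bracket: stem 1 = ``[ ]``, stem 2 = ``( )``."""
    out = ["."] * seq.n
    for (lo, hi) in dec.stem1_pairs:
        out[lo - 1], out[hi - 1] = "[", "]"
    for (lo, hi) in dec.stem2_pairs:
        out[lo - 1], out[hi - 1] = "(", ")"
    return "".join(out)
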