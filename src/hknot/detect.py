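"""Enumeration of H-type pseudoknot core-stem candidates.

Two interchangeable engines are provided:

* :func:`detect_grammar` — parses every substring of the sequence with the
  Earley engine and maps each derivation to full-sequence coordinates.
  One chart per start position suffices: an Earley chart for the suffix
  ``seq[a:]`` certifies every accepted prefix of that suffix, i.e. every
  window ``[a, b]``.
* :func:`detect_bruteforce` — directly enumerates position quadruples
  satisfying the candidate invariants.

Both must produce identical, canonically sorted candidate lists; the
test suite enforces this cross-oracle property.

Coordinates are 1-based inclusive throughout the public surface.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from joblib import Parallel, delayed

from . import earley
from .grammar import PseudoknotGrammar, build_grammar, core_stem_letter_pairs, is_wc

#: minimum derivable pseudoknot length: x + l1(>=1) + y + z + l2(>=1) + w
MIN_WINDOW = 6

_VALID = re.compile(r"^[ACGU]*$")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U}.

    Lowercase input and DNA-style ``T`` are normalised (with a warning);
    any other character raises :class:`ValueError`.
    """

    seq_id: str
    bases: str

    def __post_init__(self) -> None:
        normalized = self.bases.upper().replace("T", "U")
        if normalized != self.bases:
            warnings.warn(
                f"sequence {self.seq_id!r}: normalised to uppercase A/C/G/U",
                stacklevel=3,
            )
            object.__setattr__(self, "bases", normalized)
        if not _VALID.match(self.bases):
            bad = next(i for i, c in enumerate(self.bases) if c not in "ACGU")
            raise ValueError(
                f"sequence {self.seq_id!r}: invalid character "
                f"{self.bases[bad]!r} at position {bad + 1}"
            )

    @property
    def n(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.bases[pos - 1]


@dataclass(frozen=True, order=True)
class PseudoknotCandidate:
    """Core-stem quadruple: pairs (i1, j1) and (i2, j2), 1-based inclusive.

    The (i2, j2) stem crosses the (i1, j1) stem: i1 < i2 < j1 < j2.
    """

    i1: int
    i2: int
    j1: int
    j2: int
    rule_id: int
    seq_id: str = ""

    def validate(self, seq: RnaSequence, max_dd: int) -> None:
        if not (1 <= self.i1 < self.i2 < self.j1 < self.j2 <= seq.n):
            raise ValueError(f"candidate positions out of order/bounds: {self}")
        if self.i2 - self.i1 - 1 < 1:
            raise ValueError(f"left loop empty: {self}")
        if self.j2 - self.j1 - 1 < 1:
            raise ValueError(f"right loop empty: {self}")
        gap = self.j1 - self.i2 - 1
        if not (0 <= gap <= max_dd):
            raise ValueError(f"gap length {gap} outside [0, {max_dd}]: {self}")
        if not is_wc(seq.base(self.i1), seq.base(self.j1)):
            raise ValueError(f"stem 1 not Watson-Crick: {self}")
        if not is_wc(seq.base(self.i2), seq.base(self.j2)):
            raise ValueError(f"stem 2 not Watson-Crick: {self}")

    @property
    def sort_key(self) -> tuple:
        return (self.i1, self.i2, self.j1, self.j2, self.rule_id)


def _canonical(cands: list[PseudoknotCandidate]) -> list[PseudoknotCandidate]:
    uniq = {(c.i1, c.i2, c.j1, c.j2): c for c in cands}
    return sorted(uniq.values(), key=lambda c: c.sort_key)


def _grammar_for(max_dd: int) -> PseudoknotGrammar:
    return build_grammar(max_dd)


def _windows_from_start(
    seq: RnaSequence,
    grammar: PseudoknotGrammar,
    start: int,
    min_window: int,
) -> list[PseudoknotCandidate]:
    """Candidates for all windows [start, b], 0-based start; one chart."""
    suffix = seq.bases[start:]
    if len(suffix) < min_window:
        return []
    chart = earley.earley_parse(grammar, suffix)
    by_end = earley.extract_prefix_splits(grammar, suffix, chart)
    out = []
    for end, splits in by_end.items():
        if end < min_window:
            continue
        for (rule_id, l1, d) in splits:
            # local 1-based: x at 1, y at 2+l1, z at 3+l1+d, w at end
            out.append(
                PseudoknotCandidate(
                    i1=start + 1,
                    i2=start + 2 + l1,
                    j1=start + 3 + l1 + d,
                    j2=start + end,
                    rule_id=rule_id,
                    seq_id=seq.seq_id,
                )
            )
    return out


def detect_grammar(
    seq: RnaSequence, max_dd: int = 2, min_window: int = MIN_WINDOW
) -> list[PseudoknotCandidate]:
    """Sliding-window grammar engine.

    Every substring of length >= ``min_window`` is parsed; every
    derivation becomes one candidate in full-sequence coordinates.
    """
    if min_window < MIN_WINDOW:
        raise ValueError(f"min_window must be >= {MIN_WINDOW}")
    grammar = _grammar_for(max_dd)
    cands: list[PseudoknotCandidate] = []
    for start in range(seq.n):
        cands.extend(_windows_from_start(seq, grammar, start, min_window))
    return _canonical(cands)


def detect_bruteforce(
    seq: RnaSequence, max_dd: int = 2, min_window: int = MIN_WINDOW
) -> list[PseudoknotCandidate]:
    """Direct quadruple enumeration engine.

    Spots all Watson-Crick pairs, then all crossing couples whose loop
    and gap lengths satisfy the candidate invariants.
    """
    grammar = _grammar_for(max_dd)
    rid_table = {
        letters: rule.id
        for rule, letters in zip(grammar.s_rules, core_stem_letter_pairs(grammar))
    }
    b = seq.bases
    n = seq.n
    cands: list[PseudoknotCandidate] = []
    for i1 in range(1, n + 1):
        for i2 in range(i1 + 2, n + 1):  # left loop >= 1
            for j1 in range(i2 + 1, min(i2 + 1 + max_dd, n) + 1):  # gap <= max_dd
                if not is_wc(b[i1 - 1], b[j1 - 1]):
                    continue
                for j2 in range(j1 + 2, n + 1):  # right loop >= 1
                    if not is_wc(b[i2 - 1], b[j2 - 1]):
                        continue
                    if j2 - i1 + 1 < min_window:
                        continue
                    rid = rid_table[(b[i1 - 1], b[i2 - 1], b[j1 - 1], b[j2 - 1])]
                    cands.append(
                        PseudoknotCandidate(
                            i1=i1, i2=i2, j1=j1, j2=j2,
                            rule_id=rid, seq_id=seq.seq_id,
                        )
                    )
    return _canonical(cands)


def detect_parallel(
    seq: RnaSequence,
    max_dd: int = 2,
    min_window: int = MIN_WINDOW,
    workers: int = 1,
) -> list[PseudoknotCandidate]:
    """Grammar engine with window starts fanned out over worker processes.

    Output is bit-identical to :func:`detect_grammar` for any worker
    count: windows are independent and results are canonically sorted
    after the join.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if min_window < MIN_WINDOW:
        raise ValueError(f"min_window must be >= {MIN_WINDOW}")
    if workers == 1 or seq.n < 2 * min_window:
        return detect_grammar(seq, max_dd, min_window)
    grammar = _grammar_for(max_dd)
    chunks = Parallel(n_jobs=workers)(
        delayed(_windows_from_start)(seq, grammar, start, min_window)
        for start in range(seq.n)
    )
    cands = [c for chunk in chunks for c in chunk]
    return _canonical(cands)


def detect(
    seq: RnaSequence,
    engine: str = "bruteforce",
    max_dd: int = 2,
    min_window: int = MIN_WINDOW,
    workers: int = 1,
) -> list[PseudoknotCandidate]:
    """Engine dispatch used by the prediction pipeline and the CLI."""
    if engine == "bruteforce":
        return detect_bruteforce(seq, max_dd, min_window)
    if engine == "grammar":
        if workers > 1:
            return detect_parallel(seq, max_dd, min_window, workers)
        return detect_grammar(seq, max_dd, min_window)
    raise ValueError(f"unknown engine {engine!r} (use 'grammar' or 'bruteforce')")
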