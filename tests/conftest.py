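"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive language membership and derivation splits by
direct decomposition of the target shape ``x l1 y d z l2 w`` — they never
touch the grammar/parser code paths they are used to check.
"""

from __future__ import annotations

import pytest

from hknot.detect import RnaSequence

# Watson-Crick pairs, written out independently of hknot.grammar
WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}

#: the 19-nt worked-example sequence
WORKED_SEQ = "CCAUCGCCUGAUUUGAGGA"
WORKED_FINAL_DB = "..[[[.(((]]]...)))."
WORKED_CORE_DB = "....[...(].....)..."

#: the 12-nt substring with the rule-6 parse
WORKED_SUBSTR = "CGCCUGAUUUGA"


def oracle_splits(s: str, max_dd: int) -> set[tuple[str, str, str, str, int, int]]:
    """All decompositions x·l1·y·d·z·l2·w of ``s``, by exhaustive scan.

    Returns (x, y, z, w, l1_len, d_len) tuples; (x,z) and (y,w) must be
    Watson-Crick, both loops nonempty, gap length at most ``max_dd``.
    """
    n = len(s)
    out = set()
    for l1 in range(1, n):
        for d in range(0, max_dd + 1):
            l2 = n - 4 - l1 - d
            if l2 < 1:
                continue
            x, y = s[0], s[1 + l1]
            z, w = s[2 + l1 + d], s[n - 1]
            if (x, z) in WC and (y, w) in WC:
                out.add((x, y, z, w, l1, d))
    return out


def oracle_member(s: str, max_dd: int) -> bool:
    return len(s) >= 6 and bool(oracle_splits(s, max_dd))


def oracle_candidates(bases: str, max_dd: int) -> set[tuple[int, int, int, int]]:
    """All core-stem quadruples (1-based) of a full sequence, windows included."""
    n = len(bases)
    out = set()
    for a in range(n):
        for b in range(a + 5, n):
            for (_, _, _, _, l1, d) in oracle_splits(bases[a:b + 1], max_dd):
                out.add((a + 1, a + 2 + l1, a + 3 + l1 + d, b + 1))
    return out


@pytest.fixture(scope="session")
def grammar2():
    from hknot.grammar import build_grammar

    return build_grammar(2)


@pytest.fixture()
def worked_seq() -> RnaSequence:
    return RnaSequence(seq_id="worked", bases=WORKED_SEQ)
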