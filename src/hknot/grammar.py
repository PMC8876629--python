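"""Context-free grammar describing the core stems of an H-type pseudoknot.

The grammar recognises strings of the shape ``x l1 y d z l2 w`` where
``(x, z)`` and ``(y, w)`` are Watson-Crick pairs (the two crossing *core
stems*), ``l1``/``l2`` are nonempty loop runs and ``d`` is a bounded gap of
0..max_dd bases between the two inner stem halves.  One start rule exists
per ordered combination of the four Watson-Crick letter pairs, 16 in all.

The rule set is stored as plain data so that other engines (brute force,
tests) can introspect it rather than re-encode it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

TERMINALS = ("A", "C", "G", "U")

#: Watson-Crick letter pairs in canonical rule order.
WC_PAIRS = (("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"))

WC_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

START = "Start"  # augmented start used by the parser
S, L, D = "S", "L", "D"

#: Names for the optional-gap chain nonterminals; the first two match the
#: published two-base-gap rule table, further ones are synthesised.
_GAP_NAMES = ("K", "N")


def is_wc(a: str, b: str) -> bool:
    """True iff (a, b) is a Watson-Crick pair."""
    return WC_COMPLEMENT.get(a) == b


def is_gu(a: str, b: str) -> bool:
    """True iff (a, b) is a G-U wobble pair (either orientation)."""
    return (a, b) in (("G", "U"), ("U", "G"))


@dataclass(frozen=True)
class Symbol:
    """Terminal or nonterminal grammar symbol."""

    name: str
    is_terminal: bool

    def __repr__(self) -> str:  # compact for chart dumps
        return f'"{self.name}"' if self.is_terminal else self.name


def t(name: str) -> Symbol:
    if name not in TERMINALS:
        raise ValueError(f"not a terminal: {name!r}")
    return Symbol(name, True)


def nt(name: str) -> Symbol:
    return Symbol(name, False)


@dataclass(frozen=True)
class GrammarRule:
    """Production ``lhs -> rhs`` with a dense integer id."""

    id: int
    lhs: str
    rhs: tuple[Symbol, ...]

    def __str__(self) -> str:
        body = " ".join(repr(s) for s in self.rhs) if self.rhs else "ε"
        return f"{self.id}: {self.lhs} -> {body}"


@dataclass
class PseudoknotGrammar:
    """The full rule table, parameterised by the maximum inter-stem gap."""

    rules: list[GrammarRule]
    max_dd: int
    start: str = S
    _by_lhs: dict[str, list[GrammarRule]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for rule in self.rules:
            self._by_lhs.setdefault(rule.lhs, []).append(rule)

    @property
    def s_rules(self) -> list[GrammarRule]:
        return self._by_lhs[S]

    def rules_for(self, lhs: str) -> list[GrammarRule]:
        return self._by_lhs.get(lhs, [])

    @property
    def nonterminals(self) -> set[str]:
        return set(self._by_lhs)

    def nullable(self) -> set[str]:
        """Nonterminals that derive the empty string (fixpoint computation)."""
        out: set[str] = set()
        changed = True
        while changed:
            changed = False
            for rule in self.rules:
                if rule.lhs in out:
                    continue
                if all((not s.is_terminal) and s.name in out for s in rule.rhs):
                    out.add(rule.lhs)
                    changed = True
        return out

    def dump(self) -> str:
        """One rule per line, in the published table notation."""
        return "\n".join(str(r) for r in self.rules)


def build_grammar(max_dd: int) -> PseudoknotGrammar:
    """Build the pseudoknot core-stem grammar for a given maximum gap.

    Parameters
    ----------
    max_dd
        Maximum number of bases derivable from the gap nonterminal ``D``
        (the bases between the two inner core-stem halves).  ``max_dd = 2``
        reproduces the published 35-rule table.
    """
    if max_dd < 0:
        raise ValueError(f"max_dd must be >= 0, got {max_dd}")

    rules: list[GrammarRule] = []
    rid = 0

    # 16 start rules: S -> x L y D z L w, one per ordered WC pair combination.
    for y, w in WC_PAIRS:
        for x, z in WC_PAIRS:
            rhs = (t(x), nt(L), t(y), nt(D), t(z), nt(L), t(w))
            rules.append(GrammarRule(rid, S, rhs))
            rid += 1

    # Loops: L derives every nonempty terminal string.
    for a in TERMINALS:
        rules.append(GrammarRule(rid, L, (t(a), nt(L))))
        rid += 1
    for a in TERMINALS:
        rules.append(GrammarRule(rid, L, (t(a),)))
        rid += 1

    # Gap: D -> G1 G2 ... G_max_dd, each Gi optional-terminal, so D derives
    # exactly the terminal strings of length 0..max_dd.
    gap_names = [
        _GAP_NAMES[i] if i < len(_GAP_NAMES) else f"D{i + 1}" for i in range(max_dd)
    ]
    rules.append(GrammarRule(rid, D, tuple(nt(g) for g in gap_names)))
    rid += 1
    for g in gap_names:
        for a in TERMINALS:
            rules.append(GrammarRule(rid, g, (t(a),)))
            rid += 1
        rules.append(GrammarRule(rid, g, ()))
        rid += 1

    return PseudoknotGrammar(rules=rules, max_dd=max_dd)


def core_stem_letter_pairs(grammar: PseudoknotGrammar) -> list[tuple[str, str, str, str]]:
    """The (x, y, z, w) terminal letters of each start rule, in rule-id order."""
    out = []
    for rule in grammar.s_rules:
        x, _, y, _, z, _, w = rule.rhs
        out.append((x.name, y.name, z.name, w.name))
    return out


def rule_id_for_bases(grammar: PseudoknotGrammar, x: str, y: str, z: str, w: str) -> int:
    """Start-rule id whose core-stem letters are (x, y, z, w); KeyError if none."""
    table = {letters: rule.id for rule, letters in
             zip(grammar.s_rules, core_stem_letter_pairs(grammar))}
    return table[(x, y, z, w)]


def iter_gap_strings(max_dd: int) -> Iterator[str]:
    """All terminal strings derivable from D, i.e. lengths 0..max_dd."""
    from itertools import product

    for n in range(max_dd + 1):
        for combo in product(TERMINALS, repeat=n):
            yield "".join(combo)
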