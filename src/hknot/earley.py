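"""Chart-based Earley parser for the (ambiguous) pseudoknot grammar.

States are ``(rule_id, dot, origin)`` triples.  The chart holds one state
set per input position; sets only grow while the Predictor / Scanner /
Completer loop runs, and membership is keyed on the full triple so the
loop terminates.

Empty-string rules (the optional gap symbols) are handled with the
Aycock-Horspool refinement: when the Predictor meets a nullable
nonterminal it also advances the dot over it immediately, which closes
the same-set completion hole of the textbook algorithm.

The parser is generic over the rule table, but derivation extraction
(:func:`extract_splits`) is specific to the seven-symbol start rules:
for this grammar a parse tree is fully identified by the start rule used
and the lengths of the first loop and of the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grammar import START, TERMINALS, PseudoknotGrammar

#: rule id of the synthetic augmented rule Start -> S
AUGMENTED_RULE_ID = -1

State = tuple[int, int, int]  # (rule_id, dot, origin)


class InputAlphabetError(ValueError):
    """Input contains a character outside {A, C, G, U}."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 0-based
        super().__init__(
            f"invalid character {char!r} at position {position + 1} "
            f"(alphabet is A/C/G/U)"
        )


@dataclass
class _StateSet:
    order: list[State] = field(default_factory=list)
    seen: set[State] = field(default_factory=set)
    #: states in this set whose dot precedes a given nonterminal
    wants: dict[str, list[State]] = field(default_factory=dict)
    predicted: set[str] = field(default_factory=set)

    def add(self, state: State) -> None:
        if state not in self.seen:
            self.seen.add(state)
            self.order.append(state)


@dataclass
class Chart:
    """Earley chart: ``n + 1`` state sets for an input of length ``n``."""

    sets: list[_StateSet]
    grammar: PseudoknotGrammar
    input: str

    def __len__(self) -> int:
        return len(self.sets)

    def contains(self, i: int, state: State) -> bool:
        return state in self.sets[i].seen

    def accepted_prefix(self, k: int) -> bool:
        """True iff the length-``k`` prefix of the input is in the language."""
        return (AUGMENTED_RULE_ID, 1, 0) in self.sets[k].seen

    @property
    def accepted(self) -> bool:
        return self.accepted_prefix(len(self.input))

    def dump(self) -> str:
        """One state per line: ``i: F rule_id dot``."""
        lines = []
        for i, ss in enumerate(self.sets):
            for (rid, dot, origin) in ss.order:
                lines.append(f"{i}: {origin} {rid} {dot}")
        return "\n".join(lines)


def _validate_input(s: str) -> None:
    for pos, ch in enumerate(s):
        if ch not in TERMINALS:
            raise InputAlphabetError(ch, pos)


def earley_parse(grammar: PseudoknotGrammar, s: str) -> Chart:
    """Run the Earley algorithm and return the completed chart."""
    _validate_input(s)
    n = len(s)

    rule_rhs: dict[int, tuple] = {r.id: r.rhs for r in grammar.rules}
    rule_lhs: dict[int, str] = {r.id: r.lhs for r in grammar.rules}
    # augmented start rule Start -> S
    start_sym = grammar.rules_for(grammar.start)[0].lhs
    from .grammar import Symbol

    rule_rhs[AUGMENTED_RULE_ID] = (Symbol(start_sym, False),)
    rule_lhs[AUGMENTED_RULE_ID] = START

    nullable = grammar.nullable()
    sets = [_StateSet() for _ in range(n + 1)]
    sets[0].add((AUGMENTED_RULE_ID, 0, 0))

    for i in range(n + 1):
        ss = sets[i]
        pos = 0
        while pos < len(ss.order):
            state = ss.order[pos]
            pos += 1
            rid, dot, origin = state
            rhs = rule_rhs[rid]
            if dot < len(rhs):
                sym = rhs[dot]
                if sym.is_terminal:
                    # Scanner
                    if i < n and s[i] == sym.name:
                        sets[i + 1].add((rid, dot + 1, origin))
                else:
                    # Predictor
                    b = sym.name
                    ss.wants.setdefault(b, []).append(state)
                    if b in nullable:
                        ss.add((rid, dot + 1, origin))
                    if b not in ss.predicted:
                        ss.predicted.add(b)
                        for rule in grammar.rules_for(b):
                            ss.add((rule.id, 0, i))
            else:
                # Completer
                lhs = rule_lhs[rid]
                for (rid2, dot2, origin2) in sets[origin].wants.get(lhs, ()):
                    ss.add((rid2, dot2 + 1, origin2))

    return Chart(sets=sets, grammar=grammar, input=s)


def recognize(grammar: PseudoknotGrammar, s: str) -> bool:
    """True iff ``s`` is derivable from the grammar's start symbol."""
    if len(s) == 0:
        return False
    return earley_parse(grammar, s).accepted


Split = tuple[int, int, int]  # (rule_id, l1_len, d_len)


def extract_splits(
    grammar: PseudoknotGrammar, s: str, chart: Chart, end: int | None = None
) -> set[Split]:
    """All derivations of ``s[:end]``, as ``(rule_id, l1_len, d_len)`` triples.

    For the start rules ``S -> x L y D z L w`` the second loop length is
    implied by the total length, so the triple identifies a parse tree
    uniquely.  Returns the empty set when the (prefix of the) input is
    not accepted.
    """
    if end is None:
        end = len(s)
    return extract_prefix_splits(grammar, s, chart).get(end, set())


def extract_prefix_splits(
    grammar: PseudoknotGrammar, s: str, chart: Chart
) -> dict[int, set[Split]]:
    """Derivations of every accepted prefix, keyed by prefix length.

    A start-rule state with origin 0 and the dot after ``y`` pins the
    first loop length; the dot after ``z`` pins the gap length; the
    completed rule at a prefix boundary certifies the full derivation.
    Enumerating consistent combinations of those chart states yields
    exactly the set of parse trees.
    """
    s_ids = {r.id for r in grammar.s_rules}
    # positions of key dotted states per start rule, origin 0 only
    after_y: dict[int, set[int]] = {rid: set() for rid in s_ids}  # dot == 3
    after_z: dict[int, set[int]] = {rid: set() for rid in s_ids}  # dot == 5
    done: dict[int, set[int]] = {rid: set() for rid in s_ids}  # dot == 7
    for i, ss in enumerate(chart.sets):
        for (rid, dot, origin) in ss.order:
            if origin == 0 and rid in s_ids:
                if dot == 3:
                    after_y[rid].add(i)
                elif dot == 5:
                    after_z[rid].add(i)
                elif dot == 7:
                    done[rid].add(i)

    out: dict[int, set[Split]] = {}
    for rid in s_ids:
        for end in done[rid]:
            for k in after_y[rid]:  # k = 2 + l1
                l1 = k - 2
                if l1 < 1:
                    continue
                for d in range(grammar.max_dd + 1):
                    # x(1) l1(l1) y(1) d(d) z(1) l2 w(1) spans `end` symbols
                    l2 = end - 4 - l1 - d
                    if l2 < 1:
                        continue
                    if (3 + l1 + d) in after_z[rid]:
                        out.setdefault(end, set()).add((rid, l1, d))
    return out
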