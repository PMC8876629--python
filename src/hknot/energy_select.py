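"""Pseudoknot energy scoring and optimal-structure selection.

The energy of a decorated pseudoknot is the linear form

    g_pseudo = beta1 + beta2 * Bp + beta3 * Up

where ``Bp`` is the number of core stems (2 for H-type; a config switch
allows counting all base pairs instead) and ``Up`` the number of unpaired
bases strictly inside the outermost paired span.  Selection is hybrid:
maximise the pair count first, then minimise the energy over the
top-ranked subset only, with a deterministic positional tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .decorate import DecoratedStructure, decorate, to_dotbracket
from .detect import MIN_WINDOW, PseudoknotCandidate, RnaSequence, detect

#: adjacency-keyed stacking energies: ((b5, b3), (b5', b3')) -> energy
StackTable = Mapping[tuple[tuple[str, str], tuple[str, str]], float]


@dataclass(frozen=True)
class EnergyParams:
    """Weights of the pseudoknot energy model."""

    beta1: float = 9.6  # existence of the pseudoknot
    beta2: float = 0.1  # per core stem
    beta3: float = 0.1  # per unpaired base inside the span
    stack_table: StackTable | None = None
    #: "core_stems" counts Bp = 2; "pairs" counts every base pair
    bp_mode: str = "core_stems"


@dataclass(frozen=True)
class ScoredStructure:
    dec: DecoratedStructure
    bp: int
    up: int
    g_pseudo: float
    stack_energy: float = 0.0

    @property
    def pair_count(self) -> int:
        return self.dec.pair_count


def _stack_energy(seq: RnaSequence, dec: DecoratedStructure, table: StackTable) -> float:
    """Sum of stacking terms over consecutive pairs within each stem."""
    total = 0.0
    for stem in (dec.stem1_pairs, dec.stem2_pairs):
        ordered = sorted(stem)  # outermost (smallest left index) first
        for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
            outer = (seq.base(lo1), seq.base(hi1))
            inner = (seq.base(lo2), seq.base(hi2))
            total += table.get((outer, inner), 0.0)
    return total


def pseudoknot_energy(
    dec: DecoratedStructure,
    params: EnergyParams = EnergyParams(),
    seq: RnaSequence | None = None,
) -> ScoredStructure:
    """Score a decorated structure; ``seq`` is only needed for stacking."""
    paired = dec.paired_positions
    span_lo, span_hi = min(paired), max(paired)
    up = sum(1 for p in range(span_lo + 1, span_hi) if p not in paired)
    bp = dec.pair_count if params.bp_mode == "pairs" else 2
    stack = 0.0
    if params.stack_table is not None:
        if seq is None:
            raise ValueError("stacking energies require the sequence")
        stack = _stack_energy(seq, dec, params.stack_table)
    g = params.beta1 + params.beta2 * bp + params.beta3 * up + stack
    return ScoredStructure(dec=dec, bp=bp, up=up, g_pseudo=g, stack_energy=stack)


def _tiebreak(s: ScoredStructure) -> tuple:
    c = s.dec.candidate
    return (s.g_pseudo, c.i1, c.j2, c.i2)


def select_best(scored: Sequence[ScoredStructure]) -> ScoredStructure | None:
    """Maximum pair count, then minimum energy, then positional tie-break.

    Returns ``None`` for an empty list ("no pseudoknot found").
    """
    if not scored:
        return None
    top = max(s.pair_count for s in scored)
    finalists = [s for s in scored if s.pair_count == top]
    return min(finalists, key=_tiebreak)


@dataclass(frozen=True)
class PredictConfig:
    engine: str = "bruteforce"
    max_dd: int = 2
    min_window: int = MIN_WINDOW
    allow_gu: bool = False
    min_loop: int = 0
    workers: int = 1
    energy: EnergyParams = field(default_factory=EnergyParams)


@dataclass(frozen=True)
class Prediction:
    seq_id: str
    dot_bracket: str
    candidate: PseudoknotCandidate | None
    scored: ScoredStructure | None
    #: every decorated candidate, for CSV dumps (scored lazily; only the
    #: maximal-pair subset carries an energy)
    all_scored: tuple[ScoredStructure, ...] = ()

    @property
    def found(self) -> bool:
        return self.candidate is not None


def predict(seq: RnaSequence, config: PredictConfig = PredictConfig()) -> Prediction:
    """End-to-end pipeline: detect, decorate, score, select, render."""
    cands = detect(
        seq,
        engine=config.engine,
        max_dd=config.max_dd,
        min_window=config.min_window,
        workers=config.workers,
    )
    decs = [
        decorate(seq, c, allow_gu=config.allow_gu,
                 max_dd=config.max_dd, min_loop=config.min_loop)
        for c in cands
    ]
    if not decs:
        return Prediction(seq.seq_id, "." * seq.n, None, None)

    # energy is evaluated only for the maximal-pair subset
    top = max(d.pair_count for d in decs)
    scored = [
        pseudoknot_energy(d, config.energy, seq)
        for d in decs
        if d.pair_count == top
    ]
    best = select_best(scored)
    assert best is not None
    return Prediction(
        seq_id=seq.seq_id,
        dot_bracket=to_dotbracket(seq, best.dec),
        candidate=best.dec.candidate,
        scored=best,
        all_scored=tuple(scored),
    )
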