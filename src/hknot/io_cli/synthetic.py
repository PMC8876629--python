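"""Seeded generator of sequences with one planted H-type pseudoknot.

The planted layout, 5' to 3':

    [flank5][stem1][loop1][stem2][gap][stem1'][loop2][stem2'][flank3]

where ``stem1'``/``stem2'`` are reverse complements of ``stem1``/``stem2``.
The innermost pair of each stem is the core candidate; the remaining
pairs are exactly what outward decoration recovers.

Random context (loops, gap, flanks) is rejection-sampled until the
planted structure is the unique maximal-pair candidate and decoration of
the planted core reproduces the planted pairs exactly — so a correct
pipeline must recover the ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from ..decorate import decorate, to_dotbracket
from ..detect import PseudoknotCandidate, RnaSequence, detect_bruteforce
from ..grammar import TERMINALS, WC_COMPLEMENT


class GenerationError(RuntimeError):
    """Rejection sampling exhausted without a valid fixture."""


@dataclass(frozen=True)
class PlantSpec:
    stem1_len: int = 3
    stem2_len: int = 3
    loop1_len: int = 1
    loop2_len: int = 3
    gap_len: int = 0
    flank5_len: int = 2
    flank3_len: int = 1
    max_dd: int = 2
    seed: int = 0
    max_tries: int = 500

    def validate(self) -> None:
        if min(self.stem1_len, self.stem2_len, self.loop1_len, self.loop2_len) < 1:
            raise ValueError("stem and loop lengths must be >= 1")
        if not (0 <= self.gap_len <= self.max_dd):
            raise ValueError(f"gap_len must be in [0, {self.max_dd}]")
        if min(self.flank5_len, self.flank3_len) < 0:
            raise ValueError("flank lengths must be >= 0")


@dataclass(frozen=True)
class PlantedFixture:
    sequence: RnaSequence
    dot_bracket: str
    core: PseudoknotCandidate

    def __iter__(self):
        # allows `seq, db = generate_planted(spec)`
        return iter((self.sequence, self.dot_bracket))


def _revcomp(s: str) -> str:
    return "".join(WC_COMPLEMENT[c] for c in reversed(s))


def _assemble(spec: PlantSpec, rng: random.Random) -> tuple[str, str, PseudoknotCandidate]:
    draw = lambda k: "".join(rng.choice(TERMINALS) for _ in range(k))  # noqa: E731
    stem1, stem2 = draw(spec.stem1_len), draw(spec.stem2_len)
    parts = [
        draw(spec.flank5_len),
        stem1,
        draw(spec.loop1_len),
        stem2,
        draw(spec.gap_len),
        _revcomp(stem1),
        draw(spec.loop2_len),
        _revcomp(stem2),
        draw(spec.flank3_len),
    ]
    seq = "".join(parts)

    s1, s2 = spec.stem1_len, spec.stem2_len
    off = [0]
    for p in parts:
        off.append(off[-1] + len(p))
    # innermost pair of each stem (1-based)
    i1 = off[2]              # last base of stem1 block
    i2 = off[4]              # last base of stem2 block
    j1 = off[5] + 1          # first base of stem1' block
    j2 = off[7] + 1          # first base of stem2' block
    core = PseudoknotCandidate(i1=i1, i2=i2, j1=j1, j2=j2, rule_id=-1)

    db = ["."] * len(seq)
    for k in range(s1):
        db[off[1] + k] = "["
        db[off[5] + k] = "]"
    for k in range(s2):
        db[off[3] + k] = "("
        db[off[7] + k] = ")"
    return seq, "".join(db), core


def generate_planted(spec: PlantSpec, seq_id: str = "planted") -> PlantedFixture:
    """Generate one fixture; reproducible for a fixed ``spec.seed``."""
    spec.validate()
    rng = random.Random(spec.seed)

    for _ in range(spec.max_tries):
        bases, db, core = _assemble(spec, rng)
        seq = RnaSequence(seq_id=seq_id, bases=bases)

        cands = detect_bruteforce(seq, max_dd=spec.max_dd)
        planted = [
            c for c in cands
            if (c.i1, c.i2, c.j1, c.j2) == (core.i1, core.i2, core.j1, core.j2)
        ]
        if not planted:
            continue  # planted core needs loop >= 1 etc.; should not happen
        planted_cand = planted[0]
        dec = decorate(seq, planted_cand, max_dd=spec.max_dd)
        if to_dotbracket(seq, dec) != db:
            continue  # decoration over- or under-shot the planted stems
        target = dec.pair_count
        unique_max = all(
            decorate(seq, c, max_dd=spec.max_dd).pair_count < target
            for c in cands
            if c is not planted_cand
        )
        if unique_max:
            return PlantedFixture(sequence=seq, dot_bracket=db, core=planted_cand)

    raise GenerationError(
        f"no valid fixture after {spec.max_tries} tries for {spec}"
    )
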