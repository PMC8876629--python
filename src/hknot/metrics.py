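"""Evaluation toolkit: per-base confusion counts, PPV/recall/F1/MCC and
core-stem exact matching with one-position slippage.

The classification unit is the base, not the pair: a position counts as a
true positive when it is paired in both prediction and reference (strict
mode additionally requires the same partner).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .detect import PseudoknotCandidate

_OPEN = {"(": ")", "[": "]"}
_CLOSE = {v: k for k, v in _OPEN.items()}


def parse_dotbracket(db: str) -> dict[int, int]:
    """Pair map (1-based, both directions) of a two-layer dot-bracket string."""
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    pairs: dict[int, int] = {}
    for pos, ch in enumerate(db, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[ch].append(pos)
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            if not stacks[opener]:
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            lo = stacks[opener].pop()
            pairs[lo] = pos
            pairs[pos] = lo
        else:
            raise ValueError(f"invalid structure character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced {opener!r} at position {stack[-1]}")
    return pairs


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    ppv: float
    recall: float
    f1: float
    mcc: float
    #: names of metrics whose denominator was zero (reported as 0)
    degenerate: tuple[str, ...] = ()


def confusion(pred_db: str, ref_db: str, strict_partners: bool = False) -> ConfusionCounts:
    """Per-base confusion counts between two dot-bracket strings."""
    if len(pred_db) != len(ref_db):
        raise ValueError(
            f"length mismatch: prediction {len(pred_db)} vs reference {len(ref_db)}"
        )
    pred = parse_dotbracket(pred_db)
    ref = parse_dotbracket(ref_db)
    tp = tn = fp = fn = 0
    for pos in range(1, len(ref_db) + 1):
        in_pred = pos in pred
        in_ref = pos in ref
        if in_pred and in_ref:
            if strict_partners and pred[pos] != ref[pos]:
                fp += 1  # paired, but to the wrong partner
            else:
                tp += 1
        elif in_pred:
            fp += 1
        elif in_ref:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def score(c: ConfusionCounts) -> Metrics:
    """PPV, recall, F1 and MCC from raw counts; zero denominators give 0."""
    degenerate: list[str] = []

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    ppv = ratio("ppv", c.tp, c.tp + c.fp)
    recall = ratio("recall", c.tp, c.tp + c.fn)
    f1 = ratio("f1", 2 * ppv * recall, ppv + recall)
    mcc_den = math.sqrt(
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = ratio("mcc", c.tp * c.tn - c.fp * c.fn, mcc_den)
    return Metrics(ppv=ppv, recall=recall, f1=f1, mcc=mcc,
                   degenerate=tuple(degenerate))


def round3(x: float) -> float:
    """Round-half-up to 3 decimals, as printed in the reference tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _pair_matches(pred: tuple[int, int], ref: tuple[int, int], slip: int) -> bool:
    (i, j), (ri, rj) = pred, ref
    if slip == 0:
        return (i, j) == (ri, rj)
    # one coordinate may shift by <= slip; the other must be exact
    return (i == ri and abs(j - rj) <= slip) or (j == rj and abs(i - ri) <= slip)


def core_stem_match(
    pred: PseudoknotCandidate, ref: PseudoknotCandidate, slip: int = 1
) -> bool:
    """Exact-location match of both core stems under slippage equivalence."""
    if slip < 0:
        raise ValueError("slip must be >= 0")
    return _pair_matches((pred.i1, pred.j1), (ref.i1, ref.j1), slip) and \
        _pair_matches((pred.i2, pred.j2), (ref.i2, ref.j2), slip)


@dataclass
class EvalRecord:
    seq_id: str
    length: int
    pred_db: str
    ref_db: str
    pred_core: PseudoknotCandidate | None = None
    ref_core: PseudoknotCandidate | None = None


@dataclass
class DatasetReport:
    overall: pd.DataFrame
    per_bin: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def _bin_label(length: int, edges: Sequence[int]) -> str:
    # closed-left convention: edge e starts the bin "e <= L < next"
    lo = None
    for e in edges:
        if length >= e:
            lo = e
        else:
            break
    if lo is None:
        return f"L < {edges[0]}"
    idx = edges.index(lo)
    if idx + 1 < len(edges):
        return f"{lo} <= L < {edges[idx + 1]}"
    return f"L >= {lo}"


def evaluate_dataset(
    records: Iterable[EvalRecord],
    length_bins: Sequence[int] = (30, 40, 50),
    slip: int = 1,
    strict_partners: bool = False,
) -> DatasetReport:
    """Micro-averaged metrics and exact-match rates, overall and per bin.

    Counts are summed over sequences before metrics are computed, so each
    group yields a single tp/tn/fp/fn quadruple.
    """
    bins: dict[str, dict] = {}
    skipped: list[str] = []

    def bucket(label: str) -> dict:
        return bins.setdefault(
            label, {"counts": ConfusionCounts(), "n": 0, "exact": 0, "with_core": 0}
        )

    for rec in records:
        if not rec.ref_db:
            skipped.append(rec.seq_id)
            continue
        c = confusion(rec.pred_db, rec.ref_db, strict_partners=strict_partners)
        labels = ["overall", _bin_label(rec.length, length_bins)]
        for label in labels:
            b = bucket(label)
            b["counts"] = b["counts"] + c
            b["n"] += 1
            if rec.ref_core is not None:
                b["with_core"] += 1
                if rec.pred_core is not None and core_stem_match(
                    rec.pred_core, rec.ref_core, slip
                ):
                    b["exact"] += 1

    rows = []
    for label, b in bins.items():
        counts: ConfusionCounts = b["counts"]
        m = score(counts)
        rows.append({
            "bin": label,
            "n_sequences": b["n"],
            "tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn,
            "ppv": round3(m.ppv), "recall": round3(m.recall),
            "f1": round3(m.f1), "mcc": round3(m.mcc),
            "exact_matches": b["exact"],
            "exact_matches_pct": round(100 * b["exact"] / b["with_core"], 1)
            if b["with_core"] else float("nan"),
        })
    columns = ["bin", "n_sequences", "tp", "tn", "fp", "fn",
               "ppv", "recall", "f1", "mcc", "exact_matches", "exact_matches_pct"]
    df = pd.DataFrame(rows, columns=columns)
    overall = df[df["bin"] == "overall"].reset_index(drop=True)
    per_bin = df[df["bin"] != "overall"].reset_index(drop=True)
    return DatasetReport(overall=overall, per_bin=per_bin, skipped=skipped)
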