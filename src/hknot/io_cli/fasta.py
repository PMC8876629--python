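"""Readers and writers: FASTA, structure records and candidate CSV.

Prediction output is a FASTA-like record of three lines — header,
sequence, dot-bracket — which is also what :func:`read_structures`
accepts (besides a CSV with ``seq_id,sequence,dot_bracket`` columns).
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from ..detect import RnaSequence
from ..energy_select import Prediction

log = logging.getLogger(__name__)

CSV_SCHEMA_VERSION = 1
CANDIDATE_COLUMNS = [
    "seq_id", "i1", "i2", "j1", "j2", "rule_id",
    "pair_count", "up", "g_pseudo", "dot_bracket",
]


class FastaError(ValueError):
    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Parse a (multi-line) FASTA file into normalised RNA sequences."""
    records: list[RnaSequence] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaError(f"record {header!r} has no sequence", header_line)
        records.append(RnaSequence(seq_id=header, bases=seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else line[1:]
                if not header:
                    raise FastaError("empty FASTA header", lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaError(
                        f"sequence data before first header: {line[:20]!r}", lineno
                    )
                chunks.append(line)
    flush()
    return records


def write_prediction(path: str | Path, predictions: Iterable[Prediction],
                     sequences: dict[str, RnaSequence] | None = None) -> None:
    """Write three-line records: header, sequence (if known), dot-bracket."""
    with open(path, "w") as fh:
        for pred in predictions:
            fh.write(f">{pred.seq_id}\n")
            if sequences and pred.seq_id in sequences:
                fh.write(sequences[pred.seq_id].bases + "\n")
            fh.write(pred.dot_bracket + "\n")


def _read_structures_csv(path: Path) -> list[tuple[RnaSequence, str]]:
    df = pd.read_csv(path, comment="#")
    required = {"seq_id", "sequence", "dot_bracket"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: structure CSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return [
        (RnaSequence(seq_id=str(r.seq_id), bases=str(r.sequence)), str(r.dot_bracket))
        for r in df.itertuples()
    ]


def read_structures(path: str | Path) -> list[tuple[RnaSequence, str]]:
    """Read (sequence, dot-bracket) pairs from CSV or three-line records."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith(">"):
        return _read_structures_csv(path)

    out: list[tuple[RnaSequence, str]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected header at record starting {lines[i]!r}")
        seq_id = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {seq_id!r}")
        seq, db = lines[i + 1], lines[i + 2]
        if len(seq) != len(db):
            raise ValueError(
                f"{path}: record {seq_id!r}: sequence and structure lengths differ"
            )
        out.append((RnaSequence(seq_id=seq_id, bases=seq), db))
        i += 3
    return out


def candidates_frame(predictions: Iterable[Prediction]) -> pd.DataFrame:
    """All scored candidates of the given predictions as a data frame."""
    rows = []
    for pred in predictions:
        for s in pred.all_scored:
            c = s.dec.candidate
            rows.append({
                "seq_id": pred.seq_id,
                "i1": c.i1, "i2": c.i2, "j1": c.j1, "j2": c.j2,
                "rule_id": c.rule_id,
                "pair_count": s.pair_count,
                "up": s.up,
                "g_pseudo": s.g_pseudo,
                "dot_bracket": pred.dot_bracket if s is pred.scored else "",
            })
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates_csv(path: str | Path, predictions: Iterable[Prediction]) -> None:
    df = candidates_frame(predictions)
    buf = io.StringIO()
    buf.write(f"# hknot candidates schema v{CSV_SCHEMA_VERSION}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())
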