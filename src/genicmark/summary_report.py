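"""Derived summary quantities: unigene selection, splice-variant fraction,
length distributions, and shared percentage formatting.

Percentages are rounded to one decimal with banker's rounding by default;
a ``mode="truncate"`` escape hatch is provided because some published
figures look truncated rather than rounded.  Raw ratios are always
available so formatting never hides information.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ExpressionRecord",
    "percentage",
    "select_unigenes",
    "splice_variant_fraction",
    "length_histogram",
    "read_expression_table",
]


@dataclass(frozen=True)
class ExpressionRecord:
    """Abundance of one transcript within its isoform cluster (units opaque)."""

    transcript_id: str
    cluster_id: str
    expression: float

    def __post_init__(self) -> None:
        if self.expression < 0:
            raise ValueError(
                f"expression of {self.transcript_id!r} must be non-negative"
            )


def percentage(
    numerator: float, denominator: float, decimals: int = 1, mode: str = "round"
) -> float:
    """Return 100*numerator/denominator formatted to *decimals* places.

    ``mode="round"`` applies round-half-even; ``mode="truncate"`` chops.
    """
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    raw = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    rounding = {"round": ROUND_HALF_EVEN, "truncate": ROUND_DOWN}[mode]
    return float(raw.quantize(quantum, rounding=rounding))


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV with columns transcript_id, cluster_id, expression."""
    frame = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "cluster_id": str})
    required = {"transcript_id", "cluster_id", "expression"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"expression table {path} lacks columns: {sorted(missing)}")
    return [
        ExpressionRecord(
            transcript_id=row.transcript_id,
            cluster_id=row.cluster_id,
            expression=float(row.expression),
        )
        for row in frame.itertuples()
    ]


def select_unigenes(records: Iterable[ExpressionRecord]) -> list[str]:
    """Pick one transcript per cluster: the most expressed member.

    Ties break to the lexicographically smallest transcript id.  Exactly one
    id per cluster is returned, sorted by cluster id.
    """
    best: dict[str, ExpressionRecord] = {}
    seen: set[str] = set()
    for rec in records:
        if rec.transcript_id in seen:
            raise ValueError(f"duplicate expression record for {rec.transcript_id!r}")
        seen.add(rec.transcript_id)
        cur = best.get(rec.cluster_id)
        if (
            cur is None
            or rec.expression > cur.expression
            or (rec.expression == cur.expression and rec.transcript_id < cur.transcript_id)
        ):
            best[rec.cluster_id] = rec
    return [best[c].transcript_id for c in sorted(best)]


def splice_variant_fraction(
    n_transcripts: int, n_unigenes: int, mode: str = "round"
) -> float:
    """Percentage of transcripts that are splice variants, to one decimal."""
    if n_transcripts <= 0:
        raise ValueError("n_transcripts must be positive")
    if n_unigenes > n_transcripts:
        raise ValueError("n_unigenes cannot exceed n_transcripts")
    return percentage(n_transcripts - n_unigenes, n_transcripts, 1, mode=mode)


@dataclass(frozen=True)
class LengthSummary:
    counts: pd.DataFrame
    min: int
    max: int
    mean: float


def length_histogram(
    lengths: Sequence[int],
    bins: Sequence[tuple[int, int | None]] | None = None,
) -> LengthSummary:
    """Bin a set of lengths; bins are (low, high) nt intervals, inclusive,
    with ``high=None`` meaning open-ended.  Default bins follow the usual
    transcriptome presentation (201-500, 501-1000, >1000, plus <=200).
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("length_histogram requires non-empty input")
    if bins is None:
        bins = [(0, 200), (201, 500), (501, 1000), (1001, None)]
    rows = []
    for low, high in bins:
        if high is None:
            n = sum(1 for x in lengths if x >= low)
            label = f">={low}"
        else:
            n = sum(1 for x in lengths if low <= x <= high)
            label = f"{low}-{high}"
        rows.append({"bin": label, "count": n})
    counts = pd.DataFrame(rows, columns=["bin", "count"])
    return LengthSummary(
        counts=counts,
        min=min(lengths),
        max=max(lengths),
        mean=sum(lengths) / len(lengths),
    )
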