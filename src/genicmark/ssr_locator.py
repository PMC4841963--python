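"""Assign each SSR tract to 5'UTR, ORF, 3'UTR or Other using the
transcript's principal-ORF annotation and strand."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import OrfAnnotation
from .ssr_miner import SsrHit
from .summary_report import percentage

__all__ = ["SsrLocalization", "locate", "locate_all", "summarize_localization"]


class SsrLocalization(str, Enum):
    FIVE_UTR = "5UTR"
    ORF = "ORF"
    THREE_UTR = "3UTR"
    OTHER = "Other"


def locate(hit: SsrHit, orf: OrfAnnotation | None) -> SsrLocalization:
    """Localize one SSR against the transcript's ORF (or absence thereof).

    A tract fully inside the ORF is ORF; fully on the 5' side of the ORF
    (strand-aware) is FIVE_UTR; fully on the 3' side is THREE_UTR.  With no
    ORF annotated, or when the tract straddles an ORF boundary, the
    localization is OTHER.
    """
    if orf is None:
        return SsrLocalization.OTHER
    if orf.transcript_id != hit.transcript_id:
        raise ValueError(
            f"ORF is on {orf.transcript_id!r} but hit is on {hit.transcript_id!r}"
        )
    if orf.start <= hit.start and hit.end <= orf.end:
        return SsrLocalization.ORF
    if hit.end <= orf.start:
        return SsrLocalization.FIVE_UTR if orf.strand == "+" else SsrLocalization.THREE_UTR
    if hit.start >= orf.end:
        return SsrLocalization.THREE_UTR if orf.strand == "+" else SsrLocalization.FIVE_UTR
    return SsrLocalization.OTHER


def locate_all(
    hits: Sequence[SsrHit], orfs: Mapping[str, OrfAnnotation]
) -> list[tuple[SsrHit, SsrLocalization]]:
    return [(h, locate(h, orfs.get(h.transcript_id))) for h in hits]


_CATEGORY_ORDER = [
    SsrLocalization.FIVE_UTR,
    SsrLocalization.ORF,
    SsrLocalization.THREE_UTR,
    SsrLocalization.OTHER,
]
_KLASS_ORDER = ["di", "tri", "tetra"]


def summarize_localization(
    localized: Sequence[tuple[SsrHit, SsrLocalization]],
) -> pd.DataFrame:
    """Counts and row percentages per (category x motif class), plus totals.

    Row percentages are relative to the category total; the ``total_pct``
    column is each category's share of all SSRs (one decimal).
    """
    counts: dict[tuple[SsrLocalization, str], int] = {}
    for hit, loc in localized:
        key = (loc, hit.motif.klass)
        counts[key] = counts.get(key, 0) + 1
    grand_total = len(localized)
    rows = []
    for cat in _CATEGORY_ORDER:
        row: dict[str, object] = {"category": cat.value}
        cat_total = sum(counts.get((cat, k), 0) for k in _KLASS_ORDER)
        for k in _KLASS_ORDER:
            n = counts.get((cat, k), 0)
            row[f"{k}_n"] = n
            row[f"{k}_pct"] = percentage(n, cat_total, 1) if cat_total else 0.0
        row["total_n"] = cat_total
        row["total_pct"] = percentage(cat_total, grand_total, 1) if grand_total else 0.0
        rows.append(row)
    total_row: dict[str, object] = {"category": "Total"}
    for k in _KLASS_ORDER:
        n = sum(counts.get((c, k), 0) for c in _CATEGORY_ORDER)
        total_row[f"{k}_n"] = n
        total_row[f"{k}_pct"] = percentage(n, grand_total, 1) if grand_total else 0.0
    total_row["total_n"] = grand_total
    total_row["total_pct"] = 100.0 if grand_total else 0.0
    rows.append(total_row)
    return pd.DataFrame(rows)
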