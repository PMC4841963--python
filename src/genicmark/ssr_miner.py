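"""Perfect microsatellite (SSR) detection for di-, tri- and tetranucleotide motifs.

Motifs are canonicalized into strand/rotation families (e.g. ``AG/CT``),
and only maximal tracts of complete motif copies meeting per-class
repeat-count thresholds are reported (defaults: di >= 9, tri >= 6,
tetra >= 4 copies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import TranscriptSeq

__all__ = [
    "DEFAULT_THRESHOLDS",
    "SsrMotif",
    "SsrHit",
    "canonical_motif",
    "find_ssrs",
    "minimum_reportable_tract",
    "summarize_motifs",
    "hits_to_frame",
    "frame_to_hits",
]

#: Minimum complete motif copies per class.
DEFAULT_THRESHOLDS: dict[str, int] = {"di": 9, "tri": 6, "tetra": 4}

_KLASS_BY_LEN = {2: "di", 3: "tri", 4: "tetra"}
_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _rotations(s: str) -> list[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


@dataclass(frozen=True)
class SsrMotif:
    """A canonical motif family for a 2-4 nt repeat unit."""

    canonical: str

    @property
    def family_label(self) -> str:
        return f"{self.canonical}/{_revcomp(self.canonical)}"

    @property
    def klass(self) -> str:
        return _KLASS_BY_LEN[len(self.canonical)]


@dataclass(frozen=True)
class SsrHit:
    """A maximal perfect repeat tract, 0-based half-open in its transcript."""

    transcript_id: str
    start: int
    end: int
    motif: SsrMotif
    repeat_count: int

    @property
    def tract_length(self) -> int:
        return self.end - self.start


def canonical_motif(raw: str) -> SsrMotif | None:
    """Canonicalize a raw 2-4 nt motif; return ``None`` on rejection.

    The canonical form is the lexicographically smallest string among all
    rotations of the motif and all rotations of its reverse complement.
    Motifs that are whole-number powers of a shorter unit (``AA``, ``ATAT``,
    ``AAA`` read as a unit of a longer class, ...) and motifs containing
    characters outside ACGT are rejected.
    """
    if not (2 <= len(raw) <= 4):
        return None
    raw = raw.upper()
    if set(raw) - _ACGT:
        return None
    n = len(raw)
    for d in range(1, n):
        if n % d == 0 and raw == raw[:d] * (n // d):
            return None
    candidates = _rotations(raw) + _rotations(_revcomp(raw))
    return SsrMotif(canonical=min(candidates))


def minimum_reportable_tract(thresholds: Mapping[str, int] | None = None) -> int:
    """Shortest tract (nt) reportable under the per-class copy thresholds."""
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    lens = {"di": 2, "tri": 3, "tetra": 4}
    return min(thresholds[k] * lens[k] for k in thresholds)


def _periodic_regions(seq: str, k: int) -> list[tuple[int, int]]:
    """Maximal regions [s, e) where seq has period k (N never matches)."""
    n = len(seq)
    regions: list[tuple[int, int]] = []
    run_start: int | None = None
    for j in range(k, n):
        ok = seq[j] == seq[j - k] and seq[j] in _ACGT
        if ok:
            if run_start is None:
                run_start = j
        elif run_start is not None:
            regions.append((run_start - k, j))
            run_start = None
    if run_start is not None:
        regions.append((run_start - k, n))
    return regions


def _resolve_overlaps(candidates: list[SsrHit]) -> list[SsrHit]:
    # Longer tract wins; tie -> smaller motif class; final tie -> leftmost.
    order = sorted(
        candidates,
        key=lambda h: (-(h.end - h.start), len(h.motif.canonical), h.start),
    )
    kept: list[SsrHit] = []
    for h in order:
        if all(h.end <= o.start or o.end <= h.start for o in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def find_ssrs(
    transcript: TranscriptSeq,
    thresholds: Mapping[str, int] | None = None,
) -> list[SsrHit]:
    """Report all maximal perfect SSR tracts in *transcript*.

    Overlapping candidates of different classes are resolved to one hit per
    locus (longer tract wins, tie goes to the smaller motif class).  Hits
    are sorted by start position.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    for klass, t in thresholds.items():
        if t < 1:
            raise ValueError(f"threshold for {klass!r} must be >= 1, got {t}")
    seq = transcript.seq
    candidates: list[SsrHit] = []
    for k, klass in _KLASS_BY_LEN.items():
        min_copies = thresholds.get(klass)
        if min_copies is None:
            continue
        for s, e in _periodic_regions(seq, k):
            copies = (e - s) // k
            if copies < min_copies:
                continue
            motif = canonical_motif(seq[s : s + k])
            if motif is None:
                continue
            candidates.append(
                SsrHit(
                    transcript_id=transcript.id,
                    start=s,
                    end=s + copies * k,
                    motif=motif,
                    repeat_count=copies,
                )
            )
    return _resolve_overlaps(candidates)


def find_ssrs_all(
    transcripts: Iterable[TranscriptSeq],
    thresholds: Mapping[str, int] | None = None,
) -> list[SsrHit]:
    hits: list[SsrHit] = []
    for ts in transcripts:
        hits.extend(find_ssrs(ts, thresholds))
    return hits


# ---------------------------------------------------------------------------
# Summary


@dataclass(frozen=True)
class MotifSummary:
    """Per-class/per-family SSR statistics for one transcript set."""

    table: pd.DataFrame
    total: int
    class_totals: dict[str, int]
    unigenes_with_ssr: int
    unigene_count: int

    def class_share(self, klass: str, decimals: int = 1) -> float:
        """Percentage of all SSRs belonging to *klass*, rounded half-even."""
        from .summary_report import percentage

        return percentage(self.class_totals.get(klass, 0), self.total, decimals)

    @property
    def pct_unigenes_with_ssr(self) -> float:
        from .summary_report import percentage

        return percentage(self.unigenes_with_ssr, self.unigene_count, 1)


def summarize_motifs(hits: Sequence[SsrHit], unigene_count: int) -> MotifSummary:
    """Build the per-class / per-family motif table for one species' hits.

    Percentages of a family are relative to its class total; the summary
    also reports how many distinct unigenes carry at least one SSR and what
    fraction of *unigene_count* that is.
    """
    from .summary_report import percentage

    if unigene_count <= 0:
        raise ValueError("unigene_count must be positive")
    class_totals: dict[str, int] = {"di": 0, "tri": 0, "tetra": 0}
    family_counts: dict[tuple[str, str], int] = {}
    unigenes: set[str] = set()
    for h in hits:
        class_totals[h.motif.klass] += 1
        key = (h.motif.klass, h.motif.family_label)
        family_counts[key] = family_counts.get(key, 0) + 1
        unigenes.add(h.transcript_id)
    rows = []
    for klass in ("di", "tri", "tetra"):
        families = sorted(
            ((fam, n) for (k, fam), n in family_counts.items() if k == klass),
            key=lambda x: (-x[1], x[0]),
        )
        for fam, n in families:
            rows.append(
                {
                    "klass": klass,
                    "family": fam,
                    "count": n,
                    "pct_of_class": percentage(n, class_totals[klass], 1),
                }
            )
    table = pd.DataFrame(rows, columns=["klass", "family", "count", "pct_of_class"])
    return MotifSummary(
        table=table,
        total=len(hits),
        class_totals=class_totals,
        unigenes_with_ssr=len(unigenes),
        unigene_count=unigene_count,
    )


# ---------------------------------------------------------------------------
# TSV round-trip

_HIT_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "motif",
    "family",
    "klass",
    "repeat_count",
    "tract_length",
]


def hits_to_frame(hits: Sequence[SsrHit]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": h.transcript_id,
            "start": h.start,
            "end": h.end,
            "motif": h.motif.canonical,
            "family": h.motif.family_label,
            "klass": h.motif.klass,
            "repeat_count": h.repeat_count,
            "tract_length": h.tract_length,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=_HIT_COLUMNS)


def frame_to_hits(frame: pd.DataFrame) -> list[SsrHit]:
    return [
        SsrHit(
            transcript_id=row["transcript_id"],
            start=int(row["start"]),
            end=int(row["end"]),
            motif=SsrMotif(canonical=row["motif"]),
            repeat_count=int(row["repeat_count"]),
        )
        for _, row in frame.iterrows()
    ]
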