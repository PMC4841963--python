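"""Genotyping-suitability filter cascade for transcriptome SNVs.

Four flags are computed per variant:

* ``cs60``  - another SNV lies closer than 60 nt on the same transcript;
* ``cl60``  - the variant lies closer than 60 nt to a transcript edge;
* ``hv``    - some 100-nt window containing the variant holds more than
  5 SNVs;
* ``cef_pass`` - at least one catalogued restriction enzyme cuts the two
  allelic contexts a different number of times (CAPS-suitable).

A variant is *filtered* (kept as a suitable marker) when it is unflagged by
the first three and passes CEF.  "Closer than 60" is strict: a distance of
exactly 60 passes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import TranscriptSeq, VariantRecord

__all__ = [
    "FilterFlags",
    "RestrictionEnzyme",
    "load_enzymes",
    "count_site_matches",
    "flag_cs60",
    "flag_cl60",
    "flag_hv",
    "flag_cef",
    "apply_all",
]

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(site: str) -> str:
    return site.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with an IUPAC recognition site."""

    name: str
    site: str
    common: bool = True

    def __post_init__(self) -> None:
        site = self.site.upper()
        if len(site) < 4:
            raise ValueError(f"{self.name}: recognition site must be >= 4 nt")
        bad = set(site) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "site", site)


@dataclass(frozen=True)
class FilterFlags:
    cs60: bool
    cl60: bool
    hv: bool
    cef_pass: bool
    cef_enzymes: tuple[str, ...] = ()

    @property
    def filtered(self) -> bool:
        return (not self.cs60) and (not self.cl60) and (not self.hv) and self.cef_pass

    @property
    def flag_names(self) -> tuple[str, ...]:
        names = []
        if self.cs60:
            names.append("CS60")
        if self.cl60:
            names.append("CL60")
        if self.hv:
            names.append("HV")
        if not self.cef_pass:
            names.append("CEF")
        return tuple(names)


def load_enzymes(path: str | Path | None = None) -> list[RestrictionEnzyme]:
    """Load an enzyme catalogue TSV (name, site[, common]); default packaged."""
    if path is None:
        source = resources.files("genicmark.data").joinpath("enzymes.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    enzymes: list[RestrictionEnzyme] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"enzyme catalogue line {lineno}: expected name<TAB>site")
        common = True
        if len(fields) >= 3:
            common = fields[2].strip().lower() in ("1", "true", "yes")
        enzymes.append(RestrictionEnzyme(name=fields[0], site=fields[1], common=common))
    if not enzymes:
        raise ValueError("enzyme catalogue is empty")
    return enzymes


def _site_pattern(site: str) -> re.Pattern[str]:
    # Lookahead makes overlapping occurrences countable.
    body = "".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in site)
    return re.compile(f"(?={body})")


def count_site_matches(seq: str, enzyme: RestrictionEnzyme) -> int:
    """Count occurrences of the recognition site on both strands of *seq*.

    Palindromic sites are counted once per strand (twice per locus); the
    count is only ever compared between two contexts, so the convention
    cancels out.
    """
    fwd = len(_site_pattern(enzyme.site).findall(seq))
    rev = len(_site_pattern(revcomp_iupac(enzyme.site)).findall(seq))
    return fwd + rev


# ---------------------------------------------------------------------------
# Positional filters


def flag_cs60(positions: Sequence[int], threshold: int = 60) -> list[bool]:
    """Flag positions with another variant closer than *threshold* nt.

    Input is the full set of variant positions on one transcript (any
    order); distance is measured between first REF bases; strict ``<``.
    """
    pos_sorted = sorted(positions)
    flagged_at: dict[int, bool] = {}
    for i, p in enumerate(pos_sorted):
        near = False
        if i > 0 and p - pos_sorted[i - 1] < threshold:
            near = True
        if i + 1 < len(pos_sorted) and pos_sorted[i + 1] - p < threshold:
            near = True
        if near:
            flagged_at[p] = True
        else:
            flagged_at.setdefault(p, False)
    return [flagged_at[p] for p in positions]


def flag_cl60(pos: int, transcript_length: int, threshold: int = 60) -> bool:
    """Flag a variant closer than *threshold* nt to either transcript edge."""
    if not (0 <= pos < transcript_length):
        raise ValueError(f"position {pos} outside transcript of length {transcript_length}")
    return min(pos, transcript_length - 1 - pos) < threshold


def flag_hv(positions: Sequence[int], window: int = 100, max_snvs: int = 5) -> list[bool]:
    """Flag variants lying in a *window*-nt stretch with more than *max_snvs*
    variants (self included); strict ``>``.

    Equivalent to: there exist ``max_snvs + 1`` variants including this one
    whose positions span at most ``window - 1`` nt.
    """
    pos_sorted = sorted(positions)
    n = len(pos_sorted)
    k = max_snvs  # need k+1 variants within the window
    flagged_sorted = [False] * n
    for j in range(0, n - k):
        if pos_sorted[j + k] - pos_sorted[j] <= window - 1:
            for t in range(j, j + k + 1):
                flagged_sorted[t] = True
    flag_at: dict[int, bool] = {}
    for p, f in zip(pos_sorted, flagged_sorted):
        flag_at[p] = flag_at.get(p, False) or f
    return [flag_at[p] for p in positions]


# ---------------------------------------------------------------------------
# CEF (CAPS enzyme filter)


def allele_contexts(
    variant: VariantRecord, transcript: TranscriptSeq, flank: int = 60
) -> list[tuple[str, str]]:
    """Build (REF-context, ALT-context) sequence pairs of +-*flank* nt.

    One pair per ALT allele; contexts truncate at transcript edges.  The
    transcript is expected to carry the REF allele at the variant position.
    """
    seq = transcript.seq
    pos = variant.pos
    if not (0 <= pos < len(seq)):
        raise ValueError(
            f"variant at {variant.transcript_id}:{pos} outside transcript"
        )
    left = seq[max(0, pos - flank) : pos]
    right = seq[pos + len(variant.ref) : pos + len(variant.ref) + flank]
    return [(left + variant.ref + right, left + alt + right) for alt in variant.alts]


def flag_cef(
    variant: VariantRecord,
    transcript: TranscriptSeq,
    enzymes: Sequence[RestrictionEnzyme],
    flank: int = 60,
) -> tuple[bool, list[str]]:
    """CAPS suitability: does any enzyme cut the two allelic contexts a
    different number of times?  Multi-allelic sites pass if any ALT is
    differential; returns the differential enzyme names.
    """
    differential: list[str] = []
    pairs = allele_contexts(variant, transcript, flank)
    for enzyme in enzymes:
        for ref_ctx, alt_ctx in pairs:
            if count_site_matches(ref_ctx, enzyme) != count_site_matches(alt_ctx, enzyme):
                differential.append(enzyme.name)
                break
    return (bool(differential), differential)


# ---------------------------------------------------------------------------
# Cascade


def apply_all(
    variants: Sequence[VariantRecord],
    transcripts: Iterable[TranscriptSeq] | Mapping[str, TranscriptSeq],
    enzymes: Sequence[RestrictionEnzyme] | None = None,
    cs_threshold: int = 60,
    cl_threshold: int = 60,
    hv_window: int = 100,
    hv_max: int = 5,
    flank: int = 60,
) -> list[FilterFlags]:
    """Compute FilterFlags for every variant (order-preserving).

    CS60 and HV group variants per transcript; the result is invariant to
    the input ordering of *variants*.
    """
    if enzymes is None:
        enzymes = load_enzymes()
    if isinstance(transcripts, Mapping):
        by_id = dict(transcripts)
    else:
        by_id = {ts.id: ts for ts in transcripts}
    by_transcript: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        by_transcript.setdefault(v.transcript_id, []).append(i)
    flags: list[FilterFlags | None] = [None] * len(variants)
    for tid, idxs in by_transcript.items():
        ts = by_id.get(tid)
        if ts is None:
            raise KeyError(f"transcript {tid!r} referenced by variants but not supplied")
        positions = [variants[i].pos for i in idxs]
        cs = flag_cs60(positions, cs_threshold)
        hv = flag_hv(positions, hv_window, hv_max)
        for local, i in enumerate(idxs):
            v = variants[i]
            cl = flag_cl60(v.pos, ts.length, cl_threshold)
            cef_pass, enzymes_hit = flag_cef(v, ts, enzymes, flank)
            flags[i] = FilterFlags(
                cs60=cs[local],
                cl60=cl,
                hv=hv[local],
                cef_pass=cef_pass,
                cef_enzymes=tuple(enzymes_hit),
            )
    return [f for f in flags if f is not None]
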