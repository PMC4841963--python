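"""Synthetic transcriptome generator with planted ground truth.

Produces transcripts (FASTA), principal ORFs (BED), a multi-species VCF and
a truth table so that every pipeline stage can be tested closed-loop:
planted SSR tracts are the only SSRs present (backgrounds are
rejection-sampled), planted variants have genotype patterns whose intended
intraspecific/interspecific tags are enumerated by construction, and a
configurable share of variants is built to violate each suitability filter
(close pairs, edge-proximal sites, dense clusters, and sites with or
without a differential restriction site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    OrfAnnotation,
    SpeciesPanel,
    TranscriptSeq,
    VariantRecord,
    write_fasta,
    write_orf_bed,
    write_vcf,
)
from .marker_filters import IUPAC, RestrictionEnzyme, load_enzymes
from .ssr_miner import DEFAULT_THRESHOLDS, canonical_motif, find_ssrs

__all__ = ["SimParams", "SimulationError", "TruthTable", "simulate", "plant_caps_site", "write_outputs"]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Minimum separation between planted item spans; variant contexts extend
#: +-(flank + allele) ~ 66 nt, so 140 keeps interior contexts disjoint.
_SEP = 140
_EDGE_MARGIN = 140
_CLASS_LEN = {"di": 2, "tri": 3, "tetra": 4}


class SimulationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the requested rates."""


@dataclass(frozen=True)
class SimParams:
    n_transcripts: int = 50
    min_len: int = 300
    max_len: int = 3000
    orf_fraction: float = 0.8
    ssr_plant_rate: float = 0.5
    snp_rate: float = 1.2
    indel_rate: float = 0.3
    species: tuple[str, ...] = ("INC", "AET", "MEL", "TOR")
    het_fraction: float = 0.35
    caps_fraction: float = 0.5
    cs_pair_fraction: float = 0.15
    edge_fraction: float = 0.10
    hv_cluster_fraction: float = 0.10
    seed: int = 0
    max_attempts: int = 50

    def __post_init__(self) -> None:
        if self.min_len < 50:
            raise ValueError("min_len must be >= 50")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        for name in ("ssr_plant_rate", "snp_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.species) < 1:
            raise ValueError("at least one species is required")


@dataclass
class TruthTable:
    """Planted features with their intended classifications and flags."""

    ssrs: pd.DataFrame
    variants: pd.DataFrame

    def save(self, ssr_path: str | Path, variant_path: str | Path) -> None:
        self.ssrs.to_csv(ssr_path, sep="\t", index=False)
        self.variants.to_csv(variant_path, sep="\t", index=False)

    @classmethod
    def load(cls, ssr_path: str | Path, variant_path: str | Path) -> "TruthTable":
        read = lambda p: pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        return cls(ssrs=read(ssr_path), variants=read(variant_path))


@dataclass
class SimResult:
    params: SimParams
    transcripts: list[TranscriptSeq]
    orfs: dict[str, OrfAnnotation]
    variants: list[VariantRecord]
    panel: SpeciesPanel
    truth: TruthTable


# ---------------------------------------------------------------------------
# Low-level helpers (deliberately independent of the filter implementations:
# the truth table must not be computed through the code paths under test)


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _find_concrete_matches(seq: str, site: str) -> list[tuple[int, int]]:
    """Spans where *seq* contains *site* on either strand (concrete sites)."""
    rc = _revcomp(site)
    L = len(site)
    return [
        (i, i + L)
        for i in range(len(seq) - L + 1)
        if seq[i : i + L] == site or seq[i : i + L] == rc
    ]


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=n)]


def _localize(start: int, end: int, orf: OrfAnnotation | None) -> str:
    if orf is None:
        return "Other"
    if orf.start <= start and end <= orf.end:
        return "ORF"
    if end <= orf.start:
        return "5UTR" if orf.strand == "+" else "3UTR"
    if start >= orf.end:
        return "3UTR" if orf.strand == "+" else "5UTR"
    return "Other"


def _intended_tags(
    states: dict[str, tuple[str, int | None]],
) -> tuple[list[str], list[str]]:
    """Enumerate intended intraspecific species and interspecific combos
    from designed per-species genotype states (brute force by definition)."""
    intra = sorted(sp for sp, (s, _) in states.items() if s == "het")
    hom = {sp: a for sp, (s, a) in states.items() if s == "hom"}
    inter: list[str] = []
    hom_sp = sorted(hom)
    for k in range(2, min(4, len(hom_sp)) + 1):
        for combo in combinations(hom_sp, k):
            if len({hom[sp] for sp in combo}) >= 2:
                inter.append("+".join(combo))
    return intra, sorted(inter)


def plant_caps_site(
    transcript: TranscriptSeq,
    enzyme: RestrictionEnzyme,
    pos: int,
    rng: np.random.Generator | None = None,
    flank: int = 60,
) -> tuple[TranscriptSeq, VariantRecord]:
    """Embed *enzyme*'s recognition site over *pos* and return the modified
    transcript plus a SNP whose two alleles differ in that one site.

    The REF allelic context contains the site; the ALT substitution
    destroys it.  ``pos`` must leave at least *flank* nt on both sides.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if pos < flank or pos > transcript.length - 1 - flank:
        raise SimulationError(
            f"position {pos} does not leave >= {flank} nt flanks on {transcript.id!r}"
        )
    site_len = len(enzyme.site)
    # Concrete realization of a possibly degenerate site.
    concrete = "".join(
        IUPAC[c][int(rng.integers(0, len(IUPAC[c])))] for c in enzyme.site
    )
    offsets = [o for o in range(site_len) if len(IUPAC[enzyme.site[o]]) < 4]
    if not offsets:
        raise SimulationError(f"enzyme {enzyme.name} site is unplaceable (all-N site)")
    offset = offsets[int(rng.integers(0, len(offsets)))]
    start = pos - offset
    if start < 0 or start + site_len > transcript.length:
        raise SimulationError(f"enzyme site does not fit around position {pos}")
    seq = list(transcript.seq)
    seq[start : start + site_len] = concrete
    new_seq = "".join(seq)
    ref = concrete[offset]
    alt_options = [b for b in _BASES if b != ref and b not in IUPAC[enzyme.site[offset]]]
    if not alt_options:
        alt_options = [b for b in _BASES if b != ref]
    alt = alt_options[int(rng.integers(0, len(alt_options)))]
    modified = TranscriptSeq(id=transcript.id, seq=new_seq)
    variant = VariantRecord(
        transcript_id=transcript.id, pos=pos, ref=ref, alts=(alt,), genotypes={}
    )
    return modified, variant


# ---------------------------------------------------------------------------
# Per-transcript construction


@dataclass
class _PlannedVariant:
    pos: int
    kind: str  # "SNP" | "INDEL"
    scenario: str  # "clean" | "cs_pair" | "edge" | "hv"
    caps: bool
    ref: str = ""
    alt: str = ""
    caps_enzyme: str = ""
    site_span: tuple[int, int] | None = None
    states: dict[str, tuple[str, int | None]] = field(default_factory=dict)


def _draw_motif(rng: np.random.Generator) -> tuple[str, str]:
    klass = ("di", "tri", "tetra")[
        int(rng.choice(3, p=[0.3, 0.5, 0.2]))
    ]
    k = _CLASS_LEN[klass]
    while True:
        raw = "".join(_BASES[i] for i in rng.integers(0, 4, size=k))
        if canonical_motif(raw) is not None:
            return klass, raw


def _draw_states(
    rng: np.random.Generator, species: Sequence[str], het_fraction: float
) -> dict[str, tuple[str, int | None]]:
    """Design per-species genotype states for one planted variant."""
    states: dict[str, tuple[str, int | None]] = {}
    if rng.random() < het_fraction and len(species) >= 1:
        het_sp = species[int(rng.integers(0, len(species)))]
        for sp in species:
            if sp == het_sp:
                states[sp] = ("het", None)
            else:
                states[sp] = ("hom", 0) if rng.random() < 0.7 else ("missing", None)
    else:
        k = min(len(species), int(rng.choice([2, 3, 4], p=[0.6, 0.25, 0.15])))
        idx = list(rng.choice(len(species), size=k, replace=False))
        chosen = [species[i] for i in idx]
        alleles = [int(rng.integers(0, 2)) for _ in chosen]
        if len(set(alleles)) < 2:  # force a differential pair
            alleles[int(rng.integers(0, len(alleles)))] ^= 1
        for sp, a in zip(chosen, alleles):
            states[sp] = ("hom", a)
        for sp in species:
            if sp not in states:
                states[sp] = (
                    ("hom", 0) if rng.random() < 0.4 else ("missing", None)
                )
    # Ensure at least one ALT carrier so the site is a real variant.
    if all(
        (s == "missing") or (s == "hom" and a == 0) for s, a in states.values()
    ):
        sp = species[int(rng.integers(0, len(species)))]
        states[sp] = ("hom", 1)
    return states


def _build_transcript(
    rng: np.random.Generator,
    params: SimParams,
    tid: str,
    enzymes: list[RestrictionEnzyme],
    flank: int = 60,
) -> tuple[TranscriptSeq, OrfAnnotation | None, list[dict], list[_PlannedVariant]]:
    """Construct one transcript with planted SSRs and variants; may raise
    SimulationError if rejection sampling fails."""

    def _draw_layout():
        """Draw length, planted-item counts and a spatial layout; returns
        None when the draw does not fit (the attempt is then rejected)."""
        length = int(rng.integers(params.min_len, params.max_len + 1))

        n_ssrs = int(rng.poisson(params.ssr_plant_rate))
        budget = int(
            rng.poisson((params.snp_rate + params.indel_rate) * length / 1000.0)
        )
        p_indel = (
            params.indel_rate / (params.snp_rate + params.indel_rate)
            if (params.snp_rate + params.indel_rate) > 0
            else 0.0
        )

        blocks: list[list[_PlannedVariant]] = []
        edge_blocks: list[_PlannedVariant] = []

        def _new_variant(scenario: str, caps: bool) -> _PlannedVariant:
            kind = "INDEL" if rng.random() < p_indel else "SNP"
            return _PlannedVariant(pos=-1, kind=kind, scenario=scenario, caps=caps)

        while budget > 0:
            r = rng.random()
            if r < params.hv_cluster_fraction and budget >= 6:
                blocks.append([_new_variant("hv", False) for _ in range(6)])
                budget -= 6
            elif (
                r < params.hv_cluster_fraction + params.cs_pair_fraction
                and budget >= 2
            ):
                blocks.append([_new_variant("cs_pair", False) for _ in range(2)])
                budget -= 2
            elif (
                r
                < params.hv_cluster_fraction
                + params.cs_pair_fraction
                + params.edge_fraction
                and len(edge_blocks) < 2
            ):
                edge_blocks.append(_new_variant("edge", False))
                budget -= 1
            else:
                caps = rng.random() < params.caps_fraction
                blocks.append([_new_variant("clean", caps)])
                budget -= 1

        ssr_plans: list[dict] = []
        for _ in range(n_ssrs):
            klass, motif = _draw_motif(rng)
            k = _CLASS_LEN[klass]
            copies = DEFAULT_THRESHOLDS[klass] + int(rng.geometric(0.45)) - 1
            copies = min(copies, 80 // k)
            ssr_plans.append({"klass": klass, "motif": motif, "copies": copies})

        # interior layout: shuffle items, place left to right with _SEP gaps
        items: list[tuple[str, object, int]] = []  # (type, payload, width)
        for plan in ssr_plans:
            width = plan["copies"] * _CLASS_LEN[plan["klass"]]
            items.append(("ssr", plan, width))
        for block in blocks:
            if block[0].scenario == "hv":
                gaps = [int(rng.integers(10, 19)) for _ in range(5)]
                width = sum(gaps) + 1
                block_payload = (block, gaps)
            elif block[0].scenario == "cs_pair":
                gap = int(rng.integers(10, 60))
                width = gap + 1
                block_payload = (block, [gap])
            else:
                width = max(1, 6)  # room for ref allele / planted site wiggle
                block_payload = (block, [])
            items.append(("var", block_payload, width))
        order = list(rng.permutation(len(items)))
        items = [items[i] for i in order]

        interior_lo, interior_hi = _EDGE_MARGIN, length - _EDGE_MARGIN
        needed = sum(w for _, _, w in items) + _SEP * max(0, len(items) - 1)
        if items and needed > (interior_hi - interior_lo):
            return None  # does not fit: reject this draw

        placements: list[tuple[int, str, object, int]] = []
        if items:
            slack = (interior_hi - interior_lo) - needed
            cursor = interior_lo
            for typ, payload, width in items:
                jitter = int(rng.integers(0, slack + 1)) if slack > 0 else 0
                slack -= jitter
                cursor += jitter
                placements.append((cursor, typ, payload, width))
                cursor += width + _SEP

        # edge variants: one per side at most
        sides = ["left", "right"]
        rng.shuffle(sides)
        for v, side in zip(edge_blocks, sides):
            if side == "left":
                v.pos = int(rng.integers(3, 60))
            else:
                v.pos = length - 1 - int(rng.integers(3, 60))
        return length, placements, edge_blocks

    # --- assemble sequence with rejection sampling
    for attempt in range(params.max_attempts):
        layout = _draw_layout()
        if layout is None:
            continue
        length, placements, edge_blocks = layout
        seq = _rand_seq(rng, length)
        protected: set[int] = set()
        planted_ssrs: list[dict] = []
        variants: list[_PlannedVariant] = list(edge_blocks)

        for start, typ, payload, width in placements:
            if typ == "ssr":
                plan = payload  # type: ignore[assignment]
                k = _CLASS_LEN[plan["klass"]]
                tract = plan["motif"] * plan["copies"]
                seq[start : start + width] = tract
                # break periodicity at both tract boundaries
                if start - 1 >= 0:
                    bad = plan["motif"][k - 1]
                    choices = [b for b in _BASES if b != bad]
                    seq[start - 1] = choices[int(rng.integers(0, 3))]
                end = start + width
                if end < length:
                    bad = plan["motif"][0]
                    choices = [b for b in _BASES if b != bad]
                    seq[end] = choices[int(rng.integers(0, 3))]
                protected.update(range(max(0, start - 1), min(length, end + 1)))
                planted_ssrs.append(
                    {**plan, "start": start, "end": end}
                )
            else:
                block, gaps = payload  # type: ignore[misc]
                pos = start
                for i, v in enumerate(block):
                    v.pos = pos
                    if i < len(gaps):
                        pos += gaps[i]
                variants.extend(block)

        # --- realize alleles (CAPS planting edits the sequence)
        ok = True
        for v in variants:
            if v.kind == "SNP" and v.caps:
                enzyme = enzymes[int(rng.integers(0, len(enzymes)))]
                site = enzyme.site  # default catalogue sites are concrete
                offset = int(rng.integers(0, len(site)))
                s0 = v.pos - offset
                seq[s0 : s0 + len(site)] = site
                v.ref = site[offset]
                v.alt = [b for b in _BASES if b != v.ref][int(rng.integers(0, 3))]
                v.caps_enzyme = enzyme.name
                v.site_span = (s0, s0 + len(site))
                protected.update(range(s0, s0 + len(site)))
            elif v.kind == "INDEL" and v.caps:
                enzyme = enzymes[int(rng.integers(0, len(enzymes)))]
                site = enzyme.site
                offset = int(rng.integers(0, len(site) - 2))
                s0 = v.pos - offset
                seq[s0 : s0 + len(site)] = site
                # deletion of the base after pos removes a site base
                v.ref = "".join(seq[v.pos : v.pos + 2])
                v.alt = seq[v.pos]
                v.caps_enzyme = enzyme.name
                v.site_span = (s0, s0 + len(site))
                protected.update(range(s0, s0 + len(site)))
            elif v.kind == "SNP":
                v.ref = seq[v.pos]
                v.alt = [b for b in _BASES if b != v.ref][int(rng.integers(0, 3))]
            else:  # plain INDEL
                if rng.random() < 0.5 and v.pos + 4 < length - 1:
                    dlen = int(rng.integers(1, 4))
                    v.ref = "".join(seq[v.pos : v.pos + 1 + dlen])
                    v.alt = seq[v.pos]
                else:
                    ilen = int(rng.integers(1, 4))
                    v.ref = seq[v.pos]
                    v.alt = v.ref + "".join(
                        _BASES[i] for i in rng.integers(0, 4, size=ilen)
                    )
            protected.update(range(v.pos, v.pos + max(1, len(v.ref))))

        # --- scrub accidental restriction sites from variant contexts
        if not _scrub_contexts(rng, seq, variants, enzymes, protected, flank):
            continue

        text = "".join(seq)
        # --- verify: CAPS differential, non-CAPS silent, SSRs exact
        for v in variants:
            ref_ctx, alt_ctx = _contexts(text, v, flank)
            diffs = [
                e.name
                for e in enzymes
                if len(_find_concrete_matches(ref_ctx, e.site))
                != len(_find_concrete_matches(alt_ctx, e.site))
            ]
            if v.caps and v.caps_enzyme not in diffs:
                ok = False
                break
            if not v.caps and diffs:
                ok = False
                break
        if not ok:
            continue

        ts = TranscriptSeq(id=tid, seq=text)
        mined = find_ssrs(ts)
        expected = sorted(
            (p["start"], p["end"], p["copies"]) for p in planted_ssrs
        )
        got = sorted((h.start, h.end, h.repeat_count) for h in mined)
        if got != expected:
            continue

        # --- ORF annotation
        orf: OrfAnnotation | None = None
        if rng.random() < params.orf_fraction:
            lo = int(rng.integers(30, max(31, length // 4)))
            hi = int(rng.integers((3 * length) // 4, length - 29))
            strand = "+" if rng.random() < 0.5 else "-"
            orf = OrfAnnotation(transcript_id=tid, start=lo, end=hi, strand=strand)

        for p in planted_ssrs:
            p["localization"] = _localize_plan(p, orf)
        for v in variants:
            v.states = _draw_states(rng, params.species, params.het_fraction)
        variants.sort(key=lambda v: v.pos)
        return ts, orf, planted_ssrs, variants

    raise SimulationError(
        f"could not construct transcript {tid!r} after {params.max_attempts} attempts; "
        "rates may be too high for the requested lengths"
    )


def _localize_plan(plan: dict, orf: OrfAnnotation | None) -> str:
    return _localize(plan["start"], plan["end"], orf)


def _contexts(text: str, v: _PlannedVariant, flank: int) -> tuple[str, str]:
    left = text[max(0, v.pos - flank) : v.pos]
    right = text[v.pos + len(v.ref) : v.pos + len(v.ref) + flank]
    return left + v.ref + right, left + v.alt + right


def _scrub_contexts(
    rng: np.random.Generator,
    seq: list[str],
    variants: list[_PlannedVariant],
    enzymes: list[RestrictionEnzyme],
    protected: set[int],
    flank: int,
    max_iter: int = 400,
) -> bool:
    """Mutate background bases until no variant context carries an
    unintended recognition-site match.  Returns False on failure."""
    length = len(seq)
    for _ in range(max_iter):
        offender: list[int] | None = None
        for v in variants:
            text = "".join(seq)
            ref_ctx, alt_ctx = _contexts(text, v, flank)
            ctx_start = max(0, v.pos - flank)
            for enzyme in enzymes:
                for label, ctx in (("ref", ref_ctx), ("alt", alt_ctx)):
                    for ms, me in _find_concrete_matches(ctx, enzyme.site):
                        coords = _ctx_to_transcript(
                            range(ms, me), ctx_start, v, label
                        )
                        span = [c for c in coords if c is not None and 0 <= c < length]
                        if (
                            v.caps
                            and enzyme.name == v.caps_enzyme
                            and v.site_span is not None
                            and label == "ref"
                            and span
                            and span[0] == v.site_span[0]
                        ):
                            continue  # the intended planted site
                        mutable = [c for c in span if c not in protected]
                        if not mutable:
                            return False
                        offender = mutable
                        break
                    if offender:
                        break
                if offender:
                    break
            if offender:
                break
        if offender is None:
            return True
        c = offender[int(rng.integers(0, len(offender)))]
        current = seq[c]
        seq[c] = [b for b in _BASES if b != current][int(rng.integers(0, 3))]
    return False


def _ctx_to_transcript(
    ctx_positions, ctx_start: int, v: _PlannedVariant, which: str
) -> list[int | None]:
    """Map context coordinates back to transcript coordinates (None for
    positions inside the ALT allele, which have no background base)."""
    allele = v.ref if which == "ref" else v.alt
    allele_lo = v.pos - ctx_start
    allele_hi = allele_lo + len(allele)
    out: list[int | None] = []
    for i in ctx_positions:
        if i < allele_lo:
            out.append(ctx_start + i)
        elif i < allele_hi:
            out.append(ctx_start + i if which == "ref" else None)
        else:
            shift = i - allele_hi
            out.append(v.pos + len(v.ref) + shift)
    return out


# ---------------------------------------------------------------------------
# Intended positional flags (direct arithmetic, independent of marker_filters)


def _intended_positional_flags(
    variants: list[_PlannedVariant], length: int
) -> list[dict[str, bool]]:
    positions = [v.pos for v in variants]
    out = []
    for v in variants:
        others = [p for p in positions if p != v.pos]
        cs = any(abs(v.pos - p) < 60 for p in others)
        cl = min(v.pos, length - 1 - v.pos) < 60
        hv = False
        for w in range(max(0, v.pos - 99), v.pos + 1):
            if sum(1 for p in positions if w <= p < w + 100) > 5:
                hv = True
                break
        out.append({"cs60": cs, "cl60": cl, "hv": hv})
    return out


# ---------------------------------------------------------------------------
# Top-level simulation


def simulate(params: SimParams) -> SimResult:
    """Generate transcripts, ORFs, planted SSRs and a multi-species VCF with
    a consistent truth table.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    enzymes = load_enzymes()
    samples = [f"{sp}_1" for sp in params.species]
    panel = SpeciesPanel(dict(zip(samples, params.species)))

    transcripts: list[TranscriptSeq] = []
    orfs: dict[str, OrfAnnotation] = {}
    vcf_records: list[VariantRecord] = []
    ssr_rows: list[dict] = []
    var_rows: list[dict] = []

    width = len(str(params.n_transcripts))
    for i in range(params.n_transcripts):
        tid = f"TR{i + 1:0{width}d}"
        ts, orf, planted_ssrs, variants = _build_transcript(rng, params, tid, enzymes)
        transcripts.append(ts)
        if orf is not None:
            orfs[tid] = orf

        for p in planted_ssrs:
            motif = canonical_motif(p["motif"])
            assert motif is not None
            ssr_rows.append(
                {
                    "transcript_id": tid,
                    "start": p["start"],
                    "end": p["end"],
                    "motif": motif.canonical,
                    "family": motif.family_label,
                    "klass": p["klass"],
                    "repeat_count": p["copies"],
                    "tract_length": p["end"] - p["start"],
                    "localization": p["localization"],
                }
            )

        flags = _intended_positional_flags(variants, ts.length)
        for v, fl in zip(variants, flags):
            genotypes: dict[str, tuple[int, int] | None] = {}
            for sp, sample in zip(params.species, samples):
                state, allele = v.states[sp]
                if state == "missing":
                    genotypes[sample] = None
                elif state == "het":
                    genotypes[sample] = (0, 1)
                else:
                    genotypes[sample] = (allele, allele)
            vcf_records.append(
                VariantRecord(
                    transcript_id=tid,
                    pos=v.pos,
                    ref=v.ref,
                    alts=(v.alt,),
                    genotypes=genotypes,
                )
            )
            intra, inter = _intended_tags(v.states)
            filtered = (
                (not fl["cs60"]) and (not fl["cl60"]) and (not fl["hv"]) and v.caps
            )
            var_rows.append(
                {
                    "transcript_id": tid,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "kind": v.kind,
                    "scenario": v.scenario,
                    "intra": ",".join(intra),
                    "inter": ",".join(inter),
                    "cs60": int(fl["cs60"]),
                    "cl60": int(fl["cl60"]),
                    "hv": int(fl["hv"]),
                    "cef": int(v.caps),
                    "caps_enzyme": v.caps_enzyme,
                    "filtered": int(filtered),
                }
            )

    truth = TruthTable(
        ssrs=pd.DataFrame(
            ssr_rows,
            columns=[
                "transcript_id",
                "start",
                "end",
                "motif",
                "family",
                "klass",
                "repeat_count",
                "tract_length",
                "localization",
            ],
        ),
        variants=pd.DataFrame(
            var_rows,
            columns=[
                "transcript_id",
                "pos",
                "ref",
                "alt",
                "kind",
                "scenario",
                "intra",
                "inter",
                "cs60",
                "cl60",
                "hv",
                "cef",
                "caps_enzyme",
                "filtered",
            ],
        ),
    )
    return SimResult(
        params=params,
        transcripts=transcripts,
        orfs=orfs,
        variants=vcf_records,
        panel=panel,
        truth=truth,
    )


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/BED/VCF/panel/truth files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "bed": outdir / "orfs.bed",
        "vcf": outdir / "variants.vcf",
        "panel": outdir / "panel.tsv",
        "truth_ssrs": outdir / "truth_ssrs.tsv",
        "truth_variants": outdir / "truth_variants.tsv",
    }
    write_fasta(result.transcripts, paths["fasta"])
    write_orf_bed(
        [result.orfs[t.id] for t in result.transcripts if t.id in result.orfs],
        paths["bed"],
    )
    write_vcf(
        result.variants, list(result.panel.samples), paths["vcf"],
        contigs=result.transcripts,
    )
    with open(paths["panel"], "w") as fh:
        for sample in result.panel.samples:
            fh.write(f"{sample}\t{result.panel.species_of(sample)}\n")
    result.truth.save(paths["truth_ssrs"], paths["truth_variants"])
    return paths
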