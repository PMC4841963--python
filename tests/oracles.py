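"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive every quantity from first principles
(substring enumeration, exhaustive window scans, full digestion
simulation) and never call the implementation code paths they check.
"""

from __future__ import annotations

from itertools import combinations

_ACGT = set("ACGT")
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# SSR mining


def _canonical(motif: str) -> str:
    rots = [motif[i:] + motif[:i] for i in range(len(motif))]
    rc = revcomp(motif)
    rots += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rots)


def brute_force_ssrs(seq: str, thresholds: dict[str, int]) -> list[tuple]:
    """All maximal complete-copy tracts by substring enumeration, resolved
    with the documented one-hit-per-locus rule (longer tract, then smaller
    motif class, then leftmost).  Returns (start, end, canonical, copies)."""
    t_by_k = {2: thresholds["di"], 3: thresholds["tri"], 4: thresholds["tetra"]}
    candidates = []
    n = len(seq)
    for k, min_copies in t_by_k.items():
        for start in range(n - k + 1):
            motif = seq[start : start + k]
            if set(motif) - _ACGT:
                continue
            if any(
                k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
            ):
                continue  # power of a shorter unit
            if start - k >= 0 and seq[start - k : start] == motif:
                continue  # extendable by one complete copy on the left
            copies = 1
            while seq[start + copies * k : start + (copies + 1) * k] == motif:
                copies += 1
            if copies < min_copies:
                continue
            candidates.append((start, start + copies * k, _canonical(motif), copies, k))
    order = sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[4], c[0]))
    kept: list[tuple] = []
    for c in order:
        if all(c[1] <= o[0] or o[1] <= c[0] for o in kept):
            kept.append(c)
    kept.sort(key=lambda c: c[0])
    return [(s, e, m, cp) for s, e, m, cp, _ in kept]


# ---------------------------------------------------------------------------
# Positional filters


def brute_force_cs(positions: list[int], threshold: int = 60) -> list[bool]:
    return [
        any(i != j and abs(p - q) < threshold for j, q in enumerate(positions))
        for i, p in enumerate(positions)
    ]


def brute_force_cl(pos: int, length: int, threshold: int = 60) -> bool:
    return pos < threshold or (length - 1 - pos) < threshold


def brute_force_hv(
    positions: list[int], window: int = 100, max_snvs: int = 5
) -> list[bool]:
    """Exhaustive scan over every possible window placement."""
    flags = []
    for p in positions:
        flagged = False
        for w in range(p - window + 1, p + 1):
            if sum(1 for q in positions if w <= q < w + window) > max_snvs:
                flagged = True
                break
        flags.append(flagged)
    return flags


# ---------------------------------------------------------------------------
# CEF: full digestion simulation


def cut_positions(seq: str, site: str) -> list[int]:
    rc = revcomp(site)
    L = len(site)
    return [
        i
        for i in range(len(seq) - L + 1)
        if seq[i : i + L] == site or seq[i : i + L] == rc
    ]


def digest_fragments(seq: str, site: str) -> tuple[int, ...]:
    """Fragment-length multiset after cutting at every recognition site
    (cut placed at the site start; only comparisons matter)."""
    cuts = sorted(set(cut_positions(seq, site)))
    bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
    return tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))


def differential_enzymes_by_digestion(
    ref_ctx: str, alt_ctx: str, sites: dict[str, str]
) -> set[str]:
    """Enzymes whose digestion pattern distinguishes the two contexts:
    fragment multisets for equal-length contexts, cut counts otherwise."""
    out = set()
    for name, site in sites.items():
        if len(ref_ctx) == len(alt_ctx):
            if digest_fragments(ref_ctx, site) != digest_fragments(alt_ctx, site):
                out.add(name)
        else:
            if len(cut_positions(ref_ctx, site)) != len(cut_positions(alt_ctx, site)):
                out.add(name)
    return out


# ---------------------------------------------------------------------------
# Species classification


def brute_force_tags(
    species_states: dict[str, tuple[str, int | None]],
) -> tuple[set[str], set[frozenset[str]]]:
    """Enumerate intraspecific species and interspecific combinations from
    per-species states ('het' | ('hom', allele) | 'missing' | 'mixed')."""
    intra = {sp for sp, (s, _) in species_states.items() if s == "het"}
    hom = {sp: a for sp, (s, a) in species_states.items() if s == "hom"}
    inter = set()
    for k in range(2, min(4, len(hom)) + 1):
        for combo in combinations(sorted(hom), k):
            if len({hom[sp] for sp in combo}) >= 2:
                inter.add(frozenset(combo))
    return intra, inter
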