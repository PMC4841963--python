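"""SNP/INDEL kind split and intraspecific/interspecific classification of
multi-species variant sites.

A species is *heterozygous* at a site when any of its called samples is
het; it is *homozygous for allele a* when every called sample is a/a.  A
site is intraspecific for each heterozygous species, and interspecific for
every 2-4 species combination whose members are all homozygous-called with
at least two distinct alleles among them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SpeciesPanel, VariantRecord

__all__ = [
    "VariantKind",
    "ClassificationTags",
    "classify_kind",
    "species_allele_state",
    "classify_species",
    "count_by_category",
    "summary_from_counts",
    "interspecific_rollup",
    "combo_label",
]

MAX_COMBO_SIZE = 4


class VariantKind(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"


def classify_kind(v: VariantRecord) -> VariantKind:
    """SNP iff REF and every ALT are single bases; anything else is INDEL."""
    if len(v.ref) == 1 and all(len(a) == 1 for a in v.alts):
        return VariantKind.SNP
    return VariantKind.INDEL


@dataclass(frozen=True)
class ClassificationTags:
    intraspecific: frozenset[str]
    interspecific: frozenset[frozenset[str]]


def species_allele_state(
    genotypes: Sequence[tuple[int, int] | None],
) -> tuple[str, int | None]:
    """Collapse a species' sample genotypes to ('missing'|'het'|'hom'|'mixed', allele).

    'hom' carries the shared allele index; 'mixed' means all samples are
    homozygous but not for the same allele (counts as neither het nor hom).
    """
    called = [g for g in genotypes if g is not None]
    if not called:
        return ("missing", None)
    if any(a != b for a, b in called):
        return ("het", None)
    alleles = {g[0] for g in called}
    if len(alleles) == 1:
        return ("hom", alleles.pop())
    return ("mixed", None)


def classify_species(v: VariantRecord, panel: SpeciesPanel) -> ClassificationTags:
    """Tag one site with its intraspecific species and interspecific combos.

    Tags are not mutually exclusive: a site heterozygous in one species can
    still be interspecific for a combination of other species.  Species with
    no called genotype are excluded from every tag.
    """
    states = {
        sp: species_allele_state(gts)
        for sp, gts in v.species_genotypes(panel).items()
    }
    intraspecific = frozenset(sp for sp, (s, _) in states.items() if s == "het")
    hom = {sp: allele for sp, (s, allele) in states.items() if s == "hom"}
    inter: set[frozenset[str]] = set()
    hom_species = sorted(hom)
    for k in range(2, min(MAX_COMBO_SIZE, len(hom_species)) + 1):
        for combo in combinations(hom_species, k):
            if len({hom[sp] for sp in combo}) >= 2:
                inter.add(frozenset(combo))
    return ClassificationTags(intraspecific=intraspecific, interspecific=frozenset(inter))


def combo_label(combo: Iterable[str]) -> str:
    return "+".join(sorted(combo))


_SUMMARY_COLUMNS = [
    "category_type",
    "category",
    "indels",
    "snps",
    "total",
    "filtered_indels",
    "filtered_snps",
    "filtered",
]


def count_by_category(
    variants: Sequence[VariantRecord],
    panel: SpeciesPanel,
    tags: Sequence[ClassificationTags] | None = None,
    filtered_mask: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Build the SNV summary: one row per intraspecific species and per
    interspecific combination, with INDEL/SNP/total and filtered counts.

    ``filtered_mask`` marks variants that survived the suitability cascade
    (all zeros when not supplied).
    """
    if tags is None:
        tags = [classify_species(v, panel) for v in variants]
    if filtered_mask is None:
        filtered_mask = [False] * len(variants)
    counts: dict[tuple[str, str], dict[str, int]] = {}

    def bump(ctype: str, cat: str, kind: VariantKind, filtered: bool) -> None:
        c = counts.setdefault(
            (ctype, cat),
            {"indels": 0, "snps": 0, "filtered_indels": 0, "filtered_snps": 0},
        )
        key = "snps" if kind is VariantKind.SNP else "indels"
        c[key] += 1
        if filtered:
            c["filtered_" + key] += 1

    for v, tag, filt in zip(variants, tags, filtered_mask):
        kind = classify_kind(v)
        for sp in tag.intraspecific:
            bump("intraspecific", sp, kind, filt)
        for combo in tag.interspecific:
            bump("interspecific", combo_label(combo), kind, filt)

    rows = []
    species_order = list(panel.species_ids)
    ordered: list[tuple[str, str]] = [("intraspecific", sp) for sp in species_order]
    for k in range(2, MAX_COMBO_SIZE + 1):
        for combo in combinations(species_order, k):
            ordered.append(("interspecific", combo_label(combo)))
    for key in ordered:
        c = counts.get(
            key, {"indels": 0, "snps": 0, "filtered_indels": 0, "filtered_snps": 0}
        )
        rows.append(
            {
                "category_type": key[0],
                "category": key[1],
                "indels": c["indels"],
                "snps": c["snps"],
                "total": c["indels"] + c["snps"],
                "filtered_indels": c["filtered_indels"],
                "filtered_snps": c["filtered_snps"],
                "filtered": c["filtered_indels"] + c["filtered_snps"],
            }
        )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def summary_from_counts(
    entries: Iterable[tuple[str, Iterable[str] | str, int, int]],
) -> pd.DataFrame:
    """Build the same summary table from externally supplied per-kind counts.

    Each entry is (category_type, species-or-combination, indels, snps);
    used when published counts, rather than raw variants, are the input.
    """
    rows = []
    for ctype, cat, indels, snps in entries:
        label = cat if isinstance(cat, str) else combo_label(cat)
        rows.append(
            {
                "category_type": ctype,
                "category": label,
                "indels": int(indels),
                "snps": int(snps),
                "total": int(indels) + int(snps),
                "filtered_indels": 0,
                "filtered_snps": 0,
                "filtered": 0,
            }
        )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def interspecific_rollup(summary: pd.DataFrame, species: str) -> int:
    """Grand total of pairwise interspecific SNVs involving *species*."""
    total = 0
    for _, row in summary.iterrows():
        if row["category_type"] != "interspecific":
            continue
        members = row["category"].split("+")
        if len(members) == 2 and species in members:
            total += int(row["total"])
    return total
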