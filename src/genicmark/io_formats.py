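"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based, half-open.  The VCF boundary is the
single place where 1-based positions are converted; BED input is consumed
as 0-based half-open without conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

__all__ = [
    "TranscriptSeq",
    "OrfAnnotation",
    "SpeciesPanel",
    "VariantRecord",
    "read_fasta",
    "write_fasta",
    "read_orf_bed",
    "write_orf_bed",
    "read_panel",
    "read_vcf",
    "write_vcf",
    "write_marker_table",
    "read_marker_table",
]

_SEQ_ALPHABET = frozenset("ACGTN")
_ALLELE_ALPHABET = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class TranscriptSeq:
    """A transcript/unigene sequence; the coordinate frame for everything else."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("transcript id must be non-empty")
        if not self.seq:
            raise FormatError(f"transcript {self.id!r} has an empty sequence")
        seq = self.seq.upper()
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"transcript {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfAnnotation:
    """Principal ORF of a transcript, 0-based half-open, with strand."""

    transcript_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"ORF on {self.transcript_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"ORF strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SpeciesPanel:
    """Mapping of VCF sample columns to species identifiers."""

    sample_to_species: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.sample_to_species:
            raise FormatError("species panel is empty")
        object.__setattr__(self, "sample_to_species", dict(self.sample_to_species))

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.sample_to_species)

    @property
    def species_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for sp in self.sample_to_species.values():
            seen.setdefault(sp)
        return tuple(seen)

    def species_of(self, sample: str) -> str:
        try:
            return self.sample_to_species[sample]
        except KeyError:
            raise FormatError(f"sample {sample!r} is not in the species panel") from None

    def samples_of(self, species: str) -> tuple[str, ...]:
        return tuple(s for s, sp in self.sample_to_species.items() if sp == species)


Genotype = tuple[int, int]


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site in transcript coordinates with per-sample genotypes.

    ``pos`` is the 0-based offset of the first REF base.  ``genotypes`` maps
    sample id to an unphased pair of allele indices, or ``None`` when the
    call is missing.
    """

    transcript_id: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: Mapping[str, Genotype | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref or set(self.ref) - _ALLELE_ALPHABET:
            raise FormatError(
                f"{self.transcript_id}:{self.pos}: REF must be a non-empty ACGT string"
            )
        for a in self.alts:
            if not a or set(a) - _ALLELE_ALPHABET:
                raise FormatError(
                    f"{self.transcript_id}:{self.pos}: ALT must be a non-empty ACGT string"
                )
        n_alleles = 1 + len(self.alts)
        for sample, gt in self.genotypes.items():
            if gt is None:
                continue
            if any(not (0 <= a < n_alleles) for a in gt):
                raise FormatError(
                    f"{self.transcript_id}:{self.pos}: genotype {gt} of sample "
                    f"{sample!r} indexes a non-existent allele"
                )
        object.__setattr__(self, "alts", tuple(self.alts))
        object.__setattr__(self, "genotypes", dict(self.genotypes))

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)

    def species_genotypes(
        self, panel: SpeciesPanel
    ) -> dict[str, list[Genotype | None]]:
        """Group this record's genotypes by species according to *panel*."""
        out: dict[str, list[Genotype | None]] = {sp: [] for sp in panel.species_ids}
        for sample, gt in self.genotypes.items():
            out[panel.species_of(sample)].append(gt)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[TranscriptSeq]:
    """Read transcripts from FASTA, uppercasing and enforcing unique ids."""
    path = Path(path)
    records: list[TranscriptSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(TranscriptSeq(id=rec.id, seq=str(rec.seq)))
    return records


def write_fasta(transcripts: Iterable[TranscriptSeq], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for ts in transcripts:
            fh.write(f">{ts.id}\n")
            for i in range(0, ts.length, width):
                fh.write(ts.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED (ORFs)


def read_orf_bed(path: str | Path) -> dict[str, OrfAnnotation]:
    """Read principal-ORF annotations from BED6 (name/score columns ignored).

    A 4-column variant (chrom, start, end, strand) is also accepted.
    At most one ORF per transcript is allowed.
    """
    path = Path(path)
    orfs: dict[str, OrfAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 6:
                strand = fields[5]
            elif len(fields) == 4:
                strand = fields[3]
            else:
                raise FormatError(f"{path}:{lineno}: expected BED6 or 4-column BED")
            tid, start, end = fields[0], int(fields[1]), int(fields[2])
            if tid in orfs:
                raise FormatError(f"{path}:{lineno}: duplicate ORF for transcript {tid!r}")
            orfs[tid] = OrfAnnotation(transcript_id=tid, start=start, end=end, strand=strand)
    return orfs


def write_orf_bed(orfs: Iterable[OrfAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(
                f"{orf.transcript_id}\t{orf.start}\t{orf.end}\tORF\t0\t{orf.strand}\n"
            )


# ---------------------------------------------------------------------------
# Species panel


def read_panel(path: str | Path) -> SpeciesPanel:
    """Read a two-column TSV (sample_id, species_id) into a SpeciesPanel."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            sample, species = fields
            if sample in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            mapping[sample] = species
    return SpeciesPanel(mapping)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, panel: SpeciesPanel) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, converting POS to 0-based.

    Every sample column must be declared in *panel*; multi-allelic sites are
    kept intact; missing genotypes are represented as ``None``.
    """
    path = Path(path)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    for s in samples:
        if s not in panel.sample_to_species:
            raise FormatError(f"VCF sample {s!r} is absent from the species panel")
    records: list[VariantRecord] = []
    for i, v in enumerate(vcf, start=1):
        genotypes: dict[str, Genotype | None] = {}
        try:
            gts = v.genotypes
        except Exception as exc:  # pragma: no cover - defensive
            raise FormatError(f"{path}: malformed genotypes at record {i}") from exc
        for sample, gt in zip(samples, gts):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                genotypes[sample] = None
            else:
                genotypes[sample] = (a, b)
        records.append(
            VariantRecord(
                transcript_id=v.CHROM,
                pos=v.POS - 1,
                ref=v.REF,
                alts=tuple(v.ALT),
                genotypes=genotypes,
            )
        )
    vcf.close()
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Sequence[TranscriptSeq] | None = None,
    info_fields: Sequence[Mapping[str, str]] | None = None,
) -> None:
    """Write VariantRecords as an uncompressed VCF v4.2 text file.

    ``info_fields`` optionally supplies a per-record mapping serialized into
    the INFO column (keys must be declared by the caller's conventions).
    """
    lines = ["##fileformat=VCFv4.2"]
    if contigs is not None:
        for ts in contigs:
            lines.append(f"##contig=<ID={ts.id},length={ts.length}>")
    if info_fields is not None:
        keys = sorted({k for m in info_fields for k in m})
        for k in keys:
            lines.append(
                f'##INFO=<ID={k},Number=.,Type=String,Description="{k} tag">'
            )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(samples)
    lines.append("\t".join(header))
    for i, rec in enumerate(records):
        if info_fields is not None and info_fields[i]:
            info = ";".join(f"{k}={v}" for k, v in sorted(info_fields[i].items()))
        else:
            info = "."
        row = [
            rec.transcript_id,
            str(rec.pos + 1),
            ".",
            rec.ref,
            ",".join(rec.alts) if rec.alts else ".",
            ".",
            ".",
            info,
            "GT",
        ]
        for sample in samples:
            gt = rec.genotypes.get(sample)
            row.append("./." if gt is None else f"{gt[0]}/{gt[1]}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Marker tables (generic TSV)


def write_marker_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a marker table as TSV with a deterministic column order."""
    frame.to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a marker table written by :func:`write_marker_table`.

    All columns come back as strings; typed accessors in the owning modules
    re-parse what they need.  Empty fields round-trip as empty strings.
    """
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def serialize_flags(flag_names: Sequence[str]) -> str:
    """VCF-FILTER-style serialization: 'PASS' or ';'-joined flag names."""
    return ";".join(flag_names) if flag_names else "PASS"


def parse_flags(text: str) -> tuple[str, ...]:
    if text in ("PASS", ""):
        return ()
    return tuple(text.split(";"))
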