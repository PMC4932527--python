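"""Genome, variant, and interval I/O plus indel normalization.

Conventions used throughout the package:

* internal intervals are 0-based, half-open ``[start, end)``;
* VCF positions are 1-based and refer to the first REF base;
* conversion between the two happens only at the I/O boundary.

Indel normalization (parsimony + left alignment) lives here because every
downstream stage — private-variant subtraction in particular — must compare
*physical edits*, not the arbitrary textual encoding a caller happened to
emit.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "GenomeAssembly",
    "VariantRecord",
    "MaskSet",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_tsv",
    "write_tsv",
    "normalize_indel",
    "is_normalized",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """A set of named chromosome sequences over the alphabet {A,C,G,T,N}."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"non-IUPAC character {seq[pos]!r} in {name} at 0-based "
                    f"position {pos}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice ``[start, end)`` of a chromosome, clipped to its bounds."""
        seq = self.sequences[chrom]
        return seq[max(0, start):max(0, end)]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class VariantRecord:
    """One ALT allele of a variant call, attributed to a set of samples.

    ``pos`` is the 1-based position of the first REF base (VCF convention).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) > len(self.alt):
            return "deletion"
        if len(self.ref) < len(self.alt):
            return "insertion"
        return "complex"

    @property
    def is_indel(self) -> bool:
        return self.vtype in ("insertion", "deletion")

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open interval spanned by the REF allele."""
        start = self.pos - 1
        return start, start + len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the call irrespective of sample attribution."""
        return (self.chrom, self.pos, self.ref, self.alt)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class MaskSet:
    """Per-chromosome merged, sorted 0-based half-open intervals (e.g. a
    RepeatMasker/WindowMasker track loaded from BED)."""

    intervals: dict[str, list[tuple[int, int]]]
    label: str = "mask"

    def __post_init__(self) -> None:
        self.intervals = {
            chrom: _merge_intervals(ivs) for chrom, ivs in self.intervals.items()
        }

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.intervals.get(chrom)
        if ivs is None:
            return False
        # rightmost interval starting at or before `end`
        i = bisect_right(ivs, (end, float("inf"))) - 1
        while i >= 0 and ivs[i][1] > start:
            if ivs[i][0] < end:
                return True
            i -= 1
        return False


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a (multi-record, multi-line) FASTA into a :class:`GenomeAssembly`.

    Headers are truncated at the first whitespace; sequence is uppercased.
    Duplicate headers, empty files, and non-IUPAC characters are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA header {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeAssembly(sequences)


def write_fasta(genome: GenomeAssembly, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome.sequences:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path,
    sample_label: str,
    keep_filters: Sequence[str] = ("PASS", "."),
) -> list[VariantRecord]:
    """Read a VCF, split multi-allelic records, and tag with ``sample_label``.

    Records whose FILTER contains any value outside ``keep_filters`` are
    dropped; symbolic / breakend ALTs are skipped with a warning.
    """
    keep = set(keep_filters)
    out: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for n, rec in enumerate(vcf, start=1):
            try:
                filters = list(rec.filter.keys())
                if filters and not set(filters) <= keep:
                    continue
                if not filters and "." not in keep:
                    continue
                if rec.alts is None:
                    continue
                for alt in rec.alts:
                    alt = str(alt).upper()
                    if not set(alt) <= VALID_BASES:
                        log.warning(
                            "skipping symbolic/non-sequence ALT %r at %s:%s",
                            alt, rec.chrom, rec.pos,
                        )
                        continue
                    out.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref.upper(),
                            alt=alt,
                            samples=frozenset({sample_label}),
                        )
                    )
            except (ValueError, AttributeError) as exc:
                raise ValueError(
                    f"malformed VCF record #{n} in {path}: {exc}"
                ) from exc
    return out


def write_vcf(
    records: Iterable[VariantRecord],
    contig_lengths: Mapping[str, int],
    path: str | Path,
    source: str = "otscreen",
) -> None:
    """Write records as a minimal sites-only VCF 4.2, sorted by (chrom, pos).

    The header carries no timestamp so that regeneration is byte-stable.
    """
    recs = sorted(records, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in recs:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# BED / TSV


def read_bed(path: str | Path, label: str = "mask") -> MaskSet:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {n} in {path}: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            intervals.setdefault(chrom, []).append((start, end))
    return MaskSet(intervals, label=label)


def write_bed(
    intervals: Iterable[tuple[str, int, int]] | MaskSet, path: str | Path
) -> None:
    if isinstance(intervals, MaskSet):
        rows = [
            (chrom, s, e)
            for chrom, ivs in intervals.intervals.items()
            for s, e in ivs
        ]
    else:
        rows = list(intervals)
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, s, e in rows:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_tsv(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Indel normalization


def normalize_indel(v: VariantRecord, genome: GenomeAssembly) -> VariantRecord:
    """Return the parsimonious, left-aligned representation of ``v``.

    The procedure is the standard one: trim shared suffix bases (extending
    to the left through the reference when an allele would empty), trim the
    shared prefix keeping one anchor base, and repeat until no change.  The
    result is idempotent, and any two VCF encodings of the same physical
    edit map to the same record.
    """
    if v.chrom not in genome:
        raise ValueError(f"unknown chromosome {v.chrom!r}")
    seq = genome.sequences[v.chrom]
    start, end = v.interval
    if end > len(seq):
        raise ValueError(
            f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} exceeds chromosome "
            f"length {len(seq)}"
        )
    if seq[start:end] != v.ref:
        raise ValueError(
            f"REF allele {v.ref!r} disagrees with genome sequence "
            f"{seq[start:end]!r} at {v.chrom}:{v.pos}"
        )

    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref[-1] == alt[-1] and pos > 1:
            # allele would become empty: extend left through the reference
            b = seq[pos - 2]
            ref = b + ref[:-1]
            alt = b + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(v, pos=pos, ref=ref, alt=alt)


def is_normalized(v: VariantRecord, genome: GenomeAssembly) -> bool:
    return normalize_indel(v, genome) == v
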