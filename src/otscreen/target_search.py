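"""Genome-wide prediction of Cas9/gRNA target loci.

A *site* is any 20-bp window, on either strand, whose 3'-adjacent 3-mer
matches one of the allowed PAM patterns (NGG by default, optionally the
weaker NAG) and whose Hamming distance to the guide protospacer stays
within separate mismatch budgets for the PAM-proximal *seed* region and
the PAM-distal *non-seed* region.  Mismatches in the seed region are the
main determinant of Cas9 specificity, hence the two-part accounting.

The scan is exact: correctness is defined against an exhaustive
sliding-window comparison, and the vectorized implementation here is only
an optimization of that definition.  PAM bases are matched against IUPAC
patterns and never counted in either mismatch budget; an ``N`` in the
genome counts as a mismatch inside the protospacer window and disqualifies
a PAM position outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomeAssembly, read_tsv, write_tsv

__all__ = [
    "Guide",
    "ScanParams",
    "PredictedSite",
    "reverse_complement",
    "count_mismatches",
    "find_target_sites",
    "mismatch_bin_counts",
    "sites_to_dataframe",
    "write_sites_tsv",
    "read_sites_tsv",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, with N -> N."""
    if not set(seq) <= {"A", "C", "G", "T", "N"}:
        bad = set(seq) - {"A", "C", "G", "T", "N"}
        raise ValueError(f"invalid character(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Guide:
    """A gRNA protospacer, written 5'->3' (PAM-distal first), with the PAM
    patterns accepted on its 3' side and the length of the PAM-proximal
    seed region."""

    name: str
    protospacer: str
    pam_patterns: tuple[str, ...] = ("NGG", "NAG")
    seed_length: int = 12

    def __post_init__(self) -> None:
        if not set(self.protospacer) <= {"A", "C", "G", "T"}:
            raise ValueError("protospacer must be over {A,C,G,T}")
        if not self.pam_patterns:
            raise ValueError("at least one PAM pattern required")
        for p in self.pam_patterns:
            if len(p) != 3 or not set(p) <= set(IUPAC):
                raise ValueError(f"PAM pattern {p!r} must be 3 IUPAC letters")
        if not 1 <= self.seed_length < len(self.protospacer):
            raise ValueError(
                f"seed_length {self.seed_length} out of range for a "
                f"{len(self.protospacer)}-nt protospacer"
            )


@dataclass(frozen=True)
class ScanParams:
    """Mismatch budgets for a scan.  ``pam_patterns``/``seed_length`` of
    ``None`` defer to the guide's own values."""

    max_seed_mm: int = 3
    max_nonseed_mm: int = 6
    pam_patterns: tuple[str, ...] | None = None
    seed_length: int | None = None
    exclude_n_windows: bool = False

    def resolve(self, guide: Guide) -> tuple[tuple[str, ...], int]:
        pams = self.pam_patterns if self.pam_patterns is not None else guide.pam_patterns
        seed = self.seed_length if self.seed_length is not None else guide.seed_length
        if not 0 <= self.max_seed_mm <= seed:
            raise ValueError("max_seed_mm out of range")
        if not 0 <= self.max_nonseed_mm <= len(guide.protospacer) - seed:
            raise ValueError("max_nonseed_mm out of range")
        return tuple(pams), seed


@dataclass(frozen=True)
class PredictedSite:
    """A guide-homologous locus.  ``start``/``end`` delimit the protospacer-
    homologous segment only (0-based, half-open, + strand coordinates); the
    PAM lies outside the interval and is recorded in its own fields."""

    chrom: str
    start: int
    end: int
    strand: str
    matched_seq: str
    pam_observed: str
    pam_class: str
    seed_mm: int
    nonseed_mm: int

    @property
    def total_mm(self) -> int:
        return self.seed_mm + self.nonseed_mm

    @property
    def cut_site(self) -> int:
        """0-based coordinate of the blunt cut, 3 bp PAM-proximal."""
        return self.end - 3 if self.strand == "+" else self.start + 3


def count_mismatches(
    protospacer: str, locus_seq: str, seed_length: int
) -> tuple[int, int]:
    """Positionwise Hamming counts partitioned at the seed boundary.

    Both sequences must be in protospacer orientation (PAM-distal first);
    the seed comprises the ``seed_length`` PAM-proximal (final) positions.
    ``N`` in the locus always counts as a mismatch.
    """
    if len(protospacer) != len(locus_seq):
        raise ValueError(
            f"length disagreement: {len(protospacer)} vs {len(locus_seq)}"
        )
    boundary = len(protospacer) - seed_length
    seed_mm = nonseed_mm = 0
    for i, (p, g) in enumerate(zip(protospacer, locus_seq)):
        if g != p or g == "N":
            if i >= boundary:
                seed_mm += 1
            else:
                nonseed_mm += 1
    return seed_mm, nonseed_mm


def _pam_allowed_bytes(pattern: str) -> list[np.ndarray]:
    """Per-position allowed byte values; genome N matches no pattern letter."""
    return [
        np.frombuffer(IUPAC[letter].encode(), dtype=np.uint8)
        for letter in pattern
    ]


def _scan_oriented(
    seq: str,
    proto: str,
    pams: Sequence[str],
    seed_len: int,
    max_seed: int,
    max_nonseed: int,
    exclude_n: bool,
) -> list[tuple[int, int, int, int]]:
    """Scan one orientation of one chromosome.

    Returns tuples (window_start, seed_mm, nonseed_mm, pam_index) in the
    coordinates of ``seq`` as given.
    """
    W, P = len(proto), 3
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(arr) - W - P + 1
    if n <= 0:
        return []
    proto_b = proto.encode("ascii")
    n_byte = ord("N")

    seed_mm = np.zeros(n, dtype=np.int16)
    nonseed_mm = np.zeros(n, dtype=np.int16)
    boundary = W - seed_len
    for j in range(W):
        col = arr[j:j + n]
        mm = (col != proto_b[j]) | (col == n_byte)
        if j >= boundary:
            seed_mm += mm
        else:
            nonseed_mm += mm

    pam_idx = np.full(n, -1, dtype=np.int8)
    for pi in reversed(range(len(pams))):
        ok = np.ones(n, dtype=bool)
        for k, allowed in enumerate(_pam_allowed_bytes(pams[pi])):
            ok &= np.isin(arr[W + k:W + k + n], allowed)
        pam_idx[ok] = pi

    keep = (pam_idx >= 0) & (seed_mm <= max_seed) & (nonseed_mm <= max_nonseed)
    if exclude_n:
        has_n = np.zeros(n, dtype=bool)
        cs = np.concatenate(([0], np.cumsum(arr == n_byte)))
        has_n = (cs[W + P:W + P + n] - cs[:n]) > 0
        keep &= ~has_n
    idx = np.nonzero(keep)[0]
    return [
        (int(i), int(seed_mm[i]), int(nonseed_mm[i]), int(pam_idx[i]))
        for i in idx
    ]


def find_target_sites(
    genome: GenomeAssembly, guide: Guide, params: ScanParams = ScanParams()
) -> list[PredictedSite]:
    """Report every qualifying site on both strands, exactly once, in
    deterministic (chrom, start, strand) order.

    Coordinates always refer to the + reference strand; ``matched_seq`` and
    ``pam_observed`` are given in protospacer orientation.
    """
    pams, seed_len = params.resolve(guide)
    proto = guide.protospacer
    W = len(proto)
    sites: list[PredictedSite] = []
    for chrom in genome.sequences:
        fwd = genome.sequences[chrom]
        L = len(fwd)
        for strand, seq in (("+", fwd), ("-", reverse_complement(fwd))):
            hits = _scan_oriented(
                seq, proto, pams, seed_len,
                params.max_seed_mm, params.max_nonseed_mm,
                params.exclude_n_windows,
            )
            for s, smm, nmm, pi in hits:
                if strand == "+":
                    start = s
                else:
                    start = L - (s + W)
                sites.append(
                    PredictedSite(
                        chrom=chrom,
                        start=start,
                        end=start + W,
                        strand=strand,
                        matched_seq=seq[s:s + W],
                        pam_observed=seq[s + W:s + W + 3],
                        pam_class=pams[pi],
                        seed_mm=smm,
                        nonseed_mm=nmm,
                    )
                )
    sites.sort(key=lambda t: (t.chrom, t.start, t.strand))
    return sites


def mismatch_bin_counts(sites: Iterable[PredictedSite]) -> pd.DataFrame:
    """Site counts per (seed_mm, nonseed_mm, pam_class) cell.

    The tidy table sums to the number of input sites; it is the tabular
    equivalent of the similarity-grid figure a scan is usually summarized
    with.
    """
    rows = [(s.seed_mm, s.nonseed_mm, s.pam_class) for s in sites]
    df = pd.DataFrame(rows, columns=["seed_mm", "nonseed_mm", "pam_class"])
    if df.empty:
        return pd.DataFrame(
            columns=["seed_mm", "nonseed_mm", "pam_class", "count"]
        )
    out = (
        df.value_counts(["seed_mm", "nonseed_mm", "pam_class"])
        .rename("count")
        .reset_index()
        .sort_values(["seed_mm", "nonseed_mm", "pam_class"])
        .reset_index(drop=True)
    )
    return out


_SITE_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "pam_observed", "pam_class", "matched_seq", "seed_mm", "nonseed_mm",
]


def sites_to_dataframe(
    sites: Sequence[PredictedSite], guide_name: str = "guide"
) -> pd.DataFrame:
    """BED6-compatible table (name = guide:seed_mm:nonseed_mm, score = total
    mismatches) with extended columns."""
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "name": f"{guide_name}:{s.seed_mm}:{s.nonseed_mm}",
            "score": s.total_mm,
            "strand": s.strand,
            "pam_observed": s.pam_observed,
            "pam_class": s.pam_class,
            "matched_seq": s.matched_seq,
            "seed_mm": s.seed_mm,
            "nonseed_mm": s.nonseed_mm,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)


def write_sites_tsv(
    sites: Sequence[PredictedSite], path: str | Path, guide_name: str = "guide"
) -> None:
    write_tsv(sites_to_dataframe(sites, guide_name), path)


def read_sites_tsv(path: str | Path) -> list[PredictedSite]:
    df = read_tsv(path)
    return [
        PredictedSite(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            matched_seq=str(r.matched_seq),
            pam_observed=str(r.pam_observed),
            pam_class=str(r.pam_class),
            seed_mm=int(r.seed_mm),
            nonseed_mm=int(r.nonseed_mm),
        )
        for r in df.itertuples(index=False)
    ]
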