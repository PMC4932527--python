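"""Ranking of candidate off-target sites, validation selection, and
amplicon extraction.

Candidates are ordered by similarity to the guide — ascending
lexicographically on (seed mismatches, non-seed mismatches, distance to
the predicted locus) — because seed mismatches dominate Cas9 activity,
non-seed mismatches matter next, and a closer indel is more plausibly the
product of a cut at that locus.  The top of the list (strictly fewer than
``seed_mm_max_exclusive`` seed mismatches, default 2) is flagged for
wet-lab validation, and a ~600-bp amplicon window centered on each
selected indel is extracted for PCR/Sanger follow-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .core_io import GenomeAssembly, VariantRecord
from .target_search import PredictedSite, mismatch_bin_counts
from .variant_filters import FILTER_ORDER, FilterTrace

log = logging.getLogger(__name__)

__all__ = [
    "CandidateOTS",
    "ValidationParams",
    "rank_ots",
    "select_for_validation",
    "extract_validation_amplicon",
    "summarize_run",
    "candidates_to_dataframe",
]


@dataclass(frozen=True)
class CandidateOTS:
    """A surviving private indel joined to its nearest predicted site."""

    variant: VariantRecord
    site: PredictedSite
    distance: int
    rank: int | None = None
    selected: bool = False

    @property
    def sort_key(self):
        return (
            self.site.seed_mm,
            self.site.nonseed_mm,
            self.distance,
            self.variant.chrom,
            self.variant.pos,
        )


@dataclass(frozen=True)
class ValidationParams:
    seed_mm_max_exclusive: int = 2
    amplicon_bp: int = 600

    def __post_init__(self) -> None:
        if self.seed_mm_max_exclusive < 0 or self.amplicon_bp <= 0:
            raise ValueError("validation parameters must be positive")


def rank_ots(candidates: Sequence[CandidateOTS]) -> list[CandidateOTS]:
    """Ascending lexicographic order on (seed_mm, nonseed_mm, distance),
    ties broken by (chrom, pos); ranks assigned 1..n."""
    ordered = sorted(candidates, key=lambda c: c.sort_key)
    return [replace(c, rank=i) for i, c in enumerate(ordered, start=1)]


def select_for_validation(
    ranked: Sequence[CandidateOTS], params: ValidationParams = ValidationParams()
) -> list[CandidateOTS]:
    """Flag candidates with strictly fewer than ``seed_mm_max_exclusive``
    seed mismatches, preserving rank order; optionally everything below a
    rank cap could be taken, but no cap is applied here."""
    return [
        replace(c, selected=True)
        for c in ranked
        if c.site.seed_mm < params.seed_mm_max_exclusive
    ]


def extract_validation_amplicon(
    genome: GenomeAssembly, candidate: CandidateOTS, amplicon_bp: int = 600
) -> tuple[tuple[str, int, int], str]:
    """Window of total span ``amplicon_bp`` centered on the variant,
    clipped at contig edges (clipping is logged), plus its sequence."""
    v = candidate.variant
    if v.chrom not in genome:
        raise ValueError(f"unknown chromosome {v.chrom!r}")
    length = len(genome.sequences[v.chrom])
    s, e = v.interval
    if s >= length:
        raise ValueError(f"variant at {v.chrom}:{v.pos} beyond contig end")
    center = (s + e) // 2
    start = center - amplicon_bp // 2
    end = start + amplicon_bp
    if start < 0 or end > length:
        start_c, end_c = max(0, start), min(length, end)
        log.warning(
            "amplicon window [%d,%d) on %s clipped to [%d,%d)",
            start, end, v.chrom, start_c, end_c,
        )
        start, end = start_c, end_c
    return (v.chrom, start, end), genome.fetch(v.chrom, start, end)


def candidates_to_dataframe(ranked: Sequence[CandidateOTS]) -> pd.DataFrame:
    cols = [
        "rank", "chrom", "pos", "ref", "alt", "vtype",
        "site_start", "site_end", "strand", "pam_class",
        "seed_mm", "nonseed_mm", "distance", "selected",
    ]
    rows = [
        {
            "rank": c.rank,
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "vtype": c.variant.vtype,
            "site_start": c.site.start,
            "site_end": c.site.end,
            "strand": c.site.strand,
            "pam_class": c.site.pam_class,
            "seed_mm": c.site.seed_mm,
            "nonseed_mm": c.site.nonseed_mm,
            "distance": c.distance,
            "selected": c.selected,
        }
        for c in ranked
    ]
    return pd.DataFrame(rows, columns=cols)


def summarize_run(
    sites: Sequence[PredictedSite],
    traces: Sequence[FilterTrace],
    ranked: Sequence[CandidateOTS],
) -> dict[str, pd.DataFrame]:
    """Three report tables for one pipeline run.

    * ``site_bins`` — predicted-site counts per (seed_mm, nonseed_mm,
      pam_class) cell;
    * ``attrition`` — sequential first-failure accounting over the filter
      stages: input count, failures attributed to each stage in
      :data:`FILTER_ORDER` order, and the remaining count, which
      telescopes to the survivor count;
    * ``candidates`` — the ranked candidate table.
    """
    site_bins = mismatch_bin_counts(sites)

    stages = ("vtype",) + FILTER_ORDER
    remaining = len(traces)
    rows = [{"stage": "input", "failed": 0, "remaining": remaining}]
    pool = list(traces)
    for stage in stages:
        failed = [t for t in pool if stage in t.flags and not t.flags[stage]]
        pool = [t for t in pool if not (stage in t.flags and not t.flags[stage])]
        remaining -= len(failed)
        rows.append({"stage": stage, "failed": len(failed), "remaining": remaining})
    attrition = pd.DataFrame(rows, columns=["stage", "failed", "remaining"])

    return {
        "site_bins": site_bins,
        "attrition": attrition,
        "candidates": candidates_to_dataframe(ranked),
    }
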