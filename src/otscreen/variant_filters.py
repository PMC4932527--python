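"""The indel filtering cascade that turns raw mutant calls into candidate
off-target sites.

Five pure predicates are applied to every mutant indel:

1. *privacy* — the normalized allele must be absent from the wild-type
   control, every control-panel genome, and the variant database;
2. *repeat* — the REF-spanned interval must not intersect the repeat mask;
3. *homopolymer* — neither flank (``homopolymer_k`` bp immediately up- or
   downstream of the REF interval) may be a single-base run;
4. *gc* — the GC fraction of the flanking sequence (``gc_window`` bp total,
   half on each side, variant bases excluded) must lie within
   ``(gc_lo, gc_hi)`` — bounds are exclusive for survival, i.e. exclusion
   uses strict inequalities;
5. *proximity* — the variant must lie within ``proximity_bp`` (inclusive)
   of a predicted guide-homologous locus.

Because each predicate is a pure function of the variant and fixed context,
the surviving set is independent of application order; the cascade is an
intersection, and the per-variant trace records every verdict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_io import (
    GenomeAssembly,
    MaskSet,
    VariantRecord,
    is_normalized,
)
from .target_search import PredictedSite

log = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "FilterTrace",
    "FILTER_ORDER",
    "select_private_indels",
    "filter_repeat",
    "filter_homopolymer",
    "filter_gc",
    "annotate_proximity",
    "nearest_site",
    "run_filter_cascade",
]

#: Stage order used for attrition reporting; the survivor set does not
#: depend on it.
FILTER_ORDER = ("privacy", "repeat", "homopolymer", "gc", "proximity")


@dataclass(frozen=True)
class FilterParams:
    homopolymer_k: int = 10
    gc_window: int = 100          # total flanking span, half per side
    gc_lo: float = 0.20
    gc_hi: float = 0.60
    proximity_bp: int = 500
    indels_only: bool = True
    privacy_position_only: bool = False
    distance_anchor: str = "protospacer"   # or "cutsite"

    def __post_init__(self) -> None:
        if self.homopolymer_k < 2:
            raise ValueError("homopolymer_k must be >= 2")
        if self.gc_window <= 0 or self.gc_window % 2:
            raise ValueError("gc_window must be positive and even")
        if not 0 <= self.gc_lo < self.gc_hi <= 1:
            raise ValueError("require 0 <= gc_lo < gc_hi <= 1")
        if self.proximity_bp <= 0:
            raise ValueError("proximity_bp must be positive")
        if self.distance_anchor not in ("protospacer", "cutsite"):
            raise ValueError("distance_anchor must be protospacer|cutsite")


@dataclass
class FilterTrace:
    """Per-variant audit record: one verdict per applied filter."""

    variant: VariantRecord
    flags: dict[str, bool] = field(default_factory=dict)
    fail_reason: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.flags.values())

    @property
    def failed_filters(self) -> tuple[str, ...]:
        return tuple(name for name, ok in self.flags.items() if not ok)


# ---------------------------------------------------------------------------
# Privacy


def _privacy_key(v: VariantRecord, position_only: bool):
    return (v.chrom, v.pos) if position_only else v.key


def select_private_indels(
    mutant: Sequence[VariantRecord],
    controls: Sequence[Iterable[VariantRecord]],
    db: Iterable[VariantRecord],
    genome: GenomeAssembly | None = None,
    position_only: bool = False,
) -> list[VariantRecord]:
    """Mutant indels whose normalized identity appears in no control set and
    not in the database.

    All inputs must already be normalized; when ``genome`` is supplied this
    is verified by re-normalizing and any violation is an error.
    """
    if genome is not None:
        for v in mutant:
            if not is_normalized(v, genome):
                raise ValueError(
                    f"un-normalized input variant {v.chrom}:{v.pos} "
                    f"{v.ref}>{v.alt}"
                )
    excluded = set()
    for cset in list(controls) + [db]:
        for v in cset:
            excluded.add(_privacy_key(v, position_only))
    return [v for v in mutant if _privacy_key(v, position_only) not in excluded]


def _trace_all(
    variants: Sequence[VariantRecord], name: str, verdicts, reasons
) -> list[FilterTrace]:
    out = []
    for v, ok, why in zip(variants, verdicts, reasons):
        t = FilterTrace(v, flags={name: ok})
        if not ok:
            t.fail_reason[name] = why
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# Context filters


def _repeat_verdict(v: VariantRecord, mask: MaskSet) -> tuple[bool, str]:
    if v.chrom not in mask.intervals:
        log.info("chromosome %s absent from mask; treated as unmasked", v.chrom)
        return True, ""
    s, e = v.interval
    if mask.overlaps(v.chrom, s, e):
        return False, f"REF interval [{s},{e}) intersects {mask.label}"
    return True, ""


def filter_repeat(
    variants: Sequence[VariantRecord], mask: MaskSet
) -> list[FilterTrace]:
    """Fail a variant iff its REF-spanned interval intersects the mask."""
    verdicts = [_repeat_verdict(v, mask) for v in variants]
    return _trace_all(
        variants, "repeat", [ok for ok, _ in verdicts], [w for _, w in verdicts]
    )


def _homopolymer_verdict(
    v: VariantRecord, genome: GenomeAssembly, k: int
) -> tuple[bool, str]:
    s, e = v.interval
    up = genome.fetch(v.chrom, s - k, s)
    down = genome.fetch(v.chrom, e, e + k)
    for name, flank in (("upstream", up), ("downstream", down)):
        if len(flank) < k:
            log.warning(
                "%s flank of %s:%s truncated to %d bp by contig edge; "
                "homopolymer filter passes",
                name, v.chrom, v.pos, len(flank),
            )
            continue
        if len(set(flank)) == 1:
            return False, f"{name} {k}-bp flank is a {flank[0]}-homopolymer"
    return True, ""


def filter_homopolymer(
    variants: Sequence[VariantRecord], genome: GenomeAssembly, k: int = 10
) -> list[FilterTrace]:
    """Fail iff either the k bases immediately upstream or downstream of the
    REF interval are a single-base run (either flank suffices)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    verdicts = [_homopolymer_verdict(v, genome, k) for v in variants]
    return _trace_all(
        variants, "homopolymer",
        [ok for ok, _ in verdicts], [w for _, w in verdicts],
    )


def _gc_verdict(
    v: VariantRecord, genome: GenomeAssembly, params: FilterParams
) -> tuple[bool, str]:
    w = params.gc_window // 2
    s, e = v.interval
    left = genome.fetch(v.chrom, s - w, s)
    right = genome.fetch(v.chrom, e, e + w)
    flank = left + right
    if len(flank) < params.gc_window:
        log.warning(
            "GC window of %s:%s truncated to %d bp by contig edge",
            v.chrom, v.pos, len(flank),
        )
    counted = [b for b in flank if b != "N"]
    if not counted:
        log.warning("GC window of %s:%s contains no A/C/G/T; passes", v.chrom, v.pos)
        return True, ""
    frac = sum(b in "GC" for b in counted) / len(counted)
    if frac < params.gc_lo:
        return False, f"flanking GC {frac:.3f} < {params.gc_lo}"
    if frac > params.gc_hi:
        return False, f"flanking GC {frac:.3f} > {params.gc_hi}"
    return True, ""


def filter_gc(
    variants: Sequence[VariantRecord],
    genome: GenomeAssembly,
    params: FilterParams = FilterParams(),
) -> list[FilterTrace]:
    """Fail iff flanking GC fraction is strictly below ``gc_lo`` or strictly
    above ``gc_hi``; N bases are excluded from both numerator and
    denominator, and exact boundary values pass."""
    verdicts = [_gc_verdict(v, genome, params) for v in variants]
    return _trace_all(
        variants, "gc", [ok for ok, _ in verdicts], [w for _, w in verdicts]
    )


# ---------------------------------------------------------------------------
# Proximity


def _site_anchor_interval(site: PredictedSite, anchor: str) -> tuple[int, int]:
    if anchor == "cutsite":
        c = site.cut_site
        return c, c
    return site.start, site.end


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp between nearest edges of two half-open intervals; 0 if they touch
    or intersect (zero-length intervals supported)."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def nearest_site(
    v: VariantRecord,
    sites: Sequence[PredictedSite],
    anchor: str = "protospacer",
) -> tuple[PredictedSite | None, float]:
    """Closest predicted site on the variant's chromosome (ties resolved to
    the smaller coordinate), with its edge-to-edge distance in bp."""
    s, e = v.interval
    best: PredictedSite | None = None
    best_d = math.inf
    for site in sites:
        if site.chrom != v.chrom:
            continue
        a0, a1 = _site_anchor_interval(site, anchor)
        d = _gap(s, e, a0, a1)
        if d < best_d or (d == best_d and best is not None and site.start < best.start):
            best, best_d = site, d
    return best, best_d


def annotate_proximity(
    variants: Sequence[VariantRecord],
    sites: Sequence[PredictedSite],
    proximity_bp: int = 500,
    anchor: str = "protospacer",
) -> list[tuple[VariantRecord, PredictedSite, int]]:
    """Join each variant to its nearest predicted site and keep those within
    ``proximity_bp`` (inclusive).  Variants on chromosomes with no site are
    dropped (distance infinite, logged)."""
    out = []
    for v in variants:
        site, d = nearest_site(v, sites, anchor)
        if site is None:
            log.info(
                "no predicted site on %s; variant at %s dropped "
                "(distance = inf)", v.chrom, v.pos,
            )
            continue
        if d <= proximity_bp:
            out.append((v, site, int(d)))
    return out


# ---------------------------------------------------------------------------
# Cascade


def run_filter_cascade(
    mutant: Sequence[VariantRecord],
    controls: Sequence[Iterable[VariantRecord]],
    db: Iterable[VariantRecord],
    mask: MaskSet,
    genome: GenomeAssembly,
    sites: Sequence[PredictedSite],
    params: FilterParams = FilterParams(),
) -> tuple[list[tuple[VariantRecord, PredictedSite, int]], list[FilterTrace]]:
    """Apply all filters to every mutant variant.

    Returns ``(survivors, traces)`` where each survivor is a
    ``(variant, nearest_site, distance)`` triple and ``traces`` holds one
    audit record per input variant.  When ``params.indels_only`` is set
    (the default — indels are the expected Cas9 repair product), SNV and
    length-preserving records fail an extra ``vtype`` flag and never reach
    the five main filters' survivor set, though all verdicts are still
    recorded for them.
    """
    excluded = set()
    for cset in list(controls) + [db]:
        for cv in cset:
            excluded.add(_privacy_key(cv, params.privacy_position_only))

    traces: list[FilterTrace] = []
    survivors: list[tuple[VariantRecord, PredictedSite, int]] = []
    for v in mutant:
        t = FilterTrace(v)
        if params.indels_only:
            ok = v.is_indel
            t.flags["vtype"] = ok
            if not ok:
                t.fail_reason["vtype"] = f"{v.vtype} excluded (indels only)"

        ok = _privacy_key(v, params.privacy_position_only) not in excluded
        t.flags["privacy"] = ok
        if not ok:
            t.fail_reason["privacy"] = "present in a control set or database"

        ok, why = _repeat_verdict(v, mask)
        t.flags["repeat"] = ok
        if not ok:
            t.fail_reason["repeat"] = why

        ok, why = _homopolymer_verdict(v, genome, params.homopolymer_k)
        t.flags["homopolymer"] = ok
        if not ok:
            t.fail_reason["homopolymer"] = why

        ok, why = _gc_verdict(v, genome, params)
        t.flags["gc"] = ok
        if not ok:
            t.fail_reason["gc"] = why

        site, d = nearest_site(v, sites, params.distance_anchor)
        ok = site is not None and d <= params.proximity_bp
        t.flags["proximity"] = ok
        if not ok:
            t.fail_reason["proximity"] = (
                "no site on chromosome" if site is None
                else f"nearest site {int(d)} bp away > {params.proximity_bp}"
            )

        traces.append(t)
        if t.passed:
            assert site is not None
            survivors.append((v, site, int(d)))
    return survivors, traces
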