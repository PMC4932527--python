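"""Self-contained synthetic fixtures with machine-readable ground truth.

The generator emulates, at desk scale, the inputs of a whole-genome
off-target screen: a reference genome with *planted* guide-homologous loci
of controlled seed/non-seed mismatch composition, multi-sample variant
sets (the edited animal, a wild-type control, a small control panel, and
a dbSNP-like database) with planted private indels and decoys, a repeat
mask, and subclone reads for founder genotyping.  Every planted feature is
recorded in a truth table stating its designed fate, so end-to-end recall
and per-stage filter attribution can be measured exactly.

Decoy classes each violate exactly one filter stage:

* ``shared_with_control`` / ``in_db`` — fail the privacy subtraction;
* ``repeat_context``                  — inside a masked tandem-repeat block;
* ``homopolymer_context``             — single-base run on the upstream flank;
* ``gc_extreme``                      — GC-skewed flanking sequence;
* ``far_from_site``                   — beyond the proximity radius;
* ``snv``                             — excluded as a non-indel;
* ``survivor``                        — clean, private, near a site: passes.

Design notes: the background is an i.i.d. base model with tunable GC (no
repeat-family simulation — the filters test interval logic, not repeat
biology); repeat context is realized as explicit tandem copies that are
also written to the mask; homopolymer context is written as a run two
bases longer than the filter threshold to avoid boundary ambiguity.  All
generators are deterministic functions of their seed, and every placement
is verified against the package's own scanner and filter predicates at
generation time (with bounded redraws), so a fixture that generates at
all is internally consistent with its truth table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GenomeAssembly,
    MaskSet,
    VariantRecord,
    normalize_indel,
    read_bed,
    read_fasta,
    read_tsv,
    read_vcf,
    write_bed,
    write_fasta,
    write_tsv,
    write_vcf,
)
from .founder_genotyping import genotype_cohort, read_clone_fasta
from .target_search import (
    Guide,
    PredictedSite,
    ScanParams,
    find_target_sites,
    reverse_complement,
)
from .variant_filters import FilterParams, run_filter_cascade

log = logging.getLogger(__name__)

__all__ = [
    "PlantProfile",
    "TruthRecord",
    "CloneAllele",
    "AnimalDesign",
    "SimulatedVariants",
    "Fixture",
    "generate_genome",
    "plant_sites",
    "simulate_variant_sets",
    "simulate_clone_reads",
    "default_site_profiles",
    "default_variant_design",
    "default_cohort",
    "make_fixture",
    "verify_fixtures",
]

BASES = "ACGT"


@dataclass(frozen=True)
class PlantProfile:
    """Requested composition of one planted guide-homologous locus."""

    seed_mm: int
    nonseed_mm: int
    strand: str = "+"
    pam_class: str = "NGG"
    context: str = "clean"


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted feature (site or variant)."""

    kind: str                  # "site" | "indel" | "snv"
    chrom: str
    start: int                 # 0-based half-open feature interval
    end: int
    strand: str = "."
    seed_mm: int = -1
    nonseed_mm: int = -1
    pam_class: str = ""
    pos: int = 0               # 1-based VCF position (variants)
    ref: str = ""
    alt: str = ""
    design: str = ""
    expected_fate: str = ""    # filter stage that removes it, or "survive"


# ---------------------------------------------------------------------------
# Genome


def generate_genome(
    chrom_lengths: Mapping[str, int], gc_target: float = 0.5, seed: int = 0
) -> GenomeAssembly:
    """I.i.d. random genome with the requested GC fraction.

    Deterministic for a fixed seed; for chromosomes of at least 10 kb the
    realized GC lands within about two percentage points of the target.
    """
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    for name, length in chrom_lengths.items():
        if length < 1000:
            raise ValueError(f"chromosome {name} shorter than 1 kb")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_target) / 2, gc_target / 2
    probs = [at, gc, gc, at]   # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    for name, length in chrom_lengths.items():
        draw = rng.choice(alphabet, size=length, p=probs)
        sequences[name] = draw.tobytes().decode("ascii")
    return GenomeAssembly(sequences)


# ---------------------------------------------------------------------------
# Site planting


def _assembly(seqs: Mapping[str, bytearray]) -> GenomeAssembly:
    return GenomeAssembly({c: bytes(a).decode("ascii") for c, a in seqs.items()})


def _site_key(s: PredictedSite) -> tuple:
    return (s.chrom, s.start, s.end, s.strand, s.seed_mm, s.nonseed_mm, s.pam_class)


_COMPLEMENT_BYTE = {ord(a): ord(b) for a, b in zip("ACGTN", "TGCAN")}


def _break_window(
    seqs: dict[str, bytearray],
    site: PredictedSite,
    guide: Guide,
    seed_len: int,
    max_seed: int,
    rng: np.random.Generator,
    protected: Sequence[tuple[str, int, int]] = (),
) -> None:
    """Push an unwanted site's seed mismatch count over budget by mutating
    seed positions that currently match the guide."""
    W = len(guide.protospacer)
    need = max_seed + 1 - site.seed_mm
    candidates = []
    for j in range(W - seed_len, W):
        g = site.start + j if site.strand == "+" else site.end - 1 - j
        if any(c == site.chrom and s <= g < e for c, s, e in protected):
            continue
        oriented = (
            chr(seqs[site.chrom][g])
            if site.strand == "+"
            else chr(_COMPLEMENT_BYTE[seqs[site.chrom][g]])
        )
        if oriented == guide.protospacer[j]:
            candidates.append((j, g))
    if len(candidates) < need:
        raise RuntimeError("cannot break accidental site without touching "
                           "protected sequence")
    picks = rng.choice(len(candidates), size=need, replace=False)
    for k in picks:
        j, g = candidates[int(k)]
        current = guide.protospacer[j]
        newb = rng.choice([b for b in BASES if b != current])
        if site.strand == "-":
            newb = chr(_COMPLEMENT_BYTE[ord(newb)])
        seqs[site.chrom][g] = ord(newb)


def _realize_pam(pattern: str, rng: np.random.Generator) -> str:
    from .target_search import IUPAC

    return "".join(str(rng.choice(list(IUPAC[letter]))) for letter in pattern)


def _mutate_protospacer(
    proto: str, profile: PlantProfile, seed_len: int, rng: np.random.Generator
) -> str:
    W = len(proto)
    out = list(proto)
    seed_positions = rng.choice(
        np.arange(W - seed_len, W), size=profile.seed_mm, replace=False
    )
    nonseed_positions = rng.choice(
        np.arange(0, W - seed_len), size=profile.nonseed_mm, replace=False
    )
    for j in list(seed_positions) + list(nonseed_positions):
        j = int(j)
        out[j] = str(rng.choice([b for b in BASES if b != proto[j]]))
    return "".join(out)


def plant_sites(
    genome: GenomeAssembly,
    guide: Guide,
    profiles: Sequence[PlantProfile],
    params: ScanParams = ScanParams(),
    seed: int = 0,
    min_separation: int = 2000,
) -> tuple[GenomeAssembly, list[TruthRecord]]:
    """Write one locus per profile into the genome and return the edited
    assembly plus truth records.

    The background is first scrubbed of accidental guide-homologous sites
    (random 100-kb sequence contains a handful at the widest budgets);
    each planted locus is then verified by a full re-scan, which must
    report exactly the planted set — the whole construction is redrawn
    from a derived seed if it does not.
    """
    pams, seed_len = params.resolve(guide)
    for p in profiles:
        if p.seed_mm > params.max_seed_mm or p.nonseed_mm > params.max_nonseed_mm:
            raise ValueError(f"profile {p} exceeds scan budgets")
        if p.pam_class not in pams:
            raise ValueError(f"profile PAM {p.pam_class} not in scan PAM set")
    last_err: Exception | None = None
    for attempt in range(8):
        try:
            return _plant_once(
                genome, guide, profiles, params, seed, attempt, min_separation
            )
        except RuntimeError as exc:
            last_err = exc
    raise RuntimeError(f"site planting failed after 8 attempts: {last_err}")


def _plant_once(
    genome: GenomeAssembly,
    guide: Guide,
    profiles: Sequence[PlantProfile],
    params: ScanParams,
    seed: int,
    attempt: int,
    min_separation: int,
) -> tuple[GenomeAssembly, list[TruthRecord]]:
    rng = np.random.default_rng([seed, 17, attempt])
    pams, seed_len = params.resolve(guide)
    W = len(guide.protospacer)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}

    # scrub accidental background sites
    for _ in range(40):
        extras = find_target_sites(_assembly(seqs), guide, params)
        if not extras:
            break
        for s in extras:
            _break_window(seqs, s, guide, seed_len, params.max_seed_mm, rng)
    else:
        raise RuntimeError("background scrub did not converge")

    chroms = list(seqs)
    margin = 2500
    occupied: list[tuple[str, int, int]] = []
    truth: list[TruthRecord] = []
    for profile in profiles:
        placed = False
        for _ in range(300):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = len(seqs[chrom])
            if L < 2 * margin + W + 3:
                continue
            start = int(rng.integers(margin, L - margin - W - 3))
            window = (chrom, start, start + W + 3)
            if any(
                c == chrom and s - min_separation < window[2]
                and window[1] < e + min_separation
                for c, s, e in occupied
            ):
                continue
            mut = _mutate_protospacer(guide.protospacer, profile, seed_len, rng)
            oriented = mut + _realize_pam(profile.pam_class, rng)
            written = oriented if profile.strand == "+" else reverse_complement(oriented)
            snap = bytes(seqs[chrom][start - 60:start + W + 63])
            seqs[chrom][start:start + W + 3] = written.encode("ascii")
            if profile.strand == "+":
                pstart, pend = start, start + W
            else:
                pstart, pend = start + 3, start + W + 3
            # local re-scan: the write must introduce exactly the requested
            # site and nothing else (a guide with partial reverse-complement
            # self-similarity can otherwise gain an overlapping opposite-
            # strand hit; redraw the mismatch realization when that happens)
            r0 = start - 60
            region = GenomeAssembly(
                {chrom: bytes(seqs[chrom][r0:start + W + 63]).decode("ascii")}
            )
            local = {
                (h.start + r0, h.end + r0, h.strand, h.seed_mm,
                 h.nonseed_mm, h.pam_class)
                for h in find_target_sites(region, guide, params)
            }
            if local != {
                (pstart, pend, profile.strand, profile.seed_mm,
                 profile.nonseed_mm, profile.pam_class)
            }:
                seqs[chrom][start - 60:start + W + 63] = snap
                continue
            occupied.append(window)
            truth.append(
                TruthRecord(
                    kind="site",
                    chrom=chrom,
                    start=pstart,
                    end=pend,
                    strand=profile.strand,
                    seed_mm=profile.seed_mm,
                    nonseed_mm=profile.nonseed_mm,
                    pam_class=profile.pam_class,
                    design="planted_site",
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a site profile with the "
                               "required separation")

    expected = {
        (t.chrom, t.start, t.end, t.strand, t.seed_mm, t.nonseed_mm, t.pam_class)
        for t in truth
    }
    found = {
        _site_key(s) for s in find_target_sites(_assembly(seqs), guide, params)
    }
    if found != expected:
        raise RuntimeError(
            f"planting verification failed: {len(found - expected)} unexpected, "
            f"{len(expected - found)} missing"
        )
    return _assembly(seqs), truth


# ---------------------------------------------------------------------------
# Variant sets


def default_site_profiles() -> list[PlantProfile]:
    """Thirty profiles spanning the (seed_mm 0-3) x (nonseed_mm 0-6) grid on
    alternating strands and PAM classes, plus an exact locus on each
    strand.  The (0,0,+,NGG) entry is the on-target locus itself."""
    profiles = [
        PlantProfile(s, n, "+" if (s + n) % 2 == 0 else "-",
                     "NGG" if n % 2 == 0 else "NAG")
        for s in range(4)
        for n in range(7)
    ]
    profiles.append(PlantProfile(0, 0, "-", "NAG"))
    profiles.append(PlantProfile(1, 1, "+", "NGG"))
    return profiles


def default_variant_design() -> dict[str, int]:
    """Planted-variant counts per class (~40 variants total, including the
    on-target edit, which is always added as one extra survivor)."""
    return {
        "survivor": 7,
        "shared_with_control": 6,
        "in_db": 6,
        "far_from_site": 6,
        "repeat_context": 5,
        "homopolymer_context": 5,
        "gc_extreme": 4,
        "snv": 3,
    }


_EXPECTED_FATE = {
    "survivor": "survive",
    "on_target": "survive",
    "shared_with_control": "privacy",
    "in_db": "privacy",
    "far_from_site": "proximity",
    "repeat_context": "repeat",
    "homopolymer_context": "homopolymer",
    "gc_extreme": "gc",
    "snv": "vtype",
}


@dataclass
class SimulatedVariants:
    genome: GenomeAssembly
    sites: list[PredictedSite]
    mutant: list[VariantRecord]
    wt: list[VariantRecord]
    panels: list[list[VariantRecord]]
    db: list[VariantRecord]
    mask: MaskSet
    truth: list[TruthRecord]


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    at, g = (1 - gc) / 2, gc / 2
    return "".join(
        str(b) for b in rng.choice(list(BASES), size=n, p=[at, g, g, at])
    )


class _Placer:
    """Bookkeeping for variant placement: spacing reservations and genome
    edits with undo."""

    def __init__(self, seqs: dict[str, bytearray], spacing: int = 500):
        self.seqs = seqs
        self.spacing = spacing
        self.reserved: list[tuple[str, int, int]] = []

    def free(self, chrom: str, start: int, end: int) -> bool:
        return not any(
            c == chrom and s - self.spacing < end and start < e + self.spacing
            for c, s, e in self.reserved
        )

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.reserved.append((chrom, start, end))

    def snapshot(self, chrom: str, start: int, end: int):
        return (chrom, start, bytes(self.seqs[chrom][start:end]))

    def restore(self, snap) -> None:
        chrom, start, data = snap
        self.seqs[chrom][start:start + len(data)] = data


def _make_indel(
    seqs: dict[str, bytearray],
    chrom: str,
    anchor: int,
    rng: np.random.Generator,
    op: str | None = None,
    size: int | None = None,
) -> VariantRecord:
    seq = seqs[chrom]
    op = op or ("del" if rng.random() < 0.5 else "ins")
    size = size or int(rng.integers(1, 6))
    ref_base = chr(seq[anchor])
    if op == "del":
        ref = ref_base + bytes(seq[anchor + 1:anchor + 1 + size]).decode()
        return VariantRecord(chrom, anchor + 1, ref, ref_base)
    ins = _rand_seq(rng, size)
    return VariantRecord(chrom, anchor + 1, ref_base, ref_base + ins)


def _make_snv(
    seqs: dict[str, bytearray], chrom: str, anchor: int, rng: np.random.Generator
) -> VariantRecord:
    ref_base = chr(seqs[chrom][anchor])
    alt = str(rng.choice([b for b in BASES if b != ref_base]))
    return VariantRecord(chrom, anchor + 1, ref_base, alt)


def _no_shift_guard(
    seqs: dict[str, bytearray], chrom: str, anchor: int, size: int,
    rng: np.random.Generator, forbid: str = "",
) -> None:
    """Rewrite the anchor and the base just past a deletion so that the
    deletion cannot left-shift, optionally avoiding a context base."""
    seq = seqs[chrom]
    a_choices = [b for b in BASES if b != forbid]
    seq[anchor] = ord(str(rng.choice(a_choices)))
    d_choices = [b for b in BASES if b != chr(seq[anchor]) and b != forbid]
    seq[anchor + size] = ord(str(rng.choice(d_choices)))


def simulate_variant_sets(
    genome: GenomeAssembly,
    guide: Guide,
    site_truth: Sequence[TruthRecord],
    design: Mapping[str, int] | None = None,
    seed: int = 0,
    scan_params: ScanParams = ScanParams(),
    filter_params: FilterParams = FilterParams(),
    n_panels: int = 3,
    n_background: int = 10,
) -> SimulatedVariants:
    """Plant the multi-sample variant population around already-planted
    sites.

    Context decoys carve their sequence context (tandem-repeat block,
    homopolymer run, GC-skewed patch) into the genome first, so the
    returned assembly supersedes the input one.  Every planted variant's
    filter fate is verified with the package's own predicates at placement
    time and the full cascade + a full genome re-scan are verified at the
    end; the construction is redrawn from a derived seed on any violation.
    """
    design = dict(design or default_variant_design())
    last_err: Exception | None = None
    for attempt in range(8):
        try:
            return _simulate_once(
                genome, guide, site_truth, design, seed, attempt,
                scan_params, filter_params, n_panels, n_background,
            )
        except RuntimeError as exc:
            last_err = exc
    raise RuntimeError(f"variant simulation failed after 8 attempts: {last_err}")


def _truth_sites_to_predicted(
    site_truth: Sequence[TruthRecord], genome: GenomeAssembly, guide: Guide,
    scan_params: ScanParams,
) -> list[PredictedSite]:
    sites = find_target_sites(genome, guide, scan_params)
    expected = {
        (t.chrom, t.start, t.end, t.strand) for t in site_truth if t.kind == "site"
    }
    got = {(s.chrom, s.start, s.end, s.strand) for s in sites}
    if got != expected:
        raise RuntimeError("scan does not reproduce the planted site set")
    return sites


def _simulate_once(
    genome: GenomeAssembly,
    guide: Guide,
    site_truth: Sequence[TruthRecord],
    design: Mapping[str, int],
    seed: int,
    attempt: int,
    scan_params: ScanParams,
    filter_params: FilterParams,
    n_panels: int,
    n_background: int,
) -> SimulatedVariants:
    rng = np.random.default_rng([seed, 29, attempt])
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    sites = _truth_sites_to_predicted(site_truth, genome, guide, scan_params)
    placer = _Placer(seqs)
    # protect planted site windows (protospacer + PAM, small buffer)
    site_windows = []
    for s in sites:
        w = (s.chrom, s.start - 3 if s.strand == "-" else s.start,
             s.end + 3 if s.strand == "+" else s.end)
        site_windows.append(w)

    mask_intervals: list[tuple[str, int, int]] = []
    mutant: list[VariantRecord] = []
    wt_planted: list[VariantRecord] = []
    db_planted: list[VariantRecord] = []
    truth: list[TruthRecord] = []

    def current() -> GenomeAssembly:
        return _assembly(seqs)

    def carve_clear(chrom: str, start: int, end: int) -> bool:
        """Carve region must not touch any planted site window."""
        return not any(
            c == chrom and s - 10 < end and start < e + 10
            for c, s, e in site_windows
        )

    def near_site_anchor() -> tuple[PredictedSite, int] | None:
        site = sites[int(rng.integers(len(sites)))]
        L = len(seqs[site.chrom])
        offset = int(rng.integers(40, 420))
        anchor = (
            site.start - offset if rng.random() < 0.5 else site.end + offset
        )
        if not 200 < anchor < L - 200:
            return None
        return site, anchor

    def verdicts(v: VariantRecord) -> dict[str, bool]:
        from .variant_filters import (
            filter_gc,
            filter_homopolymer,
            filter_repeat,
            nearest_site,
        )

        g = current()
        mask = MaskSet(
            {c: [] for c in seqs} | _group_intervals(mask_intervals)
        )
        out = {
            "repeat": filter_repeat([v], mask)[0].flags["repeat"],
            "homopolymer": filter_homopolymer(
                [v], g, filter_params.homopolymer_k
            )[0].flags["homopolymer"],
            "gc": filter_gc([v], g, filter_params)[0].flags["gc"],
        }
        _, d = nearest_site(v, sites, filter_params.distance_anchor)
        out["proximity"] = d <= filter_params.proximity_bp
        return out

    def commit(
        v: VariantRecord, klass: str, expect: dict[str, bool]
    ) -> bool:
        got = verdicts(v)
        if got != expect:
            return False
        s, e = v.interval
        placer.reserve(v.chrom, s, e)
        mutant.append(v)
        truth.append(
            TruthRecord(
                kind="snv" if klass == "snv" else "indel",
                chrom=v.chrom,
                start=s,
                end=e,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                design=klass,
                expected_fate=_EXPECTED_FATE[klass],
            )
        )
        return True

    clean_pass = {"repeat": True, "homopolymer": True, "gc": True,
                  "proximity": True}

    def place_clean(klass: str, op: str | None = None) -> None:
        for _ in range(300):
            hit = near_site_anchor()
            if hit is None:
                continue
            _, anchor = hit
            if not placer.free(hit[0].chrom, anchor - 5, anchor + 10):
                continue
            chrom = hit[0].chrom
            if klass == "snv":
                v = _make_snv(seqs, chrom, anchor, rng)
            else:
                v = _make_indel(seqs, chrom, anchor, rng, op=op)
            v = normalize_indel(v, current())
            if abs(v.pos - 1 - anchor) > 30:
                continue
            if commit(v, klass, clean_pass):
                return
        raise RuntimeError(f"could not place a {klass} variant")

    # --- on-target edit: a deletion inside the exact-match locus ---------
    exact = [s for s in sites if s.seed_mm == 0 and s.nonseed_mm == 0]
    if exact:
        site = exact[0]
        for _ in range(100):
            anchor = site.start + int(rng.integers(2, 12))
            v = _make_indel(seqs, site.chrom, anchor, rng, op="del", size=3)
            v = normalize_indel(v, current())
            if commit(v, "on_target", clean_pass):
                break
        else:
            raise RuntimeError("could not place the on-target edit")

    for _ in range(design.get("survivor", 0)):
        place_clean("survivor")
    for _ in range(design.get("snv", 0)):
        place_clean("snv")
    for _ in range(design.get("shared_with_control", 0)):
        place_clean("shared_with_control")
        wt_planted.append(mutant[-1])
    for _ in range(design.get("in_db", 0)):
        place_clean("in_db")
        db_planted.append(mutant[-1])

    # --- far from any site ----------------------------------------------
    chroms = list(seqs)
    fail_proximity = dict(clean_pass, proximity=False)
    for _ in range(design.get("far_from_site", 0)):
        for _ in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = len(seqs[chrom])
            anchor = int(rng.integers(1000, L - 1000))
            if not placer.free(chrom, anchor - 5, anchor + 10):
                continue
            if any(
                s.chrom == chrom and s.start - 700 < anchor < s.end + 700
                for s in sites
            ):
                continue
            v = normalize_indel(
                _make_indel(seqs, chrom, anchor, rng), current()
            )
            if abs(v.pos - 1 - anchor) > 30:
                continue
            if commit(v, "far_from_site", fail_proximity):
                break
        else:
            raise RuntimeError("could not place a far_from_site variant")

    # --- context decoys ---------------------------------------------------
    def place_context(klass: str, carve) -> None:
        expect = dict(clean_pass)
        expect[_EXPECTED_FATE[klass]] = False
        for _ in range(400):
            hit = near_site_anchor()
            if hit is None:
                continue
            site, anchor = hit
            chrom = site.chrom
            c0, c1 = anchor - 70, anchor + 70
            if not (placer.free(chrom, c0, c1) and carve_clear(chrom, c0, c1)):
                continue
            snap = placer.snapshot(chrom, c0, c1)
            size = int(rng.integers(1, 4))
            mask_iv = carve(chrom, anchor, size)
            if mask_iv is not None:
                mask_intervals.append(mask_iv)
            v = _make_indel(seqs, chrom, anchor, rng, op="del", size=size)
            try:
                v = normalize_indel(v, current())
            except ValueError:
                v = None
            if (
                v is not None
                and abs(v.pos - 1 - anchor) <= 5
                and commit(v, klass, expect)
            ):
                placer.reserve(chrom, c0, c1)
                return
            placer.restore(snap)
            if mask_iv is not None:
                mask_intervals.pop()
        raise RuntimeError(f"could not place a {klass} variant")

    k = filter_params.homopolymer_k

    def carve_homopolymer(chrom, anchor, size):
        run_base = str(rng.choice(list(BASES)))
        run = (run_base * (k + 2)).encode("ascii")
        seqs[chrom][anchor - (k + 2):anchor] = run
        _no_shift_guard(seqs, chrom, anchor, size, rng, forbid=run_base)
        return None

    def carve_gc(chrom, anchor, size):
        hi = rng.random() < 0.5
        gc = 0.88 if hi else 0.10
        for _ in range(50):
            patch = _rand_seq(rng, 130, gc=gc)
            if _max_run(patch) <= k - 1:
                break
        else:
            raise RuntimeError("cannot draw a GC patch without homopolymers")
        seqs[chrom][anchor - 65:anchor + 65] = patch.encode("ascii")
        _no_shift_guard(seqs, chrom, anchor, size, rng)
        return None

    def carve_repeat(chrom, anchor, size):
        for _ in range(50):
            unit = _rand_seq(rng, 12)
            if len(set(unit)) >= 3 and 0.3 <= _gc_frac(unit) <= 0.7:
                break
        else:
            raise RuntimeError("cannot draw a repeat unit")
        block = (unit * 9)[:96].encode("ascii")
        seqs[chrom][anchor - 48:anchor + 48] = block
        _no_shift_guard(seqs, chrom, anchor, size, rng)
        return (chrom, anchor - 52, anchor + 52)

    for klass, carve in (
        ("homopolymer_context", carve_homopolymer),
        ("gc_extreme", carve_gc),
        ("repeat_context", carve_repeat),
    ):
        for _ in range(design.get(klass, 0)):
            place_context(klass, carve)

    # --- decoy mask intervals away from every mutant variant --------------
    for _ in range(3):
        for _ in range(300):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = len(seqs[chrom])
            start = int(rng.integers(500, L - 900))
            if placer.free(chrom, start - 100, start + 500):
                mask_intervals.append((chrom, start, start + 400))
                placer.reserve(chrom, start, start + 400)
                break

    # --- background variants in the control sets --------------------------
    mutant_keys = {v.key for v in mutant}
    final = current()

    def background(n: int) -> list[VariantRecord]:
        out: list[VariantRecord] = []
        while len(out) < n:
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = len(seqs[chrom])
            anchor = int(rng.integers(100, L - 100))
            v = (
                _make_snv(seqs, chrom, anchor, rng)
                if rng.random() < 0.4
                else _make_indel(seqs, chrom, anchor, rng)
            )
            v = normalize_indel(v, final)
            if v.key in mutant_keys:
                continue
            out.append(v)
        return out

    wt = [
        VariantRecord(*v.key, samples=frozenset({"wt"}))
        for v in wt_planted + background(n_background)
    ]
    panels = [
        [
            VariantRecord(*v.key, samples=frozenset({f"panel{i + 1}"}))
            for v in background(n_background)
        ]
        for i in range(n_panels)
    ]
    db = [
        VariantRecord(*v.key, samples=frozenset({"db"}))
        for v in db_planted + background(n_background + 5)
    ]
    mutant = [
        VariantRecord(*v.key, samples=frozenset({"mutant"})) for v in mutant
    ]

    mask = MaskSet({c: [] for c in seqs} | _group_intervals(mask_intervals))

    # --- global verification ----------------------------------------------
    rescanned = find_target_sites(final, guide, scan_params)
    if {(s.chrom, s.start, s.end, s.strand) for s in rescanned} != {
        (s.chrom, s.start, s.end, s.strand) for s in sites
    }:
        raise RuntimeError("context carving altered the planted site set")
    survivors, traces = run_filter_cascade(
        mutant, [wt] + panels, db, mask, final, rescanned, filter_params
    )
    by_key = {t.variant.key: t for t in traces}
    for t in truth:
        trace = by_key[(t.chrom, t.pos, t.ref, t.alt)]
        if t.expected_fate == "survive":
            ok = trace.passed
        else:
            ok = trace.failed_filters == (t.expected_fate,)
        if not ok:
            raise RuntimeError(
                f"variant {t.design} at {t.chrom}:{t.pos} has fate "
                f"{trace.failed_filters or 'survive'}, expected "
                f"{t.expected_fate}"
            )
    return SimulatedVariants(
        genome=final,
        sites=rescanned,
        mutant=mutant,
        wt=wt,
        panels=panels,
        db=db,
        mask=mask,
        truth=truth,
    )


def _group_intervals(
    intervals: Sequence[tuple[str, int, int]]
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        out.setdefault(chrom, []).append((s, e))
    return out


def _gc_frac(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq) if seq else 0.0


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# Clone reads


@dataclass(frozen=True)
class CloneAllele:
    """One designed allele: ``op`` in {ref, del, ins}; ``offset`` is the
    0-based edit position in the amplicon (default: staggered around the
    center, i.e. the nominal cut site)."""

    op: str = "ref"
    size: int = 0
    offset: int | None = None

    def __post_init__(self) -> None:
        if self.op not in ("ref", "del", "ins"):
            raise ValueError("op must be ref|del|ins")
        if self.op != "ref" and self.size <= 0:
            raise ValueError("indel alleles need a positive size")


@dataclass(frozen=True)
class AnimalDesign:
    animal_id: str
    alleles: tuple[tuple[CloneAllele, int], ...]

    @property
    def expected_category(self) -> str:
        distinct = [a for a, n in self.alleles if n > 0]
        mutants = [a for a in distinct if a.op != "ref"]
        has_ref = len(mutants) < len(distinct)
        if len(distinct) >= 3:
            return "mosaic"
        if len(distinct) == 2:
            return "heterozygote" if has_ref else "compound_heterozygote"
        return "wild_type" if has_ref else "homozygote"


def default_cohort() -> list[AnimalDesign]:
    """Six founders covering all five genotype categories, ten clones each.
    The homozygous 3-bp deletion mirrors the classic single-codon loss."""
    d3 = CloneAllele("del", 3)
    return [
        AnimalDesign("F01", ((d3, 10),)),
        AnimalDesign("F02", ((d3, 5), (CloneAllele("ins", 1), 5))),
        AnimalDesign(
            "F03",
            ((CloneAllele(), 3), (d3, 3), (CloneAllele("ins", 2), 2),
             (CloneAllele("del", 7), 2)),
        ),
        AnimalDesign("F04", ((CloneAllele(), 10),)),
        AnimalDesign("F05", ((CloneAllele(), 5), (d3, 5))),
        AnimalDesign("F06", ((CloneAllele("del", 2), 6),
                             (CloneAllele("del", 5), 4))),
    ]


def simulate_clone_reads(
    reference_amplicon: str,
    animal_designs: Sequence[AnimalDesign],
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Subclone reads realizing each animal's designed allele multiset.

    Returns ``(records, truth)`` where records are (header, sequence)
    pairs with headers ``animal|clone`` and truth lists each animal's
    intended category.  ``error_rate`` adds i.i.d. substitution noise
    (< 0.01/bp) mimicking Sanger base-call errors.
    """
    if not 0 <= error_rate < 0.01:
        raise ValueError("error_rate must be in [0, 0.01)")
    rng = np.random.default_rng([seed, 41])
    center = len(reference_amplicon) // 2
    records: list[tuple[str, str]] = []
    truth: list[tuple[str, str]] = []
    for design in animal_designs:
        variants: list[str] = []
        for i, (allele, _count) in enumerate(design.alleles):
            offset = allele.offset if allele.offset is not None else center + 4 * i
            if allele.op == "ref":
                seq = reference_amplicon
            elif allele.op == "del":
                seq = (
                    reference_amplicon[:offset]
                    + reference_amplicon[offset + allele.size:]
                )
            else:
                ins = _rand_seq(rng, allele.size)
                seq = (
                    reference_amplicon[:offset] + ins
                    + reference_amplicon[offset:]
                )
            variants.append(seq)
        if len(set(variants)) != len(variants):
            raise RuntimeError(
                f"designed alleles for {design.animal_id} are not distinct"
            )
        clone_no = 0
        for seq, (allele, count) in zip(variants, design.alleles):
            for _ in range(count):
                clone_no += 1
                read = seq
                if error_rate > 0:
                    chars = list(read)
                    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
                    for h in hits:
                        chars[h] = str(
                            rng.choice([b for b in BASES if b != chars[h]])
                        )
                    read = "".join(chars)
                records.append((f"{design.animal_id}|c{clone_no:02d}", read))
        truth.append((design.animal_id, design.expected_category))
    return records, truth


# ---------------------------------------------------------------------------
# Fixture orchestration


@dataclass
class Fixture:
    outdir: Path
    guide: Guide
    genome: GenomeAssembly
    sites: list[PredictedSite]
    variants: SimulatedVariants
    site_truth: list[TruthRecord]
    amplicon: str
    clone_truth: list[tuple[str, str]]
    paths: dict[str, Path]


def _self_clean(proto: str, rng: np.random.Generator) -> bool:
    """A usable protospacer must not be so self-reverse-complementary that
    embedding it next to any PAM realization creates a second, opposite-
    strand in-budget site overlapping the first."""
    g = Guide("probe", proto)
    for pam in ("TGG", "AGG", "CGG", "GGG", "TAG", "AAG", "CAG", "GAG"):
        for _ in range(2):
            ctx = _rand_seq(rng, 80)
            seq = ctx[:40] + proto + pam + ctx[40:]
            hits = find_target_sites(GenomeAssembly({"c": seq}), g, ScanParams())
            if len(hits) != 1:
                return False
    return True


def _random_guide(rng: np.random.Generator, length: int = 20) -> str:
    for _ in range(200):
        proto = _rand_seq(rng, length)
        if (
            0.4 <= _gc_frac(proto) <= 0.6
            and _max_run(proto) <= 4
            and _self_clean(proto, rng)
        ):
            return proto
    raise RuntimeError("could not draw a balanced protospacer")


def make_fixture(
    outdir: str | Path,
    seed: int = 42,
    chrom_lengths: Mapping[str, int] | None = None,
    gc_target: float = 0.5,
    site_profiles: Sequence[PlantProfile] | None = None,
    variant_design: Mapping[str, int] | None = None,
    cohort: Sequence[AnimalDesign] | None = None,
    clone_error_rate: float = 0.0,
    scan_params: ScanParams = ScanParams(),
    filter_params: FilterParams = FilterParams(),
    amplicon_bp: int = 600,
) -> Fixture:
    """Generate the full fixture tree under ``outdir``.

    Defaults: two 100-kb chromosomes at 50% GC, 30 planted sites spanning
    the mismatch grid, ~40 planted variants across all decoy classes, and
    a six-founder clone cohort.  Everything is a deterministic function of
    ``seed``; regenerating with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_lengths = dict(chrom_lengths or {"chr1": 100_000, "chr2": 100_000})
    rng = np.random.default_rng([seed, 3])
    guide = Guide(name="guideL1", protospacer=_random_guide(rng))

    base = generate_genome(chrom_lengths, gc_target=gc_target, seed=seed)
    planted, site_truth = plant_sites(
        base, guide,
        site_profiles if site_profiles is not None else default_site_profiles(),
        params=scan_params, seed=seed,
    )
    sim = simulate_variant_sets(
        planted, guide, site_truth,
        design=variant_design, seed=seed,
        scan_params=scan_params, filter_params=filter_params,
    )

    # validation amplicon over the on-target (exact-match) locus
    exact = [s for s in sim.sites if s.seed_mm == 0 and s.nonseed_mm == 0]
    anchor_site = exact[0] if exact else sim.sites[0]
    mid = (anchor_site.start + anchor_site.end) // 2
    a0 = max(0, mid - amplicon_bp // 2)
    amplicon = sim.genome.fetch(anchor_site.chrom, a0, a0 + amplicon_bp)
    clone_records, clone_truth = simulate_clone_reads(
        amplicon,
        cohort if cohort is not None else default_cohort(),
        error_rate=clone_error_rate,
        seed=seed,
    )

    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_fasta(sim.genome, p("genome.fa"))
    write_tsv(
        pd.DataFrame(
            [
                {
                    "name": guide.name,
                    "protospacer": guide.protospacer,
                    "pam_patterns": ",".join(guide.pam_patterns),
                    "seed_length": guide.seed_length,
                }
            ]
        ),
        p("guide.tsv"),
    )
    lengths = sim.genome.lengths
    write_vcf(sim.mutant, lengths, p("mutant.vcf"))
    write_vcf(sim.wt, lengths, p("wt.vcf"))
    for i, panel in enumerate(sim.panels, start=1):
        write_vcf(panel, lengths, p(f"panel_{i}.vcf"))
    write_vcf(sim.db, lengths, p("db.vcf"))
    write_bed(sim.mask, p("mask.bed"))

    write_tsv(
        pd.DataFrame(
            [
                {
                    "chrom": t.chrom, "start": t.start, "end": t.end,
                    "strand": t.strand, "seed_mm": t.seed_mm,
                    "nonseed_mm": t.nonseed_mm, "pam_class": t.pam_class,
                }
                for t in site_truth
            ]
        ),
        p("truth_sites.tsv"),
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "kind": t.kind, "chrom": t.chrom, "pos": t.pos,
                    "ref": t.ref, "alt": t.alt, "design": t.design,
                    "expected_fate": t.expected_fate,
                }
                for t in sim.truth
            ]
        ),
        p("truth_variants.tsv"),
    )
    with open(p("amplicon.fa"), "w") as fh:
        fh.write(f">amplicon|{anchor_site.chrom}:{a0}-{a0 + len(amplicon)}\n")
        for i in range(0, len(amplicon), 60):
            fh.write(amplicon[i:i + 60] + "\n")
    with open(p("clones.fa"), "w") as fh:
        for header, seq in clone_records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    write_tsv(
        pd.DataFrame(clone_truth, columns=["animal_id", "expected_category"]),
        p("truth_clones.tsv"),
    )
    return Fixture(
        outdir=outdir,
        guide=guide,
        genome=sim.genome,
        sites=sim.sites,
        variants=sim,
        site_truth=site_truth,
        amplicon=amplicon,
        clone_truth=clone_truth,
        paths=paths,
    )


# ---------------------------------------------------------------------------
# Fixture self-verification


def verify_fixtures(
    fixture_dir: str | Path,
    scan_params: ScanParams = ScanParams(),
    filter_params: FilterParams = FilterParams(),
) -> list[str]:
    """Re-derive every property a fixture's truth tables promise.

    Returns a list of discrepancy descriptions (empty = fixture verified):
    planted sites must be re-found with their designed mismatch
    composition, every planted variant must meet its designed filter fate,
    and every simulated founder must classify into its designed category.
    """
    d = Path(fixture_dir)
    problems: list[str] = []

    genome = read_fasta(d / "genome.fa")
    grow = read_tsv(d / "guide.tsv").iloc[0]
    guide = Guide(
        name=str(grow["name"]),
        protospacer=str(grow["protospacer"]),
        pam_patterns=tuple(str(grow["pam_patterns"]).split(",")),
        seed_length=int(grow["seed_length"]),
    )

    sites = find_target_sites(genome, guide, scan_params)
    found = {
        (s.chrom, s.start, s.end, s.strand, s.seed_mm, s.nonseed_mm, s.pam_class)
        for s in sites
    }
    expected = {
        (r.chrom, int(r.start), int(r.end), r.strand, int(r.seed_mm),
         int(r.nonseed_mm), r.pam_class)
        for r in read_tsv(d / "truth_sites.tsv").itertuples(index=False)
    }
    for missing in sorted(expected - found):
        problems.append(f"planted site not recovered: {missing}")
    for extra in sorted(found - expected):
        problems.append(f"unplanted site reported: {extra}")

    mutant = read_vcf(d / "mutant.vcf", "mutant")
    wt = read_vcf(d / "wt.vcf", "wt")
    panels = [
        read_vcf(path, path.stem) for path in sorted(d.glob("panel_*.vcf"))
    ]
    db = read_vcf(d / "db.vcf", "db")
    mask = read_bed(d / "mask.bed", label="repeat")
    _, traces = run_filter_cascade(
        mutant, [wt] + panels, db, mask, genome, sites, filter_params
    )
    by_key = {t.variant.key: t for t in traces}
    for r in read_tsv(d / "truth_variants.tsv").itertuples(index=False):
        key = (r.chrom, int(r.pos), r.ref, r.alt)
        trace = by_key.get(key)
        if trace is None:
            problems.append(f"planted variant missing from mutant VCF: {key}")
            continue
        if r.expected_fate == "survive":
            if not trace.passed:
                problems.append(
                    f"planted survivor failed {trace.failed_filters}: {key}"
                )
        elif trace.failed_filters != (r.expected_fate,):
            problems.append(
                f"decoy {r.design} at {key} failed "
                f"{trace.failed_filters or 'nothing'}, expected "
                f"{r.expected_fate}"
            )

    amplicon = next(iter(read_fasta(d / "amplicon.fa").sequences.values()))
    reads = read_clone_fasta(d / "clones.fa")
    per_animal, _ = genotype_cohort(reads, amplicon)
    got = dict(zip(per_animal["animal_id"], per_animal["category"]))
    for r in read_tsv(d / "truth_clones.tsv").itertuples(index=False):
        if got.get(r.animal_id) != r.expected_category:
            problems.append(
                f"animal {r.animal_id} classified {got.get(r.animal_id)}, "
                f"designed {r.expected_category}"
            )
    return problems
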