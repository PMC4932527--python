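"""Founder genotype classification from subclone amplicon sequences.

After zygotic Cas9 injection, a founder animal carries some mixture of
repair alleles at the targeted locus.  Genotyping proceeds by PCR of the
locus, subcloning, and Sanger sequencing of ~10 colonies; each colony read
represents one allele.  This module calls the allele carried by each read
(net insertion/deletion length, left-aligned position) via global pairwise
alignment against the reference amplicon, then classifies the animal from
its distinct-allele composition:

* only the reference allele          -> wild type
* one mutant allele only             -> homozygote
* reference + one mutant allele      -> heterozygote
* two distinct mutant alleles        -> compound heterozygote
* three or more distinct alleles     -> mosaic (post-zygotic editing)

The mosaic boundary follows diploidy logic — more than two distinct
alleles cannot come from a single diploid zygotic genotype — and is
reported as ``rule_v1`` in the output so downstream consumers can see
which convention produced the call.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

log = logging.getLogger(__name__)

__all__ = [
    "AlleleCall",
    "GenotypeCall",
    "CATEGORIES",
    "call_allele",
    "classify_genotype",
    "genotype_cohort",
    "read_clone_fasta",
]

CATEGORIES = (
    "wild_type",
    "heterozygote",
    "homozygote",
    "compound_heterozygote",
    "mosaic",
)

RULE_VERSION = "rule_v1"

#: Alignment scoring: match +1, mismatch -1, gap open -5, gap extend -1,
#: terminal gaps penalized like internal ones (no free end gaps).
_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-1,
)

MIN_IDENTITY = 0.80


@dataclass(frozen=True)
class Edit:
    """One contiguous indel relative to the reference amplicon.

    ``pos`` is the 0-based, left-aligned reference offset: for a deletion,
    the first deleted base; for an insertion, the base before which the
    inserted sequence sits.
    """

    kind: str          # "ins" | "del"
    pos: int
    seq: str           # inserted or deleted bases, left-aligned


@dataclass(frozen=True)
class AlleleCall:
    animal_id: str
    clone_id: str
    net_length_change: int
    edit_descriptor: str
    sequence: str
    edits: tuple[Edit, ...] = ()

    @property
    def is_reference(self) -> bool:
        return self.edit_descriptor == "0"

    @property
    def allele_key(self) -> tuple[str, str]:
        """Identity used to compare alleles between clones: the descriptor
        plus the indel-defining bases.  Keying on the edits rather than the
        whole read makes the call robust to isolated Sanger substitution
        noise."""
        return (
            self.edit_descriptor,
            ";".join(f"{e.kind}{e.pos}:{e.seq}" for e in self.edits),
        )


@dataclass(frozen=True)
class GenotypeCall:
    animal_id: str
    category: str
    alleles: tuple[tuple[str, int], ...]   # (descriptor, clone count)
    rule: str = RULE_VERSION


def _left_align_deletion(ref: str, pos: int, length: int) -> int:
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos


def _left_align_insertion(ref: str, pos: int, ins: str) -> tuple[int, str]:
    while pos > 0 and ref[pos - 1] == ins[-1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def _extract_edits(reference: str, read: str, alignment) -> list[Edit]:
    """Indels from the aligned block structure, each left-aligned."""
    blocks_t, blocks_q = alignment.aligned
    edits: list[Edit] = []
    prev_t = prev_q = 0
    bounds = list(zip(blocks_t, blocks_q)) + [
        (((len(reference), len(reference)), (len(read), len(read))))
    ]
    for (t0, t1), (q0, q1) in bounds:
        tgap, qgap = t0 - prev_t, q0 - prev_q
        if tgap > 0:
            pos = _left_align_deletion(reference, prev_t, tgap)
            edits.append(Edit("del", pos, reference[pos:pos + tgap]))
        if qgap > 0:
            pos, ins = _left_align_insertion(reference, t0, read[prev_q:q0])
            edits.append(Edit("ins", pos, ins))
        prev_t, prev_q = t1, q1
    return edits


def call_allele(
    read: str,
    reference_amplicon: str,
    animal_id: str = "",
    clone_id: str = "",
) -> AlleleCall:
    """Call the allele represented by one subclone read.

    The read is globally aligned to the reference amplicon; contiguous
    indels are reported left-aligned, and the descriptor is ``"0"`` for the
    reference allele, else ``"<+n|-n>@<1-based left-aligned position>"``
    with ``n`` the net length change.  Reads with substitution-only
    differences (no indel) are treated as the reference allele, which makes
    the caller tolerant of isolated Sanger base-call noise.  An alignment
    identity below 80% is an error: the read does not derive from this
    amplicon.
    """
    read = read.upper()
    reference = reference_amplicon.upper()
    if len(read) < 50 or len(reference) < 50:
        raise ValueError("read and reference amplicon must each be >= 50 bp")

    alignment = _ALIGNER.align(reference, read)[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns if columns else 0.0
    if identity < MIN_IDENTITY:
        raise ValueError(
            f"read does not match amplicon (identity {identity:.2f} < "
            f"{MIN_IDENTITY})"
        )

    edits = _extract_edits(reference, read, alignment)
    net = len(read) - len(reference)
    if not edits:
        descriptor = "0"
        sequence = reference          # substitution-only noise -> reference
    else:
        pos1 = edits[0].pos + 1
        descriptor = f"{net:+d}@{pos1}"
        sequence = read
    return AlleleCall(
        animal_id=animal_id,
        clone_id=clone_id,
        net_length_change=net if edits else 0,
        edit_descriptor=descriptor,
        sequence=sequence,
        edits=tuple(edits),
    )


def classify_genotype(
    alleles: Sequence[AlleleCall], min_clone_support: int = 1
) -> GenotypeCall:
    """Classify one animal from its clone-level allele calls.

    Distinct alleles are compared by descriptor + indel bases; the category
    depends only on that composition, so the call is invariant to clone
    order and to duplicating clones.  ``min_clone_support`` (default 1: no
    suppression) can drop alleles seen in too few clones, which guards
    against rare PCR/cloning artifacts at the cost of missing genuinely
    low-fraction mosaic alleles.
    """
    if len(alleles) < 2:
        raise ValueError("insufficient clones: need >= 2 allele calls")
    animals = {a.animal_id for a in alleles}
    if len(animals) > 1:
        raise ValueError(f"allele calls from multiple animals: {sorted(animals)}")
    animal_id = alleles[0].animal_id

    counts = Counter(a.allele_key for a in alleles)
    kept = {k: n for k, n in counts.items() if n >= min_clone_support}
    if not kept:
        raise ValueError("min_clone_support removed every allele")

    ref_keys = {k for k in kept if k[0] == "0"}
    mutant_keys = set(kept) - ref_keys
    n_distinct = len(kept)
    if n_distinct >= 3:
        category = "mosaic"
    elif n_distinct == 2:
        category = "heterozygote" if ref_keys else "compound_heterozygote"
    else:
        category = "wild_type" if ref_keys else "homozygote"

    allele_table = tuple(
        sorted(((k[0], n) for k, n in kept.items()), key=lambda t: (-t[1], t[0]))
    )
    return GenotypeCall(animal_id=animal_id, category=category, alleles=allele_table)


def genotype_cohort(
    reads_by_animal: Mapping[str, Sequence[tuple[str, str]]],
    reference_amplicon: str,
    min_clone_support: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype a cohort.

    ``reads_by_animal`` maps animal id to ``(clone_id, sequence)`` pairs.
    Returns a per-animal table and a per-category count summary whose
    counts sum to the cohort size.
    """
    per_animal_rows = []
    for animal_id in sorted(reads_by_animal):
        calls = [
            call_allele(seq, reference_amplicon, animal_id, clone_id)
            for clone_id, seq in reads_by_animal[animal_id]
        ]
        g = classify_genotype(calls, min_clone_support=min_clone_support)
        per_animal_rows.append(
            {
                "animal_id": g.animal_id,
                "category": g.category,
                "n_clones": len(calls),
                "alleles": ",".join(f"{d}x{n}" for d, n in g.alleles),
                "rule": g.rule,
            }
        )
    per_animal = pd.DataFrame(
        per_animal_rows,
        columns=["animal_id", "category", "n_clones", "alleles", "rule"],
    )
    summary = pd.DataFrame(
        {
            "category": CATEGORIES,
            "n_animals": [
                int((per_animal["category"] == c).sum()) if len(per_animal) else 0
                for c in CATEGORIES
            ],
        }
    )
    return per_animal, summary


def read_clone_fasta(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read clone reads with headers of the form ``animal|clone``."""
    out: dict[str, list[tuple[str, str]]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if "|" not in record.id:
            raise ValueError(
                f"clone FASTA header {record.id!r} is not of form animal|clone"
            )
        animal, clone = record.id.split("|", 1)
        out.setdefault(animal, []).append((clone, str(record.seq).upper()))
    return out
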