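# Methods

`otscreen` implements the computational arm of a CRISPR/Cas9 off-target
screen as performed on whole-genome sequencing of edited founder animals,
together with the founder-genotyping step used to classify repair
outcomes. This note records the model, the parameters that matter, the
numerical conventions, and what the synthetic fixtures do and do not
demonstrate.

## Off-target site model

A candidate off-target site (OTS) is operationalized as a *private indel*
— present in the edited animal, absent from wild-type and control
genomes — lying near a genomic locus that resembles the guide. Site
resemblance is scored by exact Hamming comparison of each 20-bp genomic
window against the protospacer, partitioned at the seed boundary:

* **seed region** — the `seed_length` (default 12) PAM-proximal
  nucleotides, where mismatches most strongly abolish Cas9 cleavage;
* **non-seed region** — the remaining PAM-distal nucleotides.

A window is a predicted site iff its 3'-adjacent 3-mer matches an allowed
PAM pattern (NGG by default, plus the weaker NAG) and its mismatch counts
satisfy `seed_mm <= max_seed_mm` (default 3) and `nonseed_mm <=
max_nonseed_mm` (default 6). These deliberately permissive budgets follow
the screening convention of casting the widest net and letting the
downstream filters and ranking discriminate. PAM bases are matched
against IUPAC patterns and never counted in either budget; when a 3-mer
satisfies several patterns the first in the configured list wins (so AGG
is classed NGG, not NAG). An `N` in the genome counts as a mismatch
inside the window and disqualifies a PAM position outright; windows
containing `N` can instead be dropped entirely via
`ScanParams(exclude_n_windows=True)`.

Correctness of the scanner is *defined* by set-equality with an
exhaustive sliding-window scan over both strands; the vectorized
implementation is an optimization with no semantics of its own, and the
test suite enforces the equivalence over the full budget grid on random
genomes.

## Filter cascade

Five pure predicates are applied to every mutant indel; the survivor set
is their intersection and is therefore independent of application order.
SNVs are excluded up front (`indels_only`, default true) because small
indels are the characteristic product of NHEJ repair at Cas9 breaks.

| filter       | rule (fail condition)                                   | default |
|--------------|---------------------------------------------------------|---------|
| privacy      | normalized (chrom, pos, ref, alt) present in any control set or the variant database | allele-exact |
| repeat       | REF interval intersects the repeat mask (BED, half-open) | —       |
| homopolymer  | either 10-bp flank of the REF interval is a single-base run | k = 10 |
| gc           | GC of the 100-bp flanking span (50 per side, variant bases excluded, N ignored) strictly < 0.20 or > 0.60 | 0.20/0.60 |
| proximity    | nearest predicted site farther than 500 bp (inclusive keep) | 500 bp |

Numerical conventions worth stating explicitly:

* internal coordinates are 0-based half-open; VCF positions 1-based;
  conversion happens only at I/O boundaries;
* GC bounds are strict ("lower than"/"higher than"), so a window at
  exactly 0.20 or 0.60 passes; proximity is inclusive ("within 500 bp"),
  so a gap of exactly 500 bp passes and 501 fails;
* the "100-bp flanking sequence" is interpreted as 100 bp total (50 per
  side); `gc_window` is configurable for the per-side reading;
* proximity is measured edge-to-edge from the variant's REF interval to
  the site's protospacer interval; `distance_anchor="cutsite"` instead
  measures to the blunt-cut position 3 bp PAM-proximal;
* nearest-site ties resolve to the smaller coordinate;
* flanks truncated by a contig edge make the homopolymer filter pass
  (with a logged warning) and the GC filter evaluate on the available
  bases — a deliberate bias toward keeping candidates near contig ends
  rather than silently discarding them;
* privacy matching is allele-exact on *normalized* representations;
  `privacy_position_only=True` offers the looser position-level
  subtraction.

Indel normalization (parsimony + left alignment, one anchor base kept) is
applied before any privacy comparison, since upstream callers may emit
the same physical edit in different encodings inside repetitive
sequence. The implementation is the standard shift-left algorithm; tests
pin it to an independent canonicalizer that reconstructs the edited
haplotype and re-derives the unique leftmost encoding, over exhaustively
enumerated equivalent encodings.

## Ranking and validation selection

Survivors are ordered ascending-lexicographically on
`(seed_mm, nonseed_mm, distance)` — seed similarity dominates, then
overall similarity, then physical proximity — with `(chrom, pos)` as the
deterministic tie-break. Mismatch *counts* rather than percent identity
are used as sort keys; for fixed region lengths the orders are
identical. Candidates with strictly fewer than 2 seed mismatches are
flagged for wet-lab validation (no additional top-N cap by default), and
a 600-bp window centered on each flagged indel is extracted as the
PCR/Sanger amplicon, clipped and logged at contig edges.

## Founder genotyping

Each subclone read is globally aligned to the reference amplicon
(match +1, mismatch −1, gap open −5, gap extend −1, end gaps penalized;
any scheme recovering the same indels is acceptable and the suite checks
the optimal score against an independent Gotoh DP). Contiguous indels
are reported left-aligned; the allele descriptor is `"0"` for reference
or `"<±n>@<pos>"` for a net length change of n at the left-aligned
1-based position. Reads aligning below 80% identity are rejected as not
deriving from the amplicon.

Distinct alleles are compared by descriptor plus the indel-defining
bases, not by full read sequence, so an isolated substitution error in a
Sanger read does not mint a new allele; substitution-only reads are
treated as the reference allele. The category rules are pure functions
of the distinct-allele composition:

* {ref} → wild type; {m} → homozygote; {ref, m} → heterozygote;
* {m1, m2} → compound heterozygote; three or more distinct alleles →
  mosaic (a diploid zygote cannot carry more than two).

The mosaic boundary is a convention (the source material names the
categories but not the rule); outputs carry `rule_v1` so downstream
consumers can see which convention produced the call. In particular
{ref, m1, m2} is called mosaic. `min_clone_support` (default 1 — no
suppression) can drop alleles seen in fewer clones to guard against PCR
chimeras, at the cost of missing low-fraction mosaic alleles.

## Synthetic fixtures

The generator produces everything the pipeline consumes, plus truth
tables, so the whole system is testable offline. Defaults: two 100-kb
chromosomes of i.i.d. sequence at 50% GC; 30 planted sites spanning the
(seed 0–3) × (non-seed 0–6) grid on both strands and both PAM classes,
at least 2 kb apart; ~43 planted mutant variants — the on-target edit,
7 clean survivors, and decoy classes each violating exactly one filter
(shared-with-control, in-database, far-from-site, repeat block,
homopolymer run, GC-skewed patch, SNV) — plus background variants in the
control sets; and a six-founder clone cohort (10 clones each) covering
all five genotype categories, including the classic homozygous 3-bp
deletion.

Construction details that keep the truth table exact:

* the background genome is scrubbed of accidental guide-homologous sites
  before planting (a random 200-kb genome contains a handful at the
  widest budgets);
* protospacers with intrinsic reverse-complement self-similarity are
  rejected at guide-drawing time, and each planted window is locally
  re-scanned — a write that introduces any site other than the requested
  one is undone and redrawn;
* repeat context is written as explicit tandem copies of a mixed 12-mer
  and masked in the BED (no repeat-family biology is simulated — the
  filter tests interval logic); homopolymer runs are written two bases
  longer than the filter threshold to avoid boundary ambiguity; GC
  patches are drawn at 88%/10% GC with homopolymers excluded so exactly
  one filter fails;
* anchor bases around planted deletions are rewritten so normalization
  cannot shift a variant out of its designed context;
* every placement is verified against the package's own scanner and
  filter predicates, and the finished construction is verified globally
  (full re-scan plus full cascade against the truth table) with bounded
  deterministic redraws.

Every generator is a deterministic function of its seed; regeneration is
byte-identical, which the suite asserts file by file.

What passing on these fixtures does *not* show: performance on real
mammalian genomes (repeat families, segmental duplications, strain-level
variation), caller-specific error modes in the input VCFs, PCR/cloning
artifacts beyond i.i.d. substitution noise, or any wet-lab validation
outcome. The fixtures demonstrate the logic of the screen, not the
biology of a particular genome.

## Problem sizes used in the shipped checks

The pytest suite runs the scanner-vs-oracle equivalence at 10 random
genomes of 50–100 kb over the full budget grid and both PAM sets;
monotonicity on 20 randomized instances; normalization on 1000+
enumerated equivalent encodings; allele calling on every single indel of
size 1–10 bp at every interior offset of a 200-bp amplicon; and the full
pipeline on the seed-42 fixture. `scripts/acceptance.py` recomputes the
same quantities from a user-supplied seed with the scanner check at 4
genomes of 30–60 kb; both complete in well under a minute on one CPU.

## Known limitations

* The scanner is a naive-equivalent exact scan: fine at desk scale and
  for the fixture sizes here, but an FM-index or seed-anchored prefilter
  would be needed for mammalian genomes.
* No bulge (indel-tolerant) guide-to-genome alignment; mismatch-only.
* No specificity scoring (CFD/MIT-style); ranking is purely the
  lexicographic mismatch/distance order.
* Multi-indel subclone reads are summarized by net length change plus
  the first edit position; genuinely complex alleles are distinguishable
  but their descriptors are not a full edit script.
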