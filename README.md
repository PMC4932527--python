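# otscreen

Off-target screening for CRISPR/Cas9 animal-editing experiments, from
whole-genome variant calls to a ranked, validation-ready candidate list —
plus founder genotype classification from Sanger subclone reads.

## Who this is for

Groups that edit animals (or cell lines) with Cas9, sequence the edited
founders and a wild-type control, and need to answer: *did the guide cut
anywhere it should not have?* The package takes a reference genome
(FASTA), per-sample variant calls from a standard caller (VCF), a repeat
mask (BED), and one or more guide definitions, and produces the candidate
off-target sites worth amplifying for Sanger validation. It also
classifies founders as wild type / heterozygous / homozygous / compound
heterozygous / mosaic from their subclone amplicon reads.

## The method

A candidate off-target site is a **private indel near a guide-homologous
locus**. Concretely:

1. **Scan** — every 20-bp window on either strand whose 3'-adjacent 3-mer
   matches an allowed PAM (NGG, optionally NAG) is scored by Hamming
   mismatches against the protospacer, split at the seed boundary: a
   window is a predicted locus iff

   `seed_mm ≤ 3` (over the 12 PAM-proximal nt) and `nonseed_mm ≤ 6`.

   The scan is exact — its contract is set-equality with an exhaustive
   sliding-window comparison, which the test suite enforces.
2. **Filter** — mutant indels survive iff they are (i) *private*: the
   left-aligned, parsimonious allele appears in no control genome, panel
   genome, or variant database; (ii) in clean sequence context: outside
   the repeat mask, neither 10-bp flank a homopolymer run, flanking GC
   within [20%, 60%]; and (iii) within 500 bp of a predicted locus.
   Every variant gets a per-filter audit trace.
3. **Rank** — survivors are ordered by `(seed_mm, nonseed_mm, distance)`
   ascending; those with fewer than 2 seed mismatches are selected for
   validation and a ~600-bp amplicon window is extracted around each.
4. **Genotype** — subclone reads are globally aligned to the reference
   amplicon; alleles are reported as net length changes at left-aligned
   positions (`-3@301` = 3-bp deletion at position 301) and each founder
   is classified from its distinct-allele composition.

A synthetic-data module generates complete, truth-tabled fixtures —
genomes with planted loci of controlled mismatch composition,
multi-sample VCFs with planted survivors and single-filter decoys, masks,
and clone reads — so the entire pipeline is testable with no downloads.
See `docs/methods.md` for the full model description and conventions.

## Worked example

Generate a fixture and run the whole screen through the CLI:

```sh
otscreen simulate --seed 42 --out fx
# fixture written to fx: 30 planted sites, 43 planted variants, 6 founders

otscreen scan --genome fx/genome.fa --guide guideL1:GACCTAAAATCCGTGACGTT \
    --out sites.tsv
# 30 predicted sites written to sites.tsv

otscreen filter --mutant fx/mutant.vcf \
    --control fx/wt.vcf --control fx/panel_1.vcf \
    --control fx/panel_2.vcf --control fx/panel_3.vcf \
    --db fx/db.vcf --mask fx/mask.bed --genome fx/genome.fa \
    --sites sites.tsv --out-dir filt
# 8/43 variants survive; outputs in filt

otscreen rank --candidates filt/candidates.tsv --genome fx/genome.fa \
    --out-dir rank
# 8 candidates ranked, 3 selected for validation; outputs in rank
```

The top of `rank/ranked.tsv`:

```
rank  chrom  pos    ref   alt  vtype      ...  seed_mm  nonseed_mm  distance  selected
1     chr1   22250  CACG  C    deletion        0        0           0         True
2     chr2   40279  GTTT  G    deletion        1        0           351       True
3     chr2   48847  T     TC   insertion       1        1           128       True
4     chr2   54028  C     CT   insertion       2        3           287       False
```

Rank 1 is the on-target edit itself — a deletion sitting at distance 0
inside the exact-match locus, recovered with zero seed and non-seed
mismatches, exactly as a sound screen must. Ranks 2–3 have fewer than 2
seed mismatches and are selected; their amplicon sequences are in
`rank/amplicons.fa`. Each of the other 35 mutant variants fails exactly
one filter, recorded per-variant in `filt/trace.tsv`.

Founder classification from the fixture's clone reads:

```sh
otscreen genotype --reads fx/clones.fa --amplicon fx/amplicon.fa --out-dir geno
```

```
animal_id              category  n_clones                        alleles    rule
      F01            homozygote        10                      -3@301x10 rule_v1
      F02 compound_heterozygote        10              +1@305x5,-3@301x5 rule_v1
      F03                mosaic        10 -3@305x3,0x3,+2@309x2,-7@313x2 rule_v1
      F04             wild_type        10                           0x10 rule_v1
      F05          heterozygote        10                   -3@305x5,0x5 rule_v1
      F06 compound_heterozygote        10              -2@301x6,-5@304x4 rule_v1
```

F01 carries the same 3-bp deletion in all ten clones — a homozygote;
F03 shows four distinct alleles, the signature of post-zygotic (mosaic)
editing. `otscreen verify-fixtures fx` re-derives every truth-table
property and reports `0 discrepancies`.

Real data drop in the same way: your genome FASTA, your caller's VCFs,
your RepeatMasker/WindowMasker BED, your guide sequence.

## Layout

```
src/otscreen/
  core_io.py             FASTA/VCF/BED I/O, coordinates, indel normalization
  target_search.py       guide-homology genome scanner (seed/non-seed, PAM)
  variant_filters.py     privacy + context + proximity filter cascade
  ranking_report.py      ranking, validation selection, amplicons, summaries
  founder_genotyping.py  allele calling and genotype classification
  synthetic_data.py      truth-tabled fixture generator and verifier
  cli.py                 otscreen scan|filter|rank|genotype|simulate|verify-fixtures
```

## Scope

Upstream read alignment and variant calling (BWA/GATK et al.) are
consumed, not reimplemented; repeat masks are inputs. No bulge-tolerant
guide alignment, no CFD/MIT specificity scores, no primer thermodynamics,
no chromatogram parsing — see the non-goals in `docs/methods.md`.
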