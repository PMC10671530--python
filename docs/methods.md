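# Methods

This note documents the models, conventions and numerical choices behind
`allelecall`, and what the synthetic-data generator does and does not
emulate.

## Substrate and coordinates

All stages operate on a gap-aware multiple alignment over `{A,C,G,T,N,-}`
with a region map assigning columns to 5′ region, exons, introns, 3′ region
and a neutral baseline. Coordinates are 0-based half-open internally; CLI
reports are 1-based inclusive. Only the '+' strand is supported — inputs
must be pre-oriented, and no alignment is computed (inputs are pre-aligned).
`N` participates in no difference call anywhere: it is treated as missing
data, never as a mutation.

## Allele calling

A *defining difference* separates two alleles:

* a 5′ difference outside a homopolymer string,
* a coding difference that changes the protein (nonsynonymous, premature
  stop, or frameshift), or
* a 5′ string difference accompanied by ≥1 additional independent
  non-string difference anywhere in the allele span.

Conventions adopted where the rules leave room:

* *Strings* ("runs of more than 3 bp of one nucleotide") are implemented as
  runs of degapped length ≥ 4, detected on the degapped sequence and mapped
  back to alignment columns; a difference is `in_string` when its columns
  intersect a run interval of **either** sequence being compared, which
  captures slips at run edges.
* A contiguous run of gap-vs-base columns with the same gapped side is
  **one** indel event anchored at its leftmost column. Mutation counts are
  event counts, not column counts.
* "Independent" corroborating change = any non-string difference anywhere
  in the allele span; no distance requirement is imposed.
* Synonymous-only coding divergence and (by default) 3′-only differences do
  not define alleles; both are retained as within-allele variation. A
  `three_prime_defining` flag flips the 3′ rule.
* The baseline region is co-genomic neutral sequence and never informs
  allele identity.
* Grouping is single-linkage over the same-allele/allelet relation. An
  intransitive triangle (A~B, B~C, but A≁C) cannot arise from clean data;
  if present it is resolved by a greedy split keeping the leftmost
  representative, with a warning. Allele names are `<locus>_a`, `_b`, … in
  input order of first representative (`name_by="count"` orders by
  decreasing member count); allelets get the parent name plus a prime.

## Ancestry painting

Informative sites are columns where the parents differ; a column where
exactly one parent is gapped is informative (gap as fifth state), shared-gap
and N columns are skipped. The hybrid is matched exactly: `A`, `B`, or
`neither` (candidate new mutation). Segmentation is minimal-switch: runs of
consecutive same-origin sites, with `neither` sites transparent — they
neither break nor switch segments. Breakpoints are open intervals between
the flanking informative sites of opposite origin, never point estimates;
summary tables use the interval midpoint. Spans before the first and after
the last informative site are `unknown`. Minimality is exact by
construction and verified against exhaustive search in the tests.

Isolated conflicting sites (e.g. A,B,A) keep both switches under parsimony;
no smoothing is applied by default. Parental-contribution fractions are
per-region shares of informative sites; the A-biased/B-biased/balanced
label uses a 0.6 threshold, a reporting convention exposed as an option,
not an inference.

## Mutation catalogue

**Hybrid mode** records every event where an allele representative differs
from both parents (exactly the `neither` sites plus merged indels). A
derived state shared by several — or all — alleles is one record carrying
all of them: fixed post-hybridization mutations still count, and locus-level
tallies count unique events. Exon substitutions are classified against the
reading frame of the locally matching parent per the allele's own painting
(falling back to parent A in unknown spans); exon indels are frameshift
unless their residue count is a multiple of 3 (then in-frame,
nonsynonymous). Sharing labels (private / within-subgroup / across-
subgroups) are filled when all carriers have subgroup labels.

**Outgroup/frequency mode** needs ≥10 conspecific haplotypes (fewer
triggers a warning, not an error). "Less than 30 %" is implemented as a
strict `<` on the minor-state frequency, counting haplotypes; a
`strict=False` switch gives `≤`. Frequency denominators exclude haplotypes
with N or a gap at the site. Tentative calls whose minor state the outgroup
shares are excluded as ancestral; columns where only the outgroup is gapped
are unresolved — retained with a flag, since single-outgroup parsimony
cannot decide. The error rate is excluded/tentative, reported to 2
decimals. There is no ancestral-state reconstruction beyond this single-
outgroup parsimony and no recurrent-mutation or context-dependent rate
model.

## Selection statistics

* **Mutation density** = events per aligned nucleotide of a region, a
  per-site quantity; the comparison period (time since the common ancestor
  of the sampled genomes) is interpretive metadata, not a divisor. Reports
  round half-up to 4 decimals, matching table conventions; raw values are
  retained and tests compare raw values.
* **Baseline test**: default is Welch's unequal-variance two-sample
  one-tailed *t*-test between per-allele region rates and per-allele
  baseline rates, with the tail chosen by the observed ordering (`tail`
  option for a pre-specified direction); a paired-by-genome variant exists
  because baselines are co-genomic, but unpaired is the default since
  summary tables report independent means ± s.e. A one-sample variant
  handles a single allele against a summarized background (mean, s.e., df).
  Degenerate all-identical input reports p = 0.5 with a flag rather than an
  undefined statistic. Directions: significantly elevated region rate →
  positive selection, depressed → negative.
* **Dunn–Šidák**: α′ = 1 − (1 − α)^(1/k); k defaults to the number of
  comparisons run in one invocation (3 for the 5′/coding/cross family) and
  is exposed as `--family-size`. Note 1 − 0.95^(1/3) = 0.016952…, which
  truncates to the conventionally quoted 0.0169.
* **Ka/Ks**: Nei–Gojobori-style counting — fractional synonymous site
  counts per reference codon; observed changes classified per codon with
  multiple-hit codons averaged over all substitution pathways at equal
  weights; pathway steps through stop codons count as nonsynonymous; codons
  containing N or gaps are skipped entirely; a terminal reference stop codon
  is excluded. Ka and Ks are raw proportions without multiple-hit
  correction: at the <2 % divergences targeted here the Jukes–Cantor
  adjustment is far below reporting precision. Ks = 0 with Ka > 0 yields an
  explicitly undefined ratio, never infinity, to avoid spurious positive-
  selection calls. No codon-model maximum-likelihood dN/dS is attempted.
* **Intensity ratio**: two lineages reaching similar accumulated mutation
  densities over time depths T₁ and T₂ imply per-year selection intensities
  in ratio T₁/T₂.

## Synthetic data

The generator emulates the data regime the pipeline assumes: an ancestor;
two parents by independent per-site substitution (default 1 % — a realistic
between-progenitor divergence for a recent plant hybrid; coding divergence
is restricted to synonymous third-position swaps so every sequence stays
frame-clean); hybrid alleles copied from parental segments between planted
breakpoints; planted derived substitutions per region per allele with a
configurable nonsynonymous fraction (default 0.7) and optional intron/5′
deletions; allelets created solely by single-base homopolymer slips in
deliberately written 5′ strings; an outgroup diverged independently from
the ancestor (default 2 %); and optional low-frequency variant planting
(recent vs ancestral, the latter mirrored into the outgroup) for
polarization scenarios. The default layout is a rice-like locus: 1014 nt
5′, 2×1080 nt exons split by an 850 nt intron (long enough to qualify as a
neutral baseline), 150 nt 3′, and an 875 nt downstream baseline; six
alleles sampled in two genomes each, one breakpoint and one 5′ + one coding
derived mutation per allele, across two subgroups.

One `numpy` Generator seeded from the config drives every draw, so equal
seeds give byte-identical FASTA. No column receives two planted changes and
there is no back-mutation: truth stays unambiguous, and at ≤2 % divergence
the multiple-hit bias this ignores is negligible. A truth ledger records
membership, breakpoints, planted events and slip positions, and is verified
at generation time by re-deriving every hybrid from the parental mosaic
plus planted events.

What the generator does **not** emulate — and what green tests therefore do
not show about real data: coalescent genealogy and linkage structure,
recurrent mutation and homoplasy, sequencing error beyond homopolymer
slips, alignment error, heterozygosity (inputs are inbred/haplotype
consensus), more than two parental sources, and selection acting during the
simulation (selection is represented only through planted counts).

## Problem sizes

Tests and the acceptance script run scaled-down loci (300 nt 5′, 2×150 nt
exons, 120 nt intron, 220 nt baseline, 4–10 alleles) for multi-seed sweeps
— 20-seed recovery sweeps and a 10,000-replicate null calibration of the
baseline test — and the full-size default locus for single-run checks.
These sizes were chosen so the entire suite exercises every stage in under
a minute while keeping ≥30 planted breakpoints and ≥100 informative sites
in the properties that need them.

## Known limitations

* Allele calling is O(n²) pairwise over hybrid haplotypes; fine for panels
  of tens, not thousands.
* Coding-effect classification of substitutions in alleles that already
  carry a frameshift uses the unshifted parental frame downstream of the
  indel.
* Outgroup-mode coding classification uses the first conspecific haplotype
  as frame reference.
* Breakpoints falling in the same inter-site interval as another breakpoint
  cancel under minimal-switch parsimony and are invisible, as for any
  parsimony painter; the recovery guarantee applies to breakpoints with at
  least one anchored informative site in each adjacent planted segment.
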