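# Methods

## The measurement model

AFLP and MSAP are dominant marker systems: a locus is a band of a given
electrophoretic mobility under a given selective primer combination, and a
lane (one individual in one digest) either shows the band (1) or does not
(0).  Heterozygotes are indistinguishable from dominant homozygotes, and a
band absent from every lane of a genotype carries no information — the
analysis therefore works entirely on presence/absence calls and excludes
all-absent loci from its denominators.

For MSAP, each sample is digested in parallel with EcoRI–HpaII and
EcoRI–MspI.  HpaII is blocked by full methylation of the internal CCGG
cytosine on both strands but cuts hemimethylated sites; MspI cuts
internal-cytosine-methylated sites but is blocked by hemimethylation of
the external cytosine.  The canonical reading of the per-locus band pair
(HpaII, MspI) is: (1,0) hemimethylated, (0,1) fully methylated, (1,1)
unmethylated, (0,0) uninformative for level summaries.  This reading
cannot see states that block both enzymes (e.g. methylation of both
cytosines), a standard limitation of the assay.

## Consensus calling

Published tables report one 0/1 state per genotype, but gels score several
replicate individuals per group.  The collapse rule is a support
threshold: the group call is 1 iff the fraction of its individuals showing
the band is ≥ `threshold`.  The default 0.5 (majority rule) is the least
assuming total rule; `threshold=1.0` reproduces the common MSAP practice
of scoring only bands monomorphic within a group, and with one individual
any threshold reproduces that individual.  Ties count as present because
the rule uses ≥, which keeps it total and monotone: raising the threshold
can only switch calls 1→0.  The exact fixtures generate unanimous
individuals, so every threshold reproduces the published patterns and the
choice of rule is immaterial there.

Missing gel calls are handled at parse time (`missing_token`, default
`NA`): the default policy rejects them, matching the strict binary
convention of the scored matrices; the `absent` policy scores them 0.
Because the matrix invariant requires strictly binary cells after
validation, missingness does not survive into consensus denominators —
a lane scored absent is counted as absent, not dropped.  Data sets with
substantial unreadable-lane rates should be filtered upstream.

## Classifications

**AFLP fragment types.**  With the reference call first: (0,1) → A
(derived-specific, gained fragment), (1,0) → B (reference-specific, lost
fragment), (1,1) → C (shared), (0,0) excluded.  Percentages are of
A+B+C; the changed fraction is (A+B)/(A+B+C).

**Methylation levels.**  Per genotype, states are tallied over its own
informative loci (non-absent), not over a cross-genotype union, so two
genotypes may legitimately have different denominators.  Total
methylation is (hemi + full)/informative.

**Pattern changes.**  The quadruple (derived HpaII, derived MspI,
reference HpaII, reference MspI) is classified by exhaustive lookup:

* A (unchanged, 3 quadruples): identical observable band pairs.
* B (demethylation, 5): the derived genotype shows strictly less
  methylation — a methylated or absent reference pattern resolving toward
  (1,1), or a band newly appearing from an all-absent reference.
* C (hypermethylation, 5): the mirror images of B.
* UNCLASSIFIED (2): the hemi↔full swaps (1,0|0,1) and (0,1|1,0), which
  change the pattern without a defensible direction on the
  less-/more-methylated axis.  They are reported but kept outside the
  A/B/C denominator; assigning them to B or C would silently shift the
  headline percentages.
* EXCLUDED (1): (0,0,0,0), unobservable.

The taxonomy partitions all 16 quadruples, and swapping the genotypes is a
bijection B↔C fixing every other class — both facts are asserted by
enumeration in the test suite.  A locus is class A exactly when its two
methylation states are equal and not both absent.

**Two-proportion comparison.**  Total-methylation rates of the two
genotypes are compared by a continuity-corrected chi-square test on the
2×2 table [(methylated, unmethylated) × genotype], computed with
`scipy.stats.chi2_contingency(correction=True)`; the result carries the
table for audit.  With identical proportions the statistic is 0 and p = 1.

## Rounding

All percentages are rounded to 2 decimals, half-away-from-zero, at report
time only; internal arithmetic is on exact counts, and the division is
done in decimal arithmetic so the printed value is the true rounded
rational (181/552 → 32.79).  Published companion percentages that are
arithmetically inconsistent with their own printed counts (the
non-methylation row of the level table; the B/C split of the pattern
table) are recomputed from the counts, which are treated as authoritative:
137/300 = 45.67%, 205/409 = 50.12%, 94/388 = 24.23%, 140/388 = 36.08%.

## The synthetic-data generator

`simulate_msap` draws a true state per locus from `ref_state_probs`
(order HEMI, FULL, NON, ABSENT), transforms it through a 4×4
row-stochastic transition matrix into the derived genotype's state, maps
states to canonical band pairs, and scores each individual lane
independently: a truly present band is missed with `dropout_rate`, a truly
absent band appears with `spurious_rate`.  One seeded generator per call;
identical parameters and seed give byte-identical serialized matrices.

The shorthand change model builds the transition matrix from two rates:
with `p_demethylation` a methylated (HEMI/FULL) site becomes NON; with
`p_hypermethylation` a NON site gains full methylation and a HEMI/FULL
site gains enough methylation to block both digests (ABSENT).  Every
shorthand transition lands in the A/B/C taxonomy (no mass on the
unclassifiable swaps), which makes injected rates identifiable from the
class tallies.

Defaults mirror the study design the classifiers assume: 10 individuals
per genotype, 400 loci, reference state probabilities
(0.40, 0.1433, 0.4567, 0) taken from the diploid's observed level tally,
change rates `p_demethylation=0.45`, `p_hypermethylation=0.36` giving
expected B/C fractions near the observed pattern-change split, and
dropout = spurious = 0.02 as a conventional gel-scoring error rate (the
source data report no within-group polymorphism from which to estimate
it).  `simulate_aflp` is the two-state analogue: 371 reference bands
(loss rate 0.485) plus a gained pool of derived-only bands (gain rate
0.488 per reference locus) — gains are new fragments, modelled as new
loci rather than 0→1 flips of scored reference bands, which keeps locus
counts interpretable.  Both matrices share the full locus list so
downstream summaries align.

What the generator does **not** emulate: band co-migration artifacts
(distinct fragments scored as one locus), fragment-size binning error
across gels, correlated scoring noise within a gel, population structure
among individuals (replicates are clonal, as for full-sib fish), and any
sequence-level process at CCGG sites.  Passing recovery tests therefore
show the pipeline is correct under independent per-lane noise, not that
real gels meet that assumption.

`estimate_change_rates` reports class fractions with Wilson score
intervals (default 95%, via statsmodels), pinned to exact 0/1 bounds at
empty/full counts.  A 200-replicate experiment in the test suite checks
≥ 90% empirical coverage of the true altered rate.

## Exact fixtures

`build_paper_fixture` emits one locus per published counted site with the
corresponding pattern and unanimous individuals.  The fragment fixture
(552 AFLP loci) and the pattern fixture (388 MSAP loci, both genotypes in
one matrix) are single matrices; the level fixture is two single-genotype
matrices (300 and 409 informative loci) because the published per-genotype
tallies are not locus-aligned across genotypes — the published totals
(704 bands vs 300+409 vs 388 pattern sites) are not mutually consistent,
so no single matrix reproduces level and pattern tallies simultaneously,
and the two views are kept as separate fixtures.  The CLI's
`--join outer` option lets per-group files scored on different band sets
be combined, scoring a band absent in gel sets that never recorded it.

## Problem sizes and numerical choices

Recovery tests use 10,000 loci (binomial SE ≈ 0.005 at rates near 0.3,
so ±3 SE is a tight check) and the coverage experiment uses 200
replicates of 500 loci — all sizes chosen so each property is checked
well inside desk scale.  Thresholds compare with ≥ throughout;
percentages are validated to sum to 100 within ±0.02 after rounding.
Degenerate inputs (no lanes for a group, zero informative loci, empty
matrices, invalid probability vectors) raise typed errors rather than
producing silent zeros.

## Known limitations

* Dominant markers cannot separate heterozygous from homozygous band
  presence, and MSAP cannot distinguish sequence loss of a CCGG site from
  methylation states blocking both enzymes — (0,0) patterns conflate the
  two.
* Band matching across gels (size binning) is assumed done upstream; the
  locus label is the join key.
* The hemi↔full swap patterns are intrinsically direction-less in this
  taxonomy; data sets rich in such transitions will see a large
  unclassified remainder, which the report surfaces.
* The two-proportion test treats loci as independent Bernoulli trials,
  ignoring linkage between co-migrating fragments.
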