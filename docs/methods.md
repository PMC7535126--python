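# Methods

This note records the models implemented, the parameter defaults and why,
the numerical choices, and what the synthetic data does and does not show.

## Variant filtering

Post-calling filters are conjunctive predicates over VCF records: site
quality strictly > 30 (PHRED), alt-supporting allele count strictly > 2, at
most 10 alleles, SNPs within 3 bp of an indel removed, call rate < 70%
removed (exactly 70% is retained), SNPs overlapping a user-supplied repeat
mask removed. "Within 3 bp of an indel" is measured from the indel's
reference-span boundaries (|SNP pos − boundary| ≤ 3); the anchor is not
standardised anywhere, and boundary distance is the common reading. Records
with N alleles are skipped with a logged warning rather than failing the
run. Because the filters are a conjunction, their order cannot change the
result; the implementation also reports per-reason removal counts that
reconcile with the input count.

## Polarization and the derived class

A bi-allelic SNP is polarized by the ancestral-genome base at its position:
if it matches the reference allele the alternative is derived, if it
matches the alternative the reference is derived, otherwise the site is
rejected. Lowercase ancestral bases are treated as low-confidence calls
(the Ensembl ancestral-FASTA convention) and rejected with a distinct
reason code, as are N bases. DAF is computed over called genotypes only.

The derived (proxy-benign) class collects (a) positions where reference and
ancestor disagree with both bases in {A,C,G,T}, excluding sites where the
ancestral allele still segregates above 5% frequency, plus (b) segregating
sites with derived frequency strictly above 90%. The boundary conventions
(strict > 0.90, strict > 0.05, inclusive DAF ≤ 10% for "rare") follow the
printed thresholds literally. When the derived and simulated classes differ
in size, the larger is downsampled uniformly to balance them.

## The variant simulator

Substitution rates are estimated in non-overlapping windows (default
100 kb): rate(X→Y, w) = (# positions in w with ancestor X, descendant Y) /
(# ancestor-X positions in w), N positions excluded from both counts.
Simulation draws windows with probability proportional to their observed
mismatch counts — so simulated density tracks observed derived density —
then a uniform non-N position within the window, then an alternative base
proportional to the window's rates for the position's ancestral base.
Unusable rate rows fall back window → chromosome → genome. Positions are
unique; a duplicate or unusable draw is retried, and 1,000 consecutive
failures raise a position-exhaustion error (bounded termination).
Context-dependent (e.g. trinucleotide/CpG-aware) mutation models are out of
scope; consequently the simulator reproduces the marginal substitution
spectrum and regional intensity but not context effects.

## Feature engineering

The design matrix is built in four steps: numeric imputation with
schema-declared values; one-hot expansion of categoricals (a missing value
becomes an all-zero block — the same pattern as the availability-gated
scores, rather than an explicit "missing" level); availability indicator
columns for conditionally defined scores, with the value column imputed
where unavailable; and categorical-block × numeric interaction columns.
Finally every column is divided by its sample (n−1) standard deviation —
no centering, since only scaling is part of the procedure and the intercept
absorbs offsets. Constant columns are left unscaled and flagged. Scale
factors and imputation values from training are stored and re-applied when
scoring new variants; scaling commutes with row subsetting by construction.
A real production schema is user-supplied configuration; the bundled
demonstration schema (conservation score, consequence category, distance to
TSS, GC content, availability-gated substitution score) exists to exercise
every encoding path, not to approximate the full 874-column configuration a
genome-scale run would use.

## Classifier and score

The classifier is L2-penalized logistic regression (scikit-learn,
C = 1/λ), one fit per penalty in {0.1, 1.0, 10.0} on a label-stratified
10:1 train/test split. The returned model minimizes test log-loss with
ROC-AUC as tiebreaker — log-loss first, matching the selection order the
procedure prescribes. Log-loss uses natural log with probabilities clipped
at 1e−15; ROC-AUC is the tie-corrected rank statistic.

Posteriors are converted to scores by ranking (descending; ties all receive
the maximum rank of their group, the conservative, less-deleterious
assignment — with continuous posteriors this affects nothing) and applying
score = −10·log₁₀(n/N). N is a user parameter: 3 × the assembly length of
the scored chromosomes for a real genome, 3 × the toy genome length on
synthetic data. The transform is strictly decreasing in rank, bounded by
[0, −10·log₁₀(1/N)], and without ties the fraction of variants scoring ≥ s
is exactly 10^(−s/10).

## Conserved-element annotation

Elements shorter than 4 bp or overlapping an assembly gap by ≥ 1 bp are
discarded. Promoters are the 2-kb region upstream of the TSS, emitted only
for genes with an annotated 5'UTR of ≥ 15 bp, truncated at chromosome ends.
Each element takes the highest-priority feature class it overlaps by ≥ 1 bp
in the fixed order CDS, 5'UTR, 3'UTR, promoter, RNA-gene, lncRNA, intronic,
intergenic; no minimum overlap fraction is imposed (overlap, not
containment, since the choice is otherwise arbitrary for short elements).
CNEs are elements whose class is lncRNA, intronic or intergenic. SNP
density is SNP count over the *union* of an interval set divided by union
length, so duplicated intervals count once. Windowed density correlations
(Pearson, two-sided p) come in a raw mode (per-window counts, final partial
windows dropped) and a scaled mode (counts divided by window length minus
coding bases, partial windows kept and coverage-scaled) — both exposed
because the treatment of partial windows is genuinely open.

## Change-point subregions

Each element's per-base score vector gets 5 bp flanks on both sides so the
inner subregion's borders may coincide with the element's borders. The
flanked signal is segmented by binary segmentation under the RBF kernel
cost c(a,b) = (b−a) − (1/(b−a))·Σ K(xᵢ,xⱼ), with the Gaussian bandwidth set
by the median heuristic over the element's own pairwise squared distances
(γ = 1/median; γ = 1 for a constant signal). The first split minimizes
total cost over the whole signal; each side is then searched independently
and the split with the larger cost reduction is kept, giving two change
points and three subregions. Minimum segment length is 2 — the smallest
value for which a subregion variance exists. Constant signals are returned
flagged degenerate. On noiseless two-step signals the greedy search
provably coincides with the exhaustive two-change-point optimum (verified
against an exhaustive oracle in the tests); on noisy signals it is a greedy
approximation and recovery is assessed within ±1 position.

Subregion elevation is tested with two two-sided Welch t-tests (1st vs 2nd,
3rd vs 2nd) — Welch because the procedure expects unequal spreads between
the flat outer and elevated inner subregions. An element passes iff both
p ≤ 0.05 *and* the inner mean exceeds both outer means; passing elements
are ranked by decreasing inner-minus-pooled-outer mean difference, with
genomic coordinate as the documented tiebreak. No multiple-testing
correction is applied across elements, reproducing the procedure as stated;
a Benjamini–Hochberg switch would be a one-line addition but is deliberately
left off by default. Note that because the change points are themselves
chosen to maximize segment heterogeneity, the composite test applied after
segmentation is anti-conservative on null *signals* (the examples show ~10%
of unplanted elements passing); the null calibration in the test suite
therefore uses randomly placed partitions, where the individual Welch test
rejects at its nominal 5% and the composite verdict is conservative (≪ 5%).

Cohen's D is the absolute standardized mean difference with pooled
(n−1-weighted) standard deviation; zero pooled sd with equal means is 0 by
convention, with distinct means it is undefined and reported as NaN.
Per-section SNP densities (5bp-up, 1st, 2nd, 3rd, 5bp-down) intersect the
subregions with the element body, map back to genome coordinates, and
report empty sections as NaN.

## Synthetic worlds

`synthetic.make_world` generates every input at toy scale with planted
truth. Defaults — chosen once as the study conditions for all tests:

| parameter | default | rationale |
|---|---|---|
| genome length | 1 Mb, one chromosome | large enough for 10 rate windows and thousands of SNPs, small enough for seconds-scale runs |
| samples | 50 diploid | ~10⁴ segregating sites at the densities below |
| reference↔ancestor divergence | 0.02 | a few percent, typical of a galliform-depth ancestor comparison |
| rate-window multipliers | log-uniform 0.5–2× per 100 kb | regional mutation-rate variation for the simulator to track |
| neutral segregating density | 0.02 /bp | matches the unconstrained SNP density scale observed in dense resequencing |
| constrained suppression | 2× | mirrors the two-fold CNE vs non-CNE density contrast |
| constrained fraction | 20% in alternating 50-kb tiles | enough constrained bases for well-powered two-proportion tests |
| DAF spectrum | mass ∝ 1/i, ×e^(−3i/2n) when constrained | discretized neutral spectrum; the exponential decay is the minimal selection-like rare-shift without a coalescent simulator |
| score signal | background 5, planted inner step +10, noise sd 1 | the inner-subregion recovery regime the change-point analysis targets |
| annotation model | planted logistic coefficients (1.5, −1.0, 0.8) | gives the classifier a known target for recovery tests |

What the world does *not* emulate: linkage disequilibrium (sites are
independent), realistic karyotype or GC landscape, context-dependent
mutation, gene-structure realism beyond a fixed UTR/CDS/intron template,
and ascertainment noise in ancestral inference. Passing tests on this world
therefore demonstrate the correctness of the algorithms and the direction
of the population-genetic contrasts, not genome-scale effect sizes: the
published genome-scale numbers depend on real data and are not reproduced
here.

`make_step_signals` generates flanked piecewise-constant signals with two
planted change points for segmentation calibration; with zero noise the
planted points are recovered exactly, with noise sd 1 and step 10 recovery
is within ±1 position in ≥ 95% of elements.

All generators consume a single integer seed through
`numpy.random.default_rng`; regenerating with the same seed is
bit-identical, and truth files record constrained coordinates, planted
change points, gene models and planted coefficients.

## Problem sizes used by the test and acceptance suites

Classifier recovery uses n = 50,000 rows (coefficient consistency),
separability checks 5,000; change-point oracle equivalence 200 noiseless
and 200 noisy elements; null calibration 1,000 elements; simulator fidelity
10⁵ draws; population-genetic direction tests the default 1 Mb / 50-sample
world. These sizes make every statistical assertion well-powered while the
whole suite runs in well under a minute of compute per module.

## Known limitations

- The greedy binary segmentation is not the global two-change-point
  optimum on noisy signals; the oracle-equivalence guarantee is for clean
  two-step signals only.
- Ranks are computed over whatever score universe is supplied; scoring a
  subsample against a genome-sized N assumes the subsample's posterior
  distribution matches the genome-wide one.
- The filter for SNPs near indels uses only indels present in the same
  record set; indels filtered out earlier by quality are still used as
  proximity anchors (they were observed, even if unreliable as variants).
- Multi-allelic sites are not polarized; they are excluded upstream by the
  bi-allelic requirement.
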