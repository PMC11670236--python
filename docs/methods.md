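# Methods

`clonal-surveil` implements two linked analyses of a treated-vs-untreated
bone-marrow study in a mouse model of spontaneous plasma-cell malignancy:
(1) classification of single plasma cells as malignant or nonmalignant from
gene-signature module scores, and (2) surveillance of the heavy-chain B-cell
receptor repertoire — clonotyping, somatic-hypermutation burden, isotype and
V-family spectra, canonical-clone (VH1-72 / W33L) tracking, clone sizes, and
Kullback–Leibler sequence logos — with the exact small-sample statistics
appropriate for cohorts of 5–16 animals per arm.  A synthetic-data generator
plants all of these effects with known ground truth so every stage can be
validated by recovery.

## Module scoring and malignancy classification

A cell's score for a gene set *S* on log-normalized expression
(counts scaled to 10,000 per cell, then log(1+x)) is

    score(c) = mean_{g in S} x_cg − mean_{g in C} x_cg

where the control pool *C* is built by ranking all genes by mean expression
across cells, cutting them into `n_bins` equal-size bins (default 24; ties
broken by gene-list order for determinism), and sampling `n_ctrl` control
genes (default 100; the pipeline default is 50, sized to its simulated
~1,500-gene universe of roughly 60 genes per bin) per set gene from the set
gene's bin, excluding all set genes.  Controls are pooled with multiplicity;
one seeded stream per call makes sampling reproducible.  Two exact
consequences anchor the tests: with one bin and all non-set genes as
controls the score equals (set mean − non-set mean), and adding a constant
to every gene of one cell changes that cell's score by exactly zero.

Plasma cells are gated before scoring: log-normalized expression above a
threshold (default 0) for at least one of Sdc1/Xbp1/Prdm1 and for none of
the excluded markers (Cd19).  Classification is dual-percentile: malignant
iff the malignant-signature score is at or above its 80th percentile **and**
the nonmalignant score at or below its 20th percentile; the mirror condition
defines nonmalignant; all other cells are unclassified.  Quantiles are
linear-interpolation quantiles computed over all gated cells pooled across
samples (pooling keeps scores comparable across arms; a per-sample variant
would localize the percentiles and is a one-line change at the call site).
Boundary comparisons are inclusive.  The compound score is
malignant − nonmalignant (higher = more malignant); a `compound_sign` flag
flips the convention for readers who prefer the opposite subtraction.
Compound-score histograms use half-open bins `[k·w, (k+1)·w)` of width 0.2
anchored at 0, with per-group frequencies in percent.

Differential expression between arms is a per-gene two-tailed rank-sum test
(tie-corrected normal approximation) with Benjamini–Hochberg adjustment and
log2 fold change of group means (pseudocount 1e-9).  Constant genes get
p = 1 by convention and are flagged.

## Repertoire analyses

Clonotypes are defined as records sharing the same V call, the same J call,
and CDR3 amino-acid identity ≥ 0.80 (inclusive).  Identity is Hamming
identity on equal-length CDR3s — records of different CDR3 length never
share a clone — and clustering is single-linkage (connected components of
the identity graph), which makes the partition invariant to record order;
complete linkage is available as an option.  A clone's mutation burden is
the mean VH mutation frequency over its **distinct** variant sequences
(each clonotype variant counted once).  Mutation frequency of a record is
the percent of aligned non-gap positions at which the V sequence differs
from its germline.

The "highly mutated expanded clonotype" frequency uses strict filters:
clones larger than 10 cells with mean mutation frequency above 2% (both
boundaries excluded).  Three denominator conventions are implemented; the
default reports the fraction of **sequences** belonging to qualifying
clones among all sequences in the sample, which is the quantity a
multiplicative depletion of clone sizes moves multiplicatively, and the two
clone-count conventions (qualifying clones, all clones) are available via
the `denominator` parameter.  An empty denominator reports missing, not 0.

Canonical-clone tracking extracts the 8-residue CDR1 window from the
aligned V region using the germline annotation (`cdr1_aa_start`, 1-based),
translates it, and classifies window position 8 — VH amino acid 33 — as
W (germline), L (the affinity-enhancing W33L replacement), or other.
Records whose alignment does not cover the window are flagged and excluded
from the counts.  Sequence logos are signed Kullback–Leibler logos: with
observed count c, column total n, background q (default uniform 1/20) and
pseudocount ψ (default 1, distributed by the background to avoid log 0),

    p = (c + ψ·q) / (n + ψ),   weight = p · log2(p / q)

so enriched residues plot above zero and depleted residues below.

## Exact statistics

Mann–Whitney, Wilcoxon signed rank and Fisher's exact test switch to full
enumeration when sample sizes permit: Mann–Whitney enumerates every
assignment of the pooled mid-ranks for n+m ≤ 12 (ties handled exactly; the
two-tailed p is the permutation probability of a U at least as far from
nm/2 as observed), the signed-rank test enumerates all 2^n sign patterns
for n ≤ 12 (zero differences dropped and counted), and Fisher's exact test
sums hypergeometric probabilities of all tables with the observed margins
whose probability does not exceed the observed table's (the
point-probability two-tailed definition; a zero margin yields p = 1,
flagged).  Above the thresholds the rank tests use tie-corrected normal
approximations with continuity correction; Kruskal–Wallis uses the
tie-corrected chi-square approximation with Dunn's z pairwise follow-up
(Benjamini–Hochberg adjusted by default, Holm optional).  Paired and
ratio-paired t tests are ordinary t tests (the ratio test operates on
logs); degenerate inputs (constant differences) are flagged rather than
producing unstable statistics.  Benjamini–Hochberg adjustment is the
standard step-up with monotonicity enforcement.  Every report records which
method produced its p-value.

## The synthetic-data generator

The generator emulates the measurement situation of the study, not the full
biology.  Expression: counts are Gamma–Poisson (negative binomial,
dispersion 0.5) with lognormal per-cell library sizes (mean 5,000 counts,
σ = 0.3) over 1,500 genes; five cell types (plasma 15%, B 30%, T/NK 20%,
granulocyte 25%, other 10%, 800 cells per sample) carry exclusive marker
genes (40× elevated in type, silent elsewhere) so the plasma gate is
well-defined; two 50-gene signature sets receive a log-scale shift of
`signature_effect` (default 2) in malignant and nonmalignant plasma cells
respectively.  Half of untreated plasma cells are malignant, reflecting
substantial marrow involvement; treated samples carry that fraction divided
by `depletion_factor` (default 10).  The cohort is 5 untreated and
6 treated samples.

Repertoire: 9,000 heavy chains per sample.  The naive compartment
(everything outside the expanded clones) draws V/J uniformly from the
packaged toy germline set (10 V of 294 nt with annotated CDR1 windows, 4 J),
IgM-dominant isotypes, CDR3 lengths 9–15, and mutates at 0.002 per site;
expanded clones (5 per sample) share a (V, J, ancestor CDR3), are
class-switched at the clone level, mutate at 0.05 per site (≈5% VH
divergence, clearly above the 2% filter), and keep members within one
substitution of the ancestor CDR3 (well inside the 80% identity rule at
typical lengths).  Non-canonical clone sizes follow a truncated power law
(exponent 2) on [72, 300]; the floor of 72 keeps sixfold-to-tenfold
depletion from pushing clones below the >10-cell filter, so the planted
multiplicative effect is recoverable rather than truncated by the size
cutoff.  The designated antigen-driven clone uses the VH1-72 analog — a
segment reserved for it, since its usage readout is meant to isolate the
antigen-driven expansion — with a controlled size of 200 members and W→L at
CDR1 window position 8 in 56% of members (untreated).  Treatment divides
every expanded clone's member count by `depletion_factor` (round half-up,
floor 0), leaves the naive compartment untouched, and selects canonical
survivors so the treated W33L fraction is 10%.  With these defaults the
expanded compartment is ~8% of the repertoire, so frequency-normalized
fold recoveries land near the planted factors (the treated total shrinks
slightly, attenuating a planted 10× to ≈9.3× in usage frequency — an
inherent property of frequency readouts, not an implementation artifact).

All outputs are pure functions of (config, seed): one root seed spawns
fixed-purpose child streams (expression; per-sample repertoire via a CRC32
of the sample name; treatment resampling).  What the generator does **not**
emulate: transcriptome-wide co-expression and batch structure, doublets and
ambient RNA, indel hypermutation, light chains, biological sharing of
clones across mice, and selection-shaped substitution biases.  Passing
recovery tests therefore demonstrates the correctness of the analysis
arithmetic and the recoverability of planted effect structure — not
performance on real droplet data.

## Numerical and design choices

- Quantile definition: NumPy linear interpolation; classification
  comparisons inclusive at the boundary.
- Gene-rank ties in score binning broken by gene-list order (stable sort).
- Depletion rounds half-up with floor 0 (deterministic, conservative).
- The clone-size group comparison defaults to clones with ≥2 members.
- Logo letters outside the 20-residue alphabet (X, stops) are excluded from
  column counts.
- Exact-enumeration thresholds (n+m ≤ 12; n ≤ 12) are configurable; they
  cover the cohort sizes this pipeline targets while keeping enumeration
  instantaneous.
- Type-I calibration of the test suite is simulated at sizes where each
  test's null distribution is effectively continuous (30 per arm for rank
  tests, 25 pairs, 3×30 for Kruskal–Wallis, binomial n = 75 per arm for
  Fisher), since exact conditional tests are intrinsically conservative on
  very small discrete tables.
- The classifier recovery grid uses 500 plasma cells per sample
  (625 cells at 80% plasma), 600 genes, signature effects {0, 1, 2, 3} and
  10 seeds — plasma-enriched so the gated population is large at desk scale.

## Limitations

Scores are computed on log-normalized values without cross-run integration;
samples sequenced in different batches would need upstream correction.  The
W33L caller relies on the germline CDR1 annotation rather than a full
numbering engine, so it applies only to segments with annotated windows.
The 80%-identity clonotype rule compares equal-length CDR3s only; a
normalized edit distance variant would merge length-variant clones and is
deliberately out of scope.  The differential-expression module is a
screening tool (rank-sum + BH), not a replacement for count-model DE on raw
data.
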