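# Methods

## The inference chain

The package operationalizes a classification that, in the laboratory,
rests on three experimental axes measured on the same transcripts:
developmental induction (blastula → gastrula), dependence on each of the
three TBP-family initiation factors (single antisense knockdowns), and
dependence on ongoing RNA polymerase II transcription (α-amanitin). A
transcript is **TBP family-insensitive (TFI)** when it is actively
transcribed by either certificate — induced, or α-amanitin sensitive — and
"not affected" by any single knockdown. Downstream, TFI genes are placed
in a genomic interaction network built from ChIP peaks of mesoderm and
organizer transcription factors.

## Change calls

Microarray-style comparisons are decided per transcript from paired
probe-level log2 differences with a one-sided Wilcoxon signed-rank test.
The historical vendor "comparison call" algorithm is proprietary; the
documented substitute here keeps its two essential properties — the test
is paired at the probe level (so probe-affinity offsets cancel) and the
call threshold is a per-comparison *P* < 0.05.

Numerical contract: zero differences are dropped (reduced-sample
treatment); for n ≤ 12 the p-value is the exact tail of W⁺ under sign
randomization, computed by dynamic programming over the (possibly tied,
average-assigned) ranks doubled to integers; for n > 12 a normal
approximation with tie correction and a 0.5 continuity correction is used.
The exact branch is verified against full 2ⁿ sign enumeration in the test
suite. With the default 11 probes per transcript, the smallest achievable
one-sided p is 1/2¹¹ ≈ 4.9 × 10⁻⁴; with four or fewer informative probe
pairs no call can reach α = 0.05, and transcripts with fewer than three
probe pairs are flagged and forced to NoChange.

Replicate handling: comparisons are paired positionally (replicate 1 vs
replicate 1, and so on), and a direction is accepted only if **every**
replicate comparison agrees; all other patterns give NoChange. The
alternative of crossing all replicate pairings is not used.

## Classification rules

All component rules share one gate width, |log2 ratio| > 1.5 (≈ 2.8-fold):

- *developmentally induced*: consistent Increase from stage 7 to stage
  10.5 and mean log2 ratio > 1.5;
- *knockdown dependent* (per factor): consistent Decrease under that
  factor's knockdown and mean log2 ratio < −1.5;
- *α-amanitin sensitive*: consistent Decrease under α-amanitin and mean
  log2 ratio ≤ −1.5;
- *unaffected by all*: for each of the three knockdowns, NOT (consistent
  call in either direction AND |mean log2 ratio| ≥ 1.5).

"Not affected" is deliberately the negation of the *composite* affected
criterion rather than mere absence of a significant call: probe-level
tests flag many small, reproducible shifts, and a transcript moved by 30%
under one knockdown is still, for this biology, insensitive to it. The
stricter call-absence variant is available via
`ClassificationRuleSet(unaffected_requires_fold_gate=False)`.

The α-amanitin classifier uses the same 1.5 log2 gate as the other calls.
The much stronger "reduced below 5% of control" figure is an RT-qPCR-scale
effect; it is kept as the *generator's* effect size
(`amanitin_residual = 0.05`, i.e. −4.3 in log2), not as the array-scale
decision threshold.

## Ratio clustering

Response profiles (knockdown/control, stage 10.5/stage 7 and
α-amanitin/control log2 ratios, one column per replicate) are clustered
with Lloyd k-means (default k = 8) under d(x, c) = 1 − Pearson(x, c).
Rows are standardized to zero mean and unit variance first; on
standardized rows the correlation distance equals cosine distance and rows
have equal norm, so the mean-of-members centroid is the exact minimizer of
the within-cluster distance and the objective is provably non-increasing.
Restarts (default 5) guard against poor seeding; empty clusters are
re-seeded from the farthest point; zero-variance rows carry no correlation
and are assigned to cluster 0 and recorded in
`assignment.attrs["degenerate_rows"]`.

## Count-based differential expression

The knockdown-vs-control count test is a compact negative-binomial
procedure in the spirit of the original NB exact-test formulation:

1. size factors by median of ratios over genes with nonzero counts in all
   samples;
2. per-gene dispersion = max(method-of-moments estimate, trend), with the
   trend a least-squares line on log dispersion vs log mean. The trend is
   fitted to *pooled* bin-level moment estimates (ratio of sums of
   (variance − mean) to squared means within ~20 mean-ordered bins) rather
   than to per-gene values: with two replicates per group the per-gene
   estimates are dominated by sampling noise, and fitting their logarithms
   systematically underestimates the trend. Taking the per-gene maximum
   with the trend makes the test mildly conservative, which is the
   intended bias direction;
3. a two-sided conditioned exact test: given the (normalized,
   integer-rounded) total of both group sums, the treated total is NB with
   mean proportional to its replicate count and dispersion scaled by 1/n;
   the p-value sums the probabilities of all splits as or less likely than
   the observed one, and collapses to the exact binomial split test as
   dispersion → 0;
4. BH adjustment, decreased/increased sets at FDR ≤ 0.10.

This reproduces the qualitative behaviour of the classic tool at desk
scale; it is not bit-compatible with it. On a 2,000-gene null simulation
the empirical type-I error at α = 0.05 falls in the 0.03–0.05 range.

## Over-representation

All enrichment is an upper-tail hypergeometric P(X ≥ k) computed in log
space, with fold = k·N/(n·K) (reported to one decimal in summaries);
depletion is out of scope. The universe is always passed explicitly —
backgrounds change both p and fold, and the package refuses to guess one.
Term (GMT) enrichment intersects every term with the universe before
sizing, adjusts across all tested terms, and reports only terms passing
term size ≥ 10, FDR ≤ 0.05 and fold ≥ 4.

Because the hypergeometric statistic is discrete, raw p-values are
conservative (P(p ≤ t) ≤ t). The calibration test therefore checks exact
uniformity of the *randomized* p-value P(X > k) + U·P(X = k) under a
random-binding null — a strictly sharper check of the tail computation
than eyeballing the conservative raw values.

## Peak filtering and regulatory domains

RPKM of a region is (overlapping reads) × 10⁹ / (library size × region
length); a read counts once per region by any-overlap, with no fractional
assignment. The peak filter computes input-track RPKM over every peak
region of a TF and keeps peaks whose ChIP RPKM exceeds the 99th percentile
(linear interpolation) of that input vector. The threshold is computed per
TF track. The phrase "greater than 99% of the input RPKM" admits a second
reading — exceed 0.99 × the per-region input value — which is available as
`mode="per-region"`.

Domains follow the basal-plus-extension rule with the standard published
defaults (basal 5 kb upstream / 1 kb downstream of the TSS in
transcription orientation; extension to the nearer of the adjacent gene's
basal-domain edge and 1 Mb from the TSS). Tie rules: extension never
retracts inside the gene's own basal domain; overlapping basal domains are
left overlapping; genes whose clipped basal domains share a start
coordinate block neither side. A directed TF → gene edge exists when any
filtered peak overlaps the gene's extended domain (half-open, ≥ 1 bp); a
peak may create several edges. All coordinates are 0-based half-open.

## The synthetic-data generator

The generator is the package's stand-in for embryo data and defines the
conditions under which recovery claims are tested.

Expression model (log2 scale): maternal-stable genes sit at N(9, 0.7) in
every sample; zygotic genes (the three dependent classes and TFI) sit at
N(10, 0.7) in the stage-10.5 control and `induction_lfc` = 3 lower at
stage 7; a knockdown shifts only its matching dependent class by
`knockdown_lfc` = −3; α-amanitin multiplies every actively transcribed
class by `amanitin_residual` = 0.05; silent genes stay at log2 = 4. Probe
values add a per-probe affinity offset N(0, 0.5) shared across samples —
which is exactly why paired probe-level tests work — plus N(0,
`probe_sd` = 0.25) noise. Default class proportions are 40% maternal, 3 ×
10% single-factor dependent, 10% TFI, 20% silent. Eleven probes per
transcript is a typical probe-set size. Setting `probe_sd = 0` (and
`nb_dispersion = 0`) collapses all outputs to closed-form expectations;
classification is then exact by construction.

Counts: NB via gamma-Poisson with dispersion 0.1 at a depth-scaled mean
(default 5 × 10⁵ reads/sample); the triple knockdown applies the union of
the three single-knockdown effects, with TFI and maternal genes unchanged.
The slight TFI *increase* seen in real triple-knockdown data is
deliberately not modeled; the generator plants "no change".

ChIP: per TF, one true peak (400 bp) centred on each target's TSS with
10-fold read enrichment over a uniform 50,000-read background, plus 20
decoy peaks whose chip coverage is thinned to 0.5× the background so the
input-percentile filter removes them; the input track is uniform. The
bundled annotations keep ≥ 12 kb between genes so basal domains do not
overlap and planted edges are identifiable. Reads are 50 bp plain-text BED
intervals, not alignments.

What the generator does **not** emulate: cross-hybridization and
background structure of real probes, GC/length biases of sequencing,
replicate batch effects, peak-width and shape variation, partially
redundant factor dependence, and maternal+zygotic mixed transcripts
(e.g. a gene both maternally loaded and zygotically induced). Passing
recovery tests therefore demonstrates correctness of the inference chain
under its stated model, not robustness to all real-data pathologies.

## Problem sizes and determinism

Test and acceptance workloads use desk-scale sizes chosen to keep the full
suite fast while leaving the statistics well-determined: 1,000 genes for
classifier recovery, 2,000 genes for type-I calibration, 500 simulated
networks for the uniformity check, 60-gene annotations with six TFs for
network recovery. Every stochastic step flows from one integer seed
through `numpy.random.default_rng`; generators and the pipeline are
byte-deterministic for a fixed seed (the pipeline rerun test compares
files byte for byte).

## Known limitations

- Real vendor software assigns change calls with a proprietary algorithm;
  agreement with it is qualitative, not numeric.
- The count test's dispersion moderation is a two-parameter log-linear
  trend; strongly non-log-linear mean–dispersion relationships would be
  tracked only coarsely.
- The per-region peak-filter mode and the percentile mode can disagree
  near the threshold; only the percentile mode is exercised by the
  recovery tests.
- `group_shift_test` has a discreteness floor (minimum two-sided p of
  2/2ⁿ), so sets of fewer than about six genes cannot reach conventional
  significance.
- Real-input mode expects the simulator's plain-text formats; arbitrary
  vendor exports need conversion by the caller.
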