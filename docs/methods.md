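# Methods

## Kinetic model

Transcription of each gene is a single-file flow of polymerases:

* initiation at the TSS is a homogeneous Poisson process with rate
  I (polymerases/minute, default 2);
* a polymerase at gene-body offset x moves at v(x), a piecewise-constant
  profile in kb/minute (default: one piece, 2 kb/min);
* an acute perturbation multiplies v by a condition factor f (> 0) for all
  t ≥ onset_time — depletion is instantaneous, matching a degron that
  clears its target well within the hour before sampling;
* polymerases disappear at the TES. There is no promoter-proximal pausing,
  backtracking, termination dwell or RNA degradation in the default model.
  These omissions are deliberate: they keep the occupancy law exact, so
  any failure of the estimator indicts the analysis, not the generator.

Positions integrate exactly through the profile pieces and the onset
(piecewise-linear trajectories), vectorized over polymerases. Steady state
is reached by letting initiations start at −warmup with warmup defaulting
to 2 × (longest gene / slowest effective velocity).

Two consequences of the model are used as analytic oracles:

* **occupancy law** — at steady state the expected number of engaged
  polymerases per 50-bp bin is I · (50 bp / v): halving v doubles mNET-seq
  bin counts;
* **pulse law** — the expected labeled bases at any position equal
  I × pulse duration, independent of v: TT-seq output is velocity-
  invariant at steady state. The TT/mNET ratio therefore tracks v, and a
  global factor f appears as a per-gene log2 change of log2 f.

Under a *non-steady-state* slowdown (onset at t = 0, labeling at
[60, 65] min) synthesis recovers behind the new-density wave that moves
from the TSS at the new velocity, but remains reduced beyond it. Genes
short enough to sit behind the wave show a flat change profile; longer
genes tilt downward toward the 3′ end — the length-quartile contrast the
tilt statistic (mean of last body quartile − mean of first) quantifies.

## Assay read-out

* **TT-seq**: each polymerase labels the segment it traverses during the
  pulse (positions at window start → window end, clipped to the gene).
  Fragments are sampled with expected count = labeled kb × depth
  (default 2/kb) × library scale, Poisson noise, lengths uniform in
  150–300 bp truncated to the interval. Velocity input is fragment
  *midpoints*; gene-body expression counts use whole fragments.
* **mNET-seq**: each engaged polymerase at the sampling time emits
  Poisson(tags_per_pol × scale) width-1 tags at its active-site base
  (default 20/pol in the recovery experiments).
* **spike-ins**: six synthetic species (three labeled, three unlabeled,
  default 10,000 copies each); a labeled spike yields Poisson(copies ×
  scale) fragments, an unlabeled one a configurable leakage fraction
  (default 0). Copies are constant across samples — the normalization
  anchor.
* **ChIP-seq**: unstranded fragments from gene-body blocks with rate
  proportional to occupancy (I/v_eff) plus a uniform background over
  non-transcribed regions (the intergenic gaps minus a 2-kb buffer).

One master seed expands into per-sample/per-assay substreams in a fixed
order; a dataset is a pure function of (config, seed), and pipeline reruns
are byte-identical.

What the generator does **not** emulate: sequence content and alignment
error (coordinates are emitted directly), empirical fragment-size
distributions, PCR duplicates, pausing and termination zones, splicing and
RNA decay, copy-number or mappability structure. Passing recovery tests
therefore certify the *estimator's* arithmetic and normalization logic
under the stated kinetics, not robustness to every artifact of real
libraries.

## Analysis conventions

* Coordinates are 0-based half-open everywhere; conversion only at format
  boundaries. mNET-seq signal is the last incorporated base (+ fragment
  [s,e) → e−1; − fragment → s). Fragment midpoint is (s+e)//2
  (right-of-center for even lengths).
* Gene-level counting uses the IntersectionNotEmpty rule, strand-specific:
  a record counts for a gene iff the intersection of the non-empty
  per-base gene sets within the record has size one; otherwise it tallies
  as ambiguous (or unassigned when it overlaps nothing). Conservation
  (assigned + ambiguous + unassigned = input) is asserted in tests.
* Expressed genes: median TT-seq RPK across samples strictly > 10, and the
  gene overlaps no other gene on the same chromosome (either strand — the
  conservative reading of dropping ambiguous loci; same-strand-only
  exclusion would retain convergent overlaps that contaminate unstranded
  ChIP rows).
* Size factors: median-of-ratios against a row-wise geometric-mean
  reference, rows with any zero excluded; labeled spike-in rows for
  TT-seq/mNET-seq, non-transcribed-region rows for ChIP-seq. Factors are
  not rescaled to geometric mean 1 — only between-sample ratios matter,
  and normalized values are value/factor.
* Velocity: replicates of a condition are summed *after* normalization;
  the ratio is formed on summed bin/region counts (never per-base, which
  would hit 0/0); bins with zero mNET signal are NA (the gray bins of the
  heatmaps); per-gene ratios use [TSS + 1 kb, TES] and genes ≤ 1 kb are NA
  with a warning. The condition contrast is the per-bin/per-gene log2
  ratio of velocity ratios, NA-propagating.
* Profiles: pseudo-count 1 before log2; scaled metagenes use 100 equal
  body spans with 50 flank bins over 2.5 kb each side (flanks beyond the
  chromosome contribute zero); heatmaps use fixed genome-anchored grids
  (50 bp TSS-aligned; 500 bp gene-center-aligned with bins not fully
  inside the body masked NA). Length quartiles are near-equal rank groups,
  remainders to earlier groups, ties broken by gene id.
* Bootstrap: percentile method, resampling gene rows with replacement
  (implemented as multinomial weights — the identical distribution — so
  10,000 iterations run as matrix products); the reported mean is the
  observed column mean. Degenerate inputs (one gene, identical rows) give
  zero-width intervals by construction.
* Wilcoxon tests follow R's wilcox.test conventions: zeros dropped, exact
  permutation distribution for n ≤ 25 (signed-rank) / n1+n2 ≤ 30
  (rank-sum) computed by dynamic programming over doubled midranks (ties
  exact), otherwise a tie- and continuity-corrected normal approximation.
  Benjamini–Hochberg adjustment delegates to statsmodels. Boxplot hinges
  are type-7 quantiles; notches median ± 1.58·IQR/√n; whiskers the extreme
  values within 1.5·IQR of the hinges.

## Recovery experiment designs

Problem sizes were chosen so each experiment's Monte-Carlo error is a few
times smaller than the effect it measures while a full validation run
stays around a minute:

* **velocity contrast** — 200 genes, lengths log-uniform 10–100 kb,
  I = 2/min, control v = 2 kb/min vs 1 kb/min, both at steady state,
  2 replicates with library scales (1.0, 1.2, 0.9, 1.1), spike-in
  normalization; expected median log2 change −1.
* **tilt** — same gene set, slowdown onset t = 0, labeling [60, 65] min,
  TT-seq depth 8/kb; tilt compared between shortest and longest length
  quartiles.
* **spike-ins** — scales (0.5, 1, 2), ≈10k labeled-spike reads per unit
  scale; factor error measured up to overall scale.
* **occupancy/pulse laws** — 200 genes, I = 4/min, one replicate per
  velocity at equal scale.
* **bootstrap calibration** — 1000 datasets of 100 i.i.d. Normal(3, 1)
  gene rows, 10,000 iterations each; nominal 95% coverage. Percentile
  intervals at this n run slightly conservative-low (≈94%), a known
  property of the method.
* **ChIP background** — 20 genes, background 100 reads/kb, scales (1, 3).

## Known limitations and numerical notes

* The per-gene velocity ratio is a ratio of Poisson sums; Jensen's
  inequality biases each ratio slightly high, and the *change* (treated
  minus control) slightly negative when the treated denominator grows —
  the recovered median log2 change runs ≈2–4% below −1 at the default
  depths. The bias shrinks as 1/counts and is far inside the ±0.1
  validation band; absolute velocities are anyway reported only up to a
  global constant.
* Fragment midpoints are depleted within half a fragment length of
  interval ends and correspondingly enriched just inside; near the TES
  the affected span scales with the polymerase travel distance during the
  pulse (v × 5 min), so it differs between conditions and imprints a small
  (|tilt| ≈ 0.05–0.1) 3′ dip on genes whose length is comparable to that
  distance. Real TT-seq midpoint data shares this geometry; it does not
  affect the quartile contrast, which compares an order-of-magnitude
  larger signal.
* The onset of the velocity change after chemical depletion is not
  observable from endpoint data; it is a config parameter (default 0,
  i.e. depletion complete at treatment start) for sensitivity analysis.
* Gene-body counts default to whole TT-seq fragments (midpoints are used
  for velocity only); both are exposed.
* Per-gene differential-expression *significance* is out of scope: the MA
  table reports normalized means and log2 fold-changes, and rank tests
  operate on summary distributions, without a negative-binomial model.
* The simulator emits coordinates, not sequences: no FASTQ, no aligner in
  the loop; real data enter as BED6 after the user's own alignment.
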