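# Methods

## The problem

Array-based methylome scans measure fractional methylation (beta values in
[0, 1]) at hundreds of thousands of CpG sites in cohorts of tens to hundreds
of samples.  Testing every probe against a phenotype carries a massive
multiple-testing burden, and single-probe hits are vulnerable to
cross-reactive or polymorphic probes.  Methylation of neighbouring CpGs is
correlated over short genomic distances, so `regionscan` tests *regions* —
runs of nearby probes that move together — instead of individual probes.
Because the probes on these arrays are spaced sparsely and irregularly
(adjacent gaps range from a few bp to tens of Mb), regions are defined
purely by inter-probe distance, not by fixed or sliding windows.

## Region definition

Probes are sorted by (chromosome, position) and partitioned into maximal
runs in which every adjacent anchor-to-anchor gap is at most `L`
(default 1,000 bp; "within L" is read inclusively, so a gap of exactly L
joins).  Runs of a single probe are discarded; chromosome boundaries always
break runs.  Regions whose member probes are more than 20% flagged as
cross-hybridizing are removed before any testing.  Internally all interval
arithmetic is 0-based half-open (a 1-based anchor `p` occupies `[p-1, p)`),
which makes the BED output exact.

## DMR scan (differential methylation with age)

Each probe `j` gets a statistic from the per-probe ordinary least squares
fit

    Y_ij = gamma_j + beta_j * X_i + e_ij

of methylation on age `X_i` (covariates optional; omitted by default).
Either the slope `beta_j` or its t-statistic can be used.  Let `q1` be the
95th percentile of the *positive* statistics and `q2` the 5th percentile of
the *negative* statistics (linear interpolation between order statistics;
ties at the cut do not pass).  A candidate DMR is a maximal run of >= 2
consecutive probes inside one distance cluster, all with statistic > q1
(hypermethylated with age) or all < q2 (hypomethylated).  Its score is the
trapezoidal area of |statistic| against genomic position in bp.

Significance: ages are permuted across samples `K` times (default 100);
after each permutation the statistics, the percentile cut-offs and the
candidate detection are all recomputed, and every null candidate's area
enters a pooled null distribution.  The empirical p-value of an observed
region is the fraction of pooled null areas at least as large (ties count;
p may be exactly 0 — a `laplace` option gives (1+c)/(1+N) for users who
need strictly positive p).  Benjamini–Hochberg step-up q-values are
computed over all candidates and regions with q below `fdr_cut` (default
0.05) are reported, together with the fraction hypomethylated with age.

When several data sets are analysed together the least-extreme cut on each
side (smallest q1, largest q2) can be applied to all of them
(`harmonize_thresholds`).

## VMR scan (inter-individual variability)

Within one group of samples each probe gets the unscaled median absolute
deviation (MAD) of its methylation values.  Candidates are runs of >= 2
consecutive in-cluster probes whose MADs all exceed the 95th percentile of
all MADs (or the lowest such cut across groups), scored by the same
trapezoidal area.

Significance comes from a parametric bootstrap.  Log-transformed MAD
(natural log, values floored at 1e-6) along a region is modelled as a
stationary first-order autoregressive process

    k_i = rho * k_{i-1} + e_i,   e_i ~ N(0, sigma^2).

The parameters are estimated by order-1 Burg fits (forward-backward
prediction error; |rho| < 1 by construction) on every region with at least
`min_probes_ar` probes (default 50) and averaged arithmetically — rho with
rho, standard deviation with standard deviation.  The stationary mean of
the log-MAD landscape is estimated once across all qualifying regions and
removed before the per-region fits; demeaning each short region by its own
mean would bias rho downward by roughly (1 + 3 rho)/n, which is material at
region lengths of 50–100.  Each bootstrap replicate generates a stationary
AR(1) log-MAD series around that mean over the *real* probe layout
(independently across clusters), exponentiates, applies the replicate's own
95th-percentile cut, reruns the candidate detection, draws `x` candidates
(the observed VMR count; all if fewer) and pools their areas.  Empirical p
and BH q then follow exactly as in the DMR scan.

Simulating around the observed mean log-MAD level matters: the area
statistic is on the scale of the data, so a null generated at the wrong
level is not comparable to the observed areas.

## Supporting analyses

* **Correlation profile.**  All probe pairs within 100 kb are enumerated,
  sorted by distance, and split into bins of near-equal pair counts
  (default 50 bins; sizes differ by at most one).  Per bin the Pearson
  correlation of the two members' values in a single sample is reported
  against the bin's median distance.  An optional tiling mode restricts
  pairs to fixed 100-kb tiles for comparison with tiled analyses; the
  default all-pairs mode does not miss boundary-straddling pairs.
* **Enrichment.**  One-tailed upper hypergeometric tests throughout.  Gene
  sets are tested probe-weighted: the background population is the probes
  contained in the background region list, successes are probes annotated
  to set genes, draws are query-region probes.  CpG-island context uses six
  categories (island, north/south shore, north/south shelf, open sea) with
  BH correction across the categories reported together.  Open-chromatin
  hot-spot overlap is tested at the region level with half-open interval
  semantics (>= 1 bp overlap).  For the joint overlap of three or more
  region lists an empirical p is computed by drawing size-matched lists
  from the background (default 1e5 repetitions); the default direction is
  enrichment (null overlap >= observed), with the depletion-style reading
  behind a flag.
* **SNP filter.**  A probe is SNP free if no variant with MAF strictly
  above 5% lies in the half-open window [anchor-100, anchor+150): a 50-bp
  probe body downstream of the anchor plus 100-bp flanks, strand ignored.
  A region is SNP free iff all member probes are.
* **Power.**  The single-probe vs region testing burden is compared for a
  two-group Wilcoxon–Mann–Whitney test via the normal approximation with an
  asymptotic-relative-efficiency correction (3/pi under a normal parent,
  0.864 as the distribution-free floor) and Bonferroni-adjusted per-test
  levels.

## Synthetic data

The generator provides the test bed for all of the above without any
external downloads.  It emulates:

* **Spacing** — inter-probe gaps are a mixture of a short exponential
  component (mean 200 bp, clipped to [2, L] so short gaps never break a
  cluster) and a Pareto-tailed long component (> L, capped at 20 Mb),
  with the short fraction defaulting to 0.8.  This reproduces the
  long-tailed, irregular layout that makes distance clustering non-trivial.
* **Cis-correlation** — each cluster has a common baseline level
  (U(0.1, 0.9)) with probe-level jitter (sd 0.03), and sampling noise is
  compound-symmetric within clusters (default 45% shared variance, total
  sd 0.03), so neighbouring probes correlate within a single sample and
  across samples while distant probes do not.  Compound symmetry was chosen
  over a distance kernel: it is sufficient to exercise clustering and
  detection, and simpler to reason about.
* **Planted DMRs** — chosen clusters add slope x age to every member probe
  (default 0.002 per year, alternating sign across planted regions),
  with baselines placed mid-range so the signal survives clipping to [0,1].
* **Planted VMRs** — each group receives a per-probe log sampling-sd field:
  log(0.04) plus a stationary AR(1) series within clusters (rho 0.5,
  innovation sd 0.3); planted regions add a log-MAD shift (default +1.5)
  in the designated group only.

Default study sizes used by the tests and the acceptance script: 5,000
probes on 4 chromosomes, 60 samples with ages evenly spaced over 1–80
years for the DMR study, and two groups of 20 samples for the VMR study —
sizes representative of published age-methylation cohorts while keeping a
full permutation analysis fast on one CPU.

What the generator does **not** emulate: array chemistry (probe-type and
dye biases), normalisation artefacts, cell-composition heterogeneity,
genotype-driven methylation (meQTLs), and missing-value patterns beyond
simple at-random holes.  Passing tests therefore demonstrate the
statistical machinery — detection geometry, null calibration, recovery
under the assumed model — not robustness to real-array preprocessing.

## Numerical choices and edge cases

* Percentiles use linear interpolation between order statistics.
* The empirical p-value implements the pooled-count formula literally (no
  +1 smoothing) so p = 0 is possible for areas beyond every null area.
* Burg's reflection coefficient is clamped to |rho| <= 1 - 1e-10; an
  exactly alternating series fits at the clamp.
* MAD values of 0 (invariant probes) are floored at 1e-6 before the log.
* Probes with more than 20% missing samples get undefined statistics:
  excluded from percentile computation and unable to join candidate runs;
  other probes use their available samples.
* Matrix columns are kept in canonical sorted sample order and rows in
  manifest order, so results are invariant to input column and row order.
* A single global seed is expanded into named per-stage substreams
  (permutation, bootstrap, simulation), making each stage independently
  reproducible.
* Chromosome names are normalised ("chr1" == "1").

## Design decisions that were genuinely open

* **q-values** are BH step-up rather than a null-distribution-based FDR
  estimate: with a pooled permutation null of modest size the latter is
  under-determined, and BH is deterministic and conservative.
* **Thresholds inside permutations** are recomputed per permutation by
  default (the full identification procedure is what is rerun); a config
  switch freezes the observed cuts instead.
* **The bootstrap's "select x regions"** samples from the candidates
  detected in each simulated landscape, so null areas reflect both the
  clustering geometry and the AR(1) correlation.
* **Pair enumeration** for the correlation profile takes all pairs within
  the window rather than fixed tiles (tiling available behind a flag).
* **Probe anchor** is the single annotated coordinate; strand is ignored
  everywhere.

## Known limitations

* The permutation null assumes exchangeable samples; confounders that
  correlate with age (batch, cell composition) are only addressed through
  the optional covariate adjustment of the per-probe fit.
* The AR(1) model treats log-MAD correlation as homogeneous across the
  genome; the pooled average hides region-to-region heterogeneity.
* Empirical p-values are bounded below by 1/(pooled null size); very small
  p-values require large K.
* The power comparison is an asymptotic approximation, accurate to within
  about two percentage points of Monte-Carlo WMW power at moderate n.
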