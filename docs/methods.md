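# Methods

This note documents the statistical models implemented in `citniche`,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions taken
where the underlying procedures left room for choice.

## Study design the package models

Twelve initially clonal Cit⁺ *E. coli* populations evolve in citrate-only
minimal medium (DM0) and twelve control populations in glucose+citrate
medium (DM25), under daily 100-fold serial transfer. The analyses
quantify (i) growth-kinetic change from OD₄₂₀ plate-reader curves,
(ii) competitive fitness from marker-based colony counts,
(iii) gene-level parallelism of the mutations accumulated in sequenced
clones, (iv) selection on parallel IS-element insertions,
(v) copy-number amplifications from sequencing coverage, and
(vi) stationary-phase mortality from stained-cell microscopy.

## Growth curves: the log-slope method

A diauxic curve in DM25 grows first on glucose, then on citrate. Rather
than fit a parametric growth model, rates are defined operationally as
OLS slopes of ln OD₄₂₀ against time within fixed OD windows where each
resource dominates:

- `r_glucose`: window OD ∈ [0.01, 0.02] (DM25 only),
- `r_citrate`: window OD ∈ [0.05, 0.10],
- lag `τ`: first time OD ≥ 0.01, linearly interpolated between the
  bracketing 10-minute observations (interpolation removes the
  sampling-interval quantization),
- observations before `t_min` = 0.5 h are discarded (early readings are
  unreliable on plate readers).

Point selection takes the *first maximal contiguous run* of in-window
points: late in the experiment stationary-phase noise can dip back into
a window, and those points carry no exponential-phase information. A
rate is reported only when the run has ≥ 2 points; inestimable
parameters propagate as undefined rather than failing a whole fit. No
blank subtraction is applied by default (`GrowthConfig.blank` provides
a constant-blank hook).

Replicate wells (6 per sample) are the unit of replication: the point
estimate is the mean of per-well estimates and the confidence interval
is a BCa bootstrap resampling wells. Per-well estimation (rather than a
pooled regression) keeps the bootstrap unit and the estimate aligned.

## Competition fitness

Each competitor's realized growth over a d-day assay with D-fold serial
transfers is its Malthusian parameter m = ln(N_f · D^(d−1) / N₀), where
N₀ and N_f are CFU/mL densities from dilution plating (colonies ×
dilution / volume). Relative fitness is W = m_test / m_ref. Replicates
are summarized by the mean and the t-distributed 95% interval. When two
dilutions of one culture are both countable, per-plate densities are
averaged weighted by colony count, so the better-counted plate
dominates; zero-colony plates are unusable (they cannot anchor a log)
and are excluded. W is invariant to density units and, for one-day
assays, m reduces to ln(N_f/N₀).

## Genomic parallelism

A mutation *qualifies* when its type is nonsynonymous SNP, deletion,
duplication/amplification or IS insertion, and it unambiguously affects
exactly one gene — a coding hit, or a promoter hit within 150 bp
upstream (the window is configurable; published analyses count promoter
hits without stating a window, and 150 bp covers bacterial core
promoters). Multi-gene deletions and intergenic events with several
candidate genes are excluded as ambiguous.

Each clone is reduced to its set of genes with ≥ 1 qualifying mutation.
Pairwise similarity is Dice's coefficient S = 2|X∩Y|/(|X|+|Y|); S_m,
S_w and S_b are its means over all, same-treatment and cross-treatment
clone pairs. Treatment specificity is tested by permuting treatment
labels across clones (group sizes preserved) and recomputing S_w − S_b;
the p-value uses the add-one convention (1 + #{permuted ≥ observed}) /
(1 + n_perm), which is never zero and matches reporting "p < 1/n_perm"
when no permutation reaches the observed value. Because the pairwise
Dice matrix depends only on the gene sets, it is computed once and
re-averaged under each of the 10,000 default permutations. A pair of
two empty gene sets has undefined similarity; it is defined as 0,
logged, and excluded from the means (synthetic low-rate tables can
produce it; real sequenced clones do not). Per-gene specificity uses
the two-tailed Fisher exact test on clones-hit × treatment; gene
rankings sort by |total_DM0 − total_DM25| among genes hit in ≥ 2
genomes, ties broken by total count then name.

The two-tailed Fisher convention is the method of small p-values
(summing all hypergeometric outcomes no more probable than the
observed table, scipy's two-sided test) rather than tail doubling;
this convention reproduces all six published specificity p-values to
their printed precision.

## IS-insertion site-preference test

Under the null that parallel insertions reflect only insertion-site
bias, an IS element can insert only at sites where insertions were
observed across a catalog of sequenced genomes, with probability
proportional to the observed count at each site. Holding a genome
group's total insertion count n fixed, each of 100,000 replicates draws
n sites multinomially; the p-value is the fraction of replicates in
which the focal site receives at least the observed number of hits.
The focal-site statistic is the default (the question is about one
specific site); a family-wise `max` statistic — the maximum count over
all sites — is available, and is never less conservative. Because the
focal count's marginal is Binomial(n, w_focal/Σw), the focal mode
samples that binomial directly; the two-site catalog therefore has an
exact oracle (e.g. weights (9,1), n = 10, observed 9 →
p = P(Bin(10, 0.9) ≥ 9) = 0.7361). Catalog construction is explicit
input; sites within one target-site duplication span should be merged
(`merge_tsd_sites`) before testing.

## Copy-number variation

Single-copy depth is modelled as NB(μ, size). The null is fitted by
truncated maximum likelihood to the depths between the 5% and 95%
coverage quantiles — the tails that amplifications and deletions
distort are excluded and the likelihood is renormalized to the retained
band, so μ and size estimate the untruncated law (a plain fit to
trimmed data would understate the variance by ~45% at size = 10).
Zero-overdispersion data degenerates to the Poisson limit, flagged.

Detection must respect that one read covers many adjacent positions: a
region of length L contains only k = ⌊L/read_length⌋ positions spaced a
full read apart (1000 bp at 150-base reads → k = 6). The package
aggregates depth into non-overlapping read-length windows — the
independent units of coverage evidence — flags windows rejecting the
window-level null (an NB with mean and size scaled by window length) at
uncorrected p < 0.05, merges contiguous flagged runs, and computes the
region p-value as the tail probability of the run's most conservative
window raised to the k-th power, times the Bonferroni factor
(genome length + initially flagged positions), capped at 1. Runs no
longer than 2 × read_length are discarded as potential false positives,
and regions are reported below corrected p < 10⁻⁴. Per-position
p-values and a literal per-position detection mode
(`granularity="position"`, with a PMF option for the extreme-depth
probability) are retained for coverage that is already smooth at read
scale; on positionwise-independent depth the per-position route has
essentially no power at low copy number, because a single unflagged
position breaks a run and the regionwide minimum of thousands of
independent draws falls inside the null bulk.

Copy numbers are ratios of interval mean/min/max depth to the
single-copy mean (the fitted μ) when a null is available. On real-sized
genomes this equals the genome-wide mean depth to within a fraction of
a percent; on short synthetic tracks it avoids the upward bias a large
amplification imposes on the global mean. `copy_number` without a
fitted null uses the genome-wide mean (exact identity: the whole genome
has copy 1.0).

## Cell viability

Segmented regions with classifier scores in [25, 50] — P(Cell) > 75% —
count as cells; a cell is dead iff red (dead-stain) fluorescence
strictly exceeds green (tie → alive, since "exceeds" is strict). The
overall mortality of a strain pools cells across replicate cultures,
Σ dead / Σ cells, identically the cell-count-weighted mean of replicate
proportions. The BCa interval resamples replicate cultures, recomputing
the weighted proportion per resample (weights travel with their
replicates); per-cell resampling is available but non-default, since
the replicate culture is the biological unit. A single replicate yields
a point estimate with no interval.

## BCa bootstrap

The interval machinery is shared: resample replicate indices uniformly,
recompute the (optionally weighted) statistic, apply bias correction z₀
(normal quantile of the fraction of bootstrap statistics below the
point estimate, clipped away from 0 and 1) and jackknife acceleration
a = Σd³ / 6(Σd²)^{3/2}. With z₀ = 0 and a = 0 the endpoints reduce
exactly to percentile endpoints; fully degenerate data returns the
degenerate interval. One top-level integer seed feeds every stochastic
routine through deterministically derived, mutually independent streams
(`stats.rng_for`), so all results are reproducible per seed.

A practical caveat: bootstrap intervals over 5–6 replicates undercover.
On exact normal data the 95% BCa interval over n = 6 values covers
~84%, and ~92% at n = 30 (scipy's independent BCa implementation
reproduces both numbers). This is a property of the method at the
study's replication level, not of the implementation; simulation
coverage results in `analysis/02` and `analysis/07` should be read
against that baseline.

## Synthetic data: what it emulates and what it does not

Every generator is deterministic per seed, writes the same formats the
readers consume, and emits a TOML truth sidecar sufficient to score any
estimator without re-deriving.

- `gen_od_curves`: piecewise-exponential diauxic trajectories (baseline
  0.005 OD → glucose phase crossing OD 0.01 exactly at the planted lag
  → shift at OD 0.03 → citrate phase → plateau 0.5), multiplicative
  lognormal noise (default log-sd 0.02; plate readers show proportional
  error). Defaults r_glucose = 0.8 h⁻¹, r_citrate = 0.3 h⁻¹, lag 2 h,
  6 wells, 10-min sampling over 48 h match the assay design. Not
  emulated: well position effects, evaporation drift, non-exponential
  transitions.
- `gen_competition_counts`: Malthusian densities with
  m_test = W·m_ref, Poisson colony counts at the plated expectation;
  the default reference just balances the daily 100-fold dilution.
  Not emulated: marker costs, frequency dependence, plate-count
  miscounting beyond Poisson.
- `gen_mutation_table`: independent Bernoulli clone × gene hits
  (presence/absence is what Dice and Fisher consume), qualifying types
  mixed 40/40/20 (nonsyn SNP / IS insertion / deletion), plus decoy
  non-qualifying records so the filter is exercised. Not emulated:
  linkage within clones, mutation-rate heterogeneity along the genome.
- `gen_insertion_sites`: multinomial draws from catalog weights with an
  optional single-site hotspot factor (factor 1 is exactly the null).
- `gen_coverage`: positionwise-independent NB(μ·copy, size) depth with
  planted copy-number segments. Read-level autocorrelation is *not*
  simulated; this makes the k-exponent construction conservative on
  synthetic data and motivates the read-length-window detection
  granularity above.
- `gen_cells`: well-separated live/dead channel distributions, real
  cells scored uniform [25, 50], a planted fraction of sub-threshold
  non-cell regions. Not emulated: segmentation errors among
  high-score regions, channel bleed-through, photobleaching.

Passing round-trip tests on these generators shows the estimators are
correct under the stated noise models at the study's replication
levels; it does not certify behaviour under structured artifacts real
instruments add (autocorrelated coverage, drifting baselines,
segmentation mistakes).

## Problem sizes used in validation

Recovery and calibration studies use 100–500 simulated datasets per
setting, 1,000 bootstrap resamples inside simulations (10,000 for
single reported intervals), 199–999 permutations inside power studies
(10,000 for single reported tests), 100,000 replicates for the
insertion-test oracle, and 100 kb synthetic genomes at 50× mean
coverage with 3 kb planted amplifications. These sizes give Monte-Carlo
standard errors comfortably below the margins being tested while
keeping the full validation suite fast.

## Known limitations

- Small-replicate BCa undercoverage (above) affects any interval built
  on 5–6 biological replicates.
- The qualifying-mutation filter trusts upstream gene annotation;
  duplications spanning many genes are excluded as ambiguous rather
  than credited to boundary genes (a strict single-gene reading; a
  permissive mode could credit boundary genes but is not implemented).
- The coverage model has no GC-bias or mappability correction and no
  positional smoothing; deletions are tested only by the symmetric
  lower tail.
- The insertion-site null depends entirely on the supplied catalog;
  with sparse catalogs the test is conservative by construction.
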