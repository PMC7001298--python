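# Methods

## The model

Two mitochondrial haplotypes, HI and HII, segregate in a population at
frequencies `p_I` and `p_II = 1 - p_I`. mtDNA is haploid and maternally
inherited, so the pair behaves as a one-locus, two-allele haploid system.
Selection is modeled as *negative frequency dependence* with a symmetric
equilibrium at 0.5: haplotype fitness declines linearly with own frequency,

    W_I  = 1 - p_I  * s_I
    W_II = 1 - p_II * s_I,

and the deterministic per-generation change is the standard haploid
replicator step

    dp_I = p_I * p_II * (W_I - W_II) / W_bar,
    W_bar = p_I * W_I + p_II * W_II = 1 - s_I * (p_I^2 + p_II^2).

For `s_I > 0` the dynamics pull `p_I` monotonically toward 0.5 from either
side; `s_I = 0` is neutral; `s_I < 0` pushes toward fixation. The model is
only defined while `W_bar > 0`, i.e. `s_I < 1/(p_I^2 + p_II^2)` (between 1
and 2 depending on frequency); inadmissible values raise rather than
silently clamp.

The estimator inverts one forward step in closed form:

    s_I = (-dp p_I - dp p_II) / (-dp p_II^2 - p_I p_II^2 + p_I^2 p_II - dp p_I^2)
        =  dp / [ dp (p_I^2 + p_II^2) + p_I p_II (p_II - p_I) ],

so `estimate_s(p, forward_delta_p(p, s)) == s` exactly (tested to 1e-10).
The sign convention follows from the algebra: `s_I > 0` whenever the
observed change points toward the 0.5 attractor. Degenerate inputs are
flagged, never returned as numbers: fixation (`p_I` in {0, 1}) and a
vanishing denominator — notably `p_I = 0.5` with `dp = 0`, a 0/0 where any
selection strength is consistent with no change.

### Multi-generation intervals

Experiments observe frequencies at generations 0, 5 and 10, not every
generation. Each interval contributes a per-generation change
`Δf = (f_end - f_start) / Δt` and one selection estimate
`estimate_s(f_start, Δf)`, using the frequency at the **start** of the
interval. The start frequency is the only frequency actually observed when
the interval opens; the alternative (midpoint or mean) is not observable
without interpolation. Because `p` drifts over five generations while the
estimator treats the change as one averaged step, this introduces a
discretization bias — the estimator applied to an exact 5-generation
deterministic trajectory with `s = 0.2` returns ≈ 0.18, not 0.20. The bias
is quantified, not corrected: the parameter-recovery test compares the
stochastic pipeline against the same deterministic-recursion oracle, so
recovery is judged against the attainable expectation rather than the
nominal truth. The estimator is exact when the true equilibrium is at 0.5
and only approximate otherwise; no correction for a displaced equilibrium is
attempted.

## The synthetic experiment

`ExperimentDesign` generates complete experiments with the statistical
structure the analysis assumes. Defaults reproduce the 12-line study
layout and are held fixed:

| parameter | default | meaning |
|---|---|---|
| start_freqs | 0.2, 0.8 | HI founded rare or common |
| environments | homogeneous, heterogeneous | resource treatment (a label by default) |
| replicates_per_cell | 3 | 12 lines total in the 2x2 design |
| n_generations | 10 | discrete, non-overlapping |
| sample_generations | 5, 10 | pool-seq time points (generation 0 is known by construction) |
| census | 773 | constant effective size per generation (mean adult count of the emulated study) |
| pool_size | 105 | flies pooled per cage per sample |
| read_depth_per_snp | 2000 | per-SNP coverage; typical for mtDNA pool-seq, where mitochondrial copy number gives deep coverage |
| snp_ids | nad5, rrnS | two diagnostic SNPs distinguishing HI/HII |
| true_s | 0.2 | representative of selection strengths the design is meant to detect |

Each generation is one unstructured haploid Wright–Fisher step: binomial
resampling of the whole census around the selection-shifted expectation.
Real transmission runs through females only, so the census here is an
*effective* size, not the adult count; no demographic detail beyond that is
modeled. `ramp_trajectory()` provides an optional founder-to-adult growth
series (100 → 773 over five generations) for sensitivity checks; the default
stays constant for simplicity. Pool sampling is hypergeometric from a cage
whose HI count is `round(census * p)`; read counts are per-SNP binomial
draws given the pool fraction. `true_s` may vary by design cell (mapping
keyed by environment or `(start_freq, environment)`), giving the
frequency-by-environment interaction a non-null regime to exercise.

One global seed spawns an independent substream per line, keyed by the
line's design cell and replicate number — enlarging the design never
changes existing lines' trajectories, and all outputs are bit-reproducible.

What the generator does *not* emulate: sequencing error, reads mapping to
neither haplotype, nuclear variation and mitonuclear epistasis, viability
selection within a generation, overlapping generations, or any mechanistic
difference between the two environments. Passing tests therefore show the
*inferential machinery* is correct and calibrated under the model's own
assumptions; they do not validate those assumptions against real cages.

## Frequency estimation

The per-sample HI frequency is the unweighted mean of the two SNPs' read
proportions. Unweighted (rather than depth-weighted) averaging is the
default because the two SNPs are duplicate measurements of the same pool
fraction, not independent samples; depth weighting is available behind a
flag. Inputs are strictly biallelic counts — upstream mapping and filtering
are out of scope. A single usable SNP is accepted with a warning; zero
usable records is an error. `snp_concordance` reports the Pearson
correlation of the two SNPs' proportions across samples as a diagnostic
(expected near 1 at realistic depth) and flags it undefined when either
SNP is constant across samples.

## Inference

Each line is the experimental unit. The two interval responses (Δf or S_I)
per line form a repeated-measures design with two between-line factors.
`rm_anova` computes the classical split-plot decomposition from balanced
sums of squares: between-line terms (SF, E, SF×E) tested against the
line-within-cell residual (df 8 with 12 lines), within-line terms (G and
interactions) against the G×line residual (df 8). Drift among replicate
lines lands in these residuals, which is what keeps the F-tests honest for
a drift-dominated system. Equivalence with a general-linear-model route
(two-way OLS on line means for the between stratum, on interval differences
for the within stratum) is enforced to 1e-8 in tests. Zero residual
variance yields flagged (NaN) F values, detected with a floating-point
noise threshold scaled to the response magnitude.

Permutation tests shuffle the `(SF, E)` label pairs jointly across lines,
keeping each line's repeated measures intact, and recompute the term's F
(upper tail; F is inherently one-tailed). The p-value uses the add-one
convention `(b + 1)/(B + 1)`, default `B = 9999`. Synchronized label
permutation preserves the within-line correlation structure and makes all
three between terms exchangeable under their joint null. When the observed
F is undefined (constant response) the maximal p of 1.0 is returned.

Bootstrap intervals are percentile intervals over lines resampled with
replacement (default 9999 replicates); the point estimate is the plain
sample mean. Percentile (not BCa) is used for transparency; its known cost
is undercoverage at small n — at 12 lines the exact Gaussian coverage of a
nominal 95% interval is ≈ 91%, approaching nominal by n ≈ 50, where the
calibration test operates. The per-line scalar entering the global
one-sample t-test (df = n − 1) and the group means is the arithmetic mean
of the line's two interval estimates — the simplest reduction consistent
with one value per line.

All tests are two-sided. No multiple-testing adjustment is applied across
ANOVA terms. Sphericity is not an issue with only two repeated levels.

## Numerical choices

- Frequencies are clamped to [0, 1] after floating arithmetic, with error
  beyond a 1e-12 tolerance.
- Estimator undefinedness is an exact zero-denominator test; near-zero
  denominators legitimately produce large `s_I` values and are left to the
  admissibility check.
- All randomness flows through `numpy.random.Generator` seeded via
  `SeedSequence`; independent consumers (lines, permutation, bootstrap,
  group cells) get spawned substreams, so results are reproducible and
  order-insensitive.

## Problem sizes in the test suite

Calibration tests use sizes chosen for tight Monte-Carlo error at modest
cost: 500 null experiments with 999 permutations each for type-I error,
1000 repeats of a 50-line Gaussian sample with 1999 bootstrap replicates for
coverage, 2000 replicate lines for the neutral-martingale check, and an
exhaustive 2520-assignment enumeration on an 8-line design as the
permutation oracle. The full suite runs in well under five minutes.

## Known limitations

- The estimator assumes the equilibrium sits exactly at 0.5; a displaced
  equilibrium biases `s_I` and is not estimated.
- Interval estimates use start-of-interval frequency; the resulting
  discretization bias (~10% at `s = 0.2` over 5-generation intervals) is
  quantified by the deterministic oracle but not corrected.
- Percentile bootstrap intervals undercover at the 12-line scale (≈ 91%
  actual for 95% nominal).
- The census is a single effective size; real cage demography (growth,
  sex structure, maternal transmission) is compressed into it.
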