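# Methods

This note records the models behind each estimator, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Flow-cytometry model

Nuclei stained with a DNA-intercalating dye fluoresce in proportion to
DNA content; fluorescence is treated as strictly linear (a single gain
constant). Nonlinearity and offset error of real instruments are out of
scope. A run contains four populations: sample 2C (G1 diploid nuclei),
standard 2C, their 4C doublings (G2 or endoreduplicated nuclei, at
exactly twice the 2C position), and debris.

The estimate is the peak-position ratio

    sample 1C = standard 1C × x_sample / x_standard ,

with `x` the Gaussian-fitted mean of a 2C peak. The ratio cancels the
gain, so the estimate is invariant to rescaling the fluorescence axis
and strictly monotone in the sample peak position.

### Peak detection and fitting

* Events are binned into 1024 equal-width channels over [0, max]
  (mimicking cytometer channel resolution) and smoothed with a 5-channel
  moving average, normalised by the in-range window size so the
  histogram edges are not biased low.
* Candidate peaks are local maxima of the smoothed counts whose
  prominence exceeds `max(0.05 × tallest bin, 4 × sqrt(height))`. The
  square-root term reflects Poisson counting noise: a noise wiggle's
  prominence scales like the square root of the local height, a real
  peak's like its full height. This keeps broad (high-CV) peaks whole
  and rejects wiggles riding on the debris tail.
* Each peak's fit window is symmetric: ±3σ₀ around the mode, with σ₀
  from the half-height width (FWHM/2.355), clipped at midpoints toward
  neighbouring peaks. A Gaussian is fitted to the raw counts by least
  squares; windows with ≤ 2 occupied channels fall back to moment
  estimates (so a delta peak returns its channel center with CV 0).
* Peaks whose event count falls below 0.5% of all events are dropped.

### Sample/standard resolution

The caller declares an expected sample range in pg; no automatic
guessing. Every ordered (standard, sample) peak pair is scored: the
implied 1C must fall in the range and every remaining peak must be the
4C doubling (within 3 combined SD) of one of the two. Exactly one
surviving assignment is required — several raise an ambiguity error
advising a different internal standard, matching the practice of
switching standards when sample and standard peaks coincide.

### QC and aggregation

A peak passes QC iff CV = 100·sd/position is strictly below 5%.
Replicate means aggregate to mean 1C (2 decimals), genome size in Mb
(unrounded pg mean × 978, then rounded — the packaged study tables are
only consistent with unrounded-pg conversion), and SE = sd/√n of the
replicate means, reported in Mb and omitted for n = 1.

## K-mer spectrum model

For a diploid genome of length G sequenced to total depth c with reads
of length L, a k-mer is expected at depth λ_k = c(L−k+1)/L if present
on both haplotypes, λ_k/2 if haplotype-specific, and m·λ_k if in an
m-copy repeat; sequencing errors create novel k-mers at depth 1–2.
k = 21 (odd, avoiding palindromes) is the default; k ≤ 31 packs into a
64-bit code.

* **Error cutoff**: the first valley (smallest d ≥ 2 with
  N_{d−1} > N_d ≤ N_{d+1}), accepted only when (i) the spectrum
  descends from depth 1 (an error slope exists) and (ii) some later
  depth rises above the valley (a genomic peak exists). Otherwise c = 1
  — without the initial-descent guard, an error-free spectrum would
  return the single-copy/repeat valley and the size estimator would
  lock onto the repeat peak.
* **Peak depth**: the modal depth at or above the cutoff (ties to the
  smaller depth), refined by a least-squares parabola on log counts
  over ±3 depths. A strict 3-point interpolation is noise-fragile (one
  noisy bin can move the refined peak by several percent at 30×); the
  ±3 window averages that noise and is exact for a Gaussian peak.
* **Genome size** = T(c)/d_hom with T(c) = Σ_{d≥c} d·N_d. For genuinely
  Poisson depths the refined mode sits near λ−0.5, a ~2% upward size
  bias at 30× — inherent to mode-ratio estimators and inside the stated
  tolerances.
* **Repeat fraction** = mass share above 1.5·d_hom (midpoint between
  the one- and two-copy peaks). Both the threshold multiplier and the
  windows below are configurable module constants.
* **Heterozygosity**: with the het window [0.35, 0.65)·d_hom and hom
  window [0.65, 1.5]·d_hom, the raw mass split
  f = m_het/(m_het+m_hom) is biased low ~25% at 30× because the het
  component's Poisson tails fall outside its window. The default
  estimator therefore unmixes the two observed window masses against
  the 2×2 matrix of Poisson occurrence-mass capture fractions
  (component means d_hom/2 and d_hom) — closed form, not an iterative
  mixture fit; the raw split is available via `depth_correction=False`.
  Per-site heterozygosity is h = 1 − (1−f)^(1/k), since a k-mer spans k
  sites. The estimator needs d_hom ≥ 4 to resolve the half-depth peak.

Full four-component negative-binomial spectrum fitting (as in genome
profilers) is deliberately out of scope; the ratio formula is the
method under study.

## Phylogenetic signal

Under Brownian motion, tip traits are multivariate normal with
covariance σ²C, C_ij the shared root-to-tip path length. A stem edge
above the root is excluded: its covariance is common to all tips and
confounded with the root state (the ape/phytools convention; including
it measurably shifts the λ optimum).

* **Pagel's λ** scales the off-diagonal of C. For fixed λ the root
  state (GLS) and rate (ML, denominator n) are closed-form, so the
  likelihood is profiled over λ ∈ [0, 1] by bounded scalar optimisation
  (absolute tolerance 1e-6), with the endpoints λ = 0, 1 also evaluated
  and likelihood-ratio tests (χ², 1 df) against both. λ > 1 is not
  searched: C(λ) can lose positive definiteness. The fit matches
  `phytools::phylosig` to ~1e-5 on test fixtures.
* **Blomberg's K** follows the standard ratio of observed to
  Brownian-expected mean squared error around the phylogenetic mean;
  K = 1 exactly on a unit star tree. Significance comes from permuting
  tip-to-value assignments with a seeded generator and the add-one
  estimator p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1), default
  n_perm = 999.
* Linear algebra goes through Cholesky factorisations (never explicit
  inverses) with a 1e-10 diagonal jitter fallback for near-singular C;
  zero-length terminal branches are perturbed by 1e-8 × tree depth with
  a warning.

## Synthetic-data generators

All generators carry explicit seeds (never global state) and are
byte-reproducible.

* **FCM events**: non-debris events split evenly between sample and
  standard; each population places a configured fraction at 4C; 2C/4C
  peaks are Gaussian with the configured CV; debris is a truncated
  exponential over (0, lowest 2C center) with scale a quarter of that
  center — a simple match to the low-channel tail of real histograms
  without modelling nuclease kinetics. Defaults are the study's
  acquisition conditions: 20,000 ungated events, 2% CVs, and — since no
  empirical fractions are published — 5% debris and 10% 4C,
  configurable. Not modelled: dye stoichiometry, S-phase fractions,
  instrument drift.
* **Expected spectra**: mixture components (hom, het, repeat) are
  spread over depth with a discretised Gaussian of variance equal to
  its mean. The Gaussian (rather than Poisson) kernel keeps the
  expected-spectrum mode exactly at λ_k so that noise-free recovery
  checks are exact; Poisson asymmetry enters through the `noise` flag
  (counts Poisson-sampled) and through read simulation, where depths
  are genuinely Poisson. Error k-mers are geometric over depth starting
  at 1 (success 0.8), G·c·e·k of them in expectation.
* **Reads**: haplotype A is a uniform random sequence with an appended
  block of `repeat_multiplicity` copies of one repeat unit (total
  length G); haplotype B carries independent per-site substitutions at
  the heterozygosity rate (no linkage, matching the estimator's model).
  Reads of fixed length are drawn uniformly from both haplotypes
  (balanced halves, random strand) to ceil(G·c/L) reads with
  independent substitution errors. Defaults: G = 200 kb, 30×, k = 21,
  h = 0.005, 30% repeats at two copies, 0.1% error, 150 bp reads —
  desk-scale versions of a large-genome resequencing experiment
  (capped at 10 Mb). Not emulated: indels, quality-score profiles,
  GC bias, transposable-element sequence structure — so passing
  recovery tests demonstrate estimator correctness under the model's
  own assumptions, not robustness to every real-data artefact.
* **Trees/traits**: pure-birth trees via dendropy, with every tip edge
  extended by one extra exponential waiting time so branch lengths are
  strictly positive and the tree stays ultrametric; Brownian traits are
  drawn from N(root·1, σ²C(λ)) by Cholesky.

## Study tables and statistics

The packaged tables transcribe the published flow-cytometry summaries
(34 sex-specific rows over 17 species), per-species sex comparisons and
the two-species flow-vs-k-mer comparison. `study_stats` reports the
overall mean 1C (unweighted over sex-specific means, 2 dp), fold range
(max/min), per-species female−male differences, and flow−k-mer
differences. The mean sex difference is the unweighted mean of
per-species differences, 0.59 pg on the packaged table; the source
study quotes 0.56 pg by an unstated averaging scheme, so the report
carries a footnote rather than asserting that figure. Sex tests use the
pooled-variance Student's t (Welch behind a flag); a group with n = 1
is tested against the pooled variance of its companion and flagged
low-confidence.

The standards suitability band (0.33, 3.30) is a calibration, not a
measurement: it is back-calculated so the *L. migratoria* male standard
spans 2–20 Gb, and the linearity of the band in 1C makes two standards'
ranges disjoint exactly when their log-1C distance exceeds
log(ratio_hi/ratio_lo).

## Problem sizes in tests

The test-suite and example problem sizes — 200 kb genomes at 30×,
20,000-event cytometry runs, 64-tip trees with 50-replicate recovery
loops, 2000-replicate null calibrations — were chosen so the whole
suite exercises every estimator end-to-end in well under a minute of
compute while keeping Monte-Carlo error far below the assertion
tolerances.

## Known limitations

* The k-mer size estimator inherits the ~2% mode-ratio bias at
  moderate coverage and assumes a resolvable homozygous peak
  (λ_k ≥ 4 warns).
* Repeat fraction conflates copy number and mass share: heterozygous
  sites inside repeats shift mass toward the single-copy region,
  biasing the estimate slightly low.
* The λ search is restricted to [0, 1]; traits more similar between
  relatives than Brownian expectation show up in K > 1, not λ > 1.
* FCS binary files are not parsed; events arrive as CSV (an external
  converter can bridge).
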