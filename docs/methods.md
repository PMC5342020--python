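# Methods

`cnabreak` implements a cohort-level analysis of somatic copy-number
aberrations (CNAs) and CNA-associated chromosomal breakpoints from
array-CGH log2 tumor/normal ratio profiles, of the kind used to profile
stage II/III microsatellite-stable colon cancers: probe ratios are
segmented per sample, segments are classified into discrete copy-number
states, the call matrix is reduced to co-aberrant regions, breakpoint
recurrence is tested against a random-breakage null, and regions,
instability scores and gene mutations are related to relapse and
disease-free survival (DFS). A synthetic-cohort generator with full
ground truth stands in for the archived tumor data, so every inference
stage is testable end to end.

## Synthetic cohorts

The generator emulates the structure of a 114-sample (57 stage II + 57
stage III) MSS colon cancer series on a scaled-down genome, by default 5
synthetic chromosomes x 400 evenly spaced probes at 17 kb (2000 probes),
so the full pipeline runs in about a minute; array-scale probe counts
are a configuration choice, not a default.

- **Signal model.** Each probe's log2 ratio is the state offset of the
  covering true segment plus optional per-chromosome sinusoidal waves
  (random phase, default amplitude 0) plus Gaussian noise
  (`noise_sd = 0.1`). State offsets are −0.6 (loss), 0 (neutral), +0.45
  (gain), +1.2 (amplification) — typical values for tumor profiles
  diluted to ~70% tumor cell content; they are configurable.
- **Archetype CNAs** emulate CRC-typical recurrent events (arm-level
  losses of 1p/17p/18-like regions at 25–40% frequency, gains of
  7/13q/20q-like regions at 45–50%, one focal amplicon at 8%).
- **Relapse-associated region.** One loss region is carried with
  penetrance 0.98 in relapsed versus 0.745 in relapse-free tumors, the
  frequencies reported for the 18q12.1–18q12.2 loss in the study this
  design emulates. Relapse counts are fixed at 22/57 (stage II) and
  27/57 (stage III).
- **Mutations.** Gene mutation indicators are drawn at MSS-CRC-typical
  frequencies (APC 0.45, TP53 0.50, KRAS 0.40, ...); KRAS/NRAS/BRAF are
  drawn near-mutually exclusively (one categorical draw per sample), as
  MAPK-pathway mutations are in real tumors. APC and TP53 mutations
  couple to chromosomal instability by adding 3–4 random CNA segments
  (10–60 probes) per mutated sample.
- **Survival.** Relapsed samples receive exponential event times
  (baseline hazard 0.012/month scaled by a relapse hazard ratio) and an
  event flag; relapse-free samples are censored uniformly within the
  follow-up horizon (120 months). The standalone `simulate_survival`
  operation generates exponential times with hazard
  `baseline x HR^stratum`, censored at the horizon, for
  stratified-survival recovery experiments.

What the generator does **not** model: FFPE/dye-bias/GC artifacts,
per-probe variance heterogeneity, tumor-cell-fraction variation between
samples (configurable dilution is off by default), subclonality, and
allele-specific copy number. Passing recovery tests therefore
demonstrates correctness of the inference machinery under an idealized
noise model, not performance on archival FFPE arrays.

## Segmentation

Per sample: median normalization (median log2 ratio → 0), optional wave
detrending, change-point segmentation per chromosome, then mode
normalization.

- **Change-point search.** Recursive max-t splitting: the statistic is
  the maximum over candidate splits of
  `|mean_1 − mean_2| / (s·sqrt(1/n_1 + 1/n_2))`, where candidates are
  all binary splits plus interior arcs `[i, i+w)` on a geometric width
  grid (all widths up to `min_width`-spaced short ones, then ×1.25
  steps). The arc (circular) form is essential: a plain binary contrast
  is diluted by short segments embedded mid-window and misses ~10% of
  focal events at these problem sizes. `s` is the sample's residual
  noise, estimated once as the normal-consistent MAD of lag-1
  differences divided by √2 (robust to the piecewise-constant signal).
  A split is kept only if its within-window permutation p-value is
  below `alpha = 0.01` (`n_perm = 1000`, with early stopping once the
  estimate is clearly above alpha). Accepted arc splits contribute both
  edges; each sub-window is recursed.
- **Boundary refinement.** Because interior arcs are searched on a
  width grid, each split point is re-located at the exact binary max-t
  position between its neighboring boundaries (iterated to a fixed
  point) before and after undo merging.
- **SD-undo.** Adjacent segments are re-merged while their mean
  difference is below `undo_sd x s`, with `undo_sd_short = 2` when
  either segment is ≤ 30 probes and `undo_sd_long = 3` when both are
  longer; the smallest-difference pair merges first. The long-segment
  threshold suppresses wave-induced shallow splits; the 30-probe cut is
  a documented choice, configurable.
- **Mode normalization.** Segment means are shifted so the modal
  (assumed neutral) state sits at 0: a Gaussian kernel density of the
  probe-weighted segment means (fixed absolute bandwidth 0.05 log2
  units) is scanned for peaks; among peaks within 60% of the tallest,
  the one nearest the probe-weighted median is used as the shift. The
  relative-height/median rule protects highly aberrant genomes where an
  aberrant state narrowly outweighs the neutral one; genomes whose
  dominant state decisively outweighs neutral are still re-centered
  wrongly — an intrinsic limitation of mode normalization, shared with
  production aCGH pipelines. All ingredients translate with the data,
  so the shift is equivariant under sample-wide additive offsets.
- **Wave detrending** (off by default) removes per-chromosome
  low-frequency trends by robust harmonic regression: an intercept plus
  Fourier pairs with wavelength ≥ `span` (fraction of the chromosome,
  default 0.3) fitted by Tukey-biweight IRLS, initialized from a
  running-median trend whose wide window rejects copy-number steps.
  Local regression was rejected: no single LOWESS span both tracks a
  1.5-cycle wave and rejects a 50-probe step. Chromosomes with < 10
  probes pass through with a warning.
- **QC.** The per-sample noise estimate doubles as the QC statistic;
  profiles with MAD ≥ 0.4 are flagged as failing (the pipeline does not
  auto-drop them).
- Per-sample permutation streams are seeded from a stable hash of the
  sample name, so segmentation is invariant to sample order.

## Calling and region reduction

Segment means (weighted by probe count) across the whole cohort are fit
with a four-component Gaussian mixture (loss < neutral < gain <
amplification) by EM with **shared component variance** (floor 0.02).
A free per-component variance lets the rare amplification component
balloon into an outlier-soaker that absorbs boundary-diluted segment
means — the shared variance pins every component to its state's tight
cluster. The neutral mean is confined to [−0.1, 0.1]. Initialization is
deterministic: component means seeded at the 2.5/50/90/99% (and, for the
rare amplification cluster, 99.9%) weighted quantiles with a fixed set
of 10 jittered restarts per variant, keeping the best likelihood. A
degenerate amplification component (weight < 1e−4, or collapsed within
0.08 of another mean) triggers a three-component refit, with
amplification retained as a zero-weight placeholder so the class
structure is stable.

Per-segment class posteriors use Bayes' rule with the probe-count-
weighted likelihood (each probe contributes the component density at the
segment mean, i.e. the density is raised to the probe count); a segment
is assigned an aberrant state only when that class's posterior exceeds
0.5, otherwise neutral — including the ambiguous case where no class
reaches 0.5. Probes inherit their segment's state and posterior.

Region reduction merges adjacent probes greedily left-to-right into
maximal runs in which every member probe's per-sample calls disagree
with the region consensus (per-sample modal state) at an average rate
≤ `averror = 0.015`; `averror = 0` reduces to maximal runs of identical
call columns. Region calls are per-sample modal states; region
posteriors are probe averages (used for clustering).

## Breakpoints and recurrent breakpoint genes

Probes added to enrich cancer-gene loci are removed and the cohort is
re-segmented on the filtered panel before breakpoint detection, keeping
probe spacing — and hence the random-breakage null — even. A breakpoint
is anchored at the first probe of every segment except each chromosome's
first, giving each event a unique probe address.

Per-probe recurrence is tested against Binomial(S, r), where r is the
genome-wide per-probe per-sample breakpoint rate, with BH-FDR control
(significant at FDR < 0.1). Breakpoints map to genes through probe
footprints (probes within the gene span; a break between two probes
flanking a probe-free gene is not attributed to it); genes with
identical probe sets are pooled, with affected-sample frequency taken
over the union. Gene-level recurrence uses the per-sample null
probability `q = 1 − (1−r)^m` for an m-probe gene and a Binomial(S, q)
tail p-value. Because these p-values are discrete, genes whose minimum
attainable p-value (`q^S`, all samples affected) exceeds the 0.1
threshold are excluded before BH is applied to the remainder — a
Tarone-style discrete-FDR correction. With the exclusion threshold set
at the nominal FDR level, the procedure provably flags a superset of
plain BH's discoveries (excluded tests could never be rejected, and
shrinking the family only lowers BH-adjusted p-values); the more
aggressive `alpha/K*` working threshold does not carry that guarantee
and was therefore not used.

## Cohort statistics

- **Two-group region tests.** Per region and per aberration type (gain
  vs no-gain, loss vs no-loss; amplification counts as gain): Pearson
  chi-square on the 2x2 carrier table without continuity correction —
  the reference distribution is the label permutation null (default
  B = 10000), so the asymptotic correction has no role. Permutation
  p = (1 + #{null ≥ observed}) / (1 + B). The permutation FDR is the
  averaged-exceedance estimator: for each region, the mean count of
  null statistics ≥ its observed statistic, divided by the count of
  observed statistics ≥ it, capped at 1; FDR families are per aberration
  type. Regions aberrant in < 10% of samples are excluded per type
  (the filter is applied per type because a region can pass it for
  losses while failing it for gains); FDR < 0.2 is the significance
  convention.
- **Instability scores.** CNA-score: probes in a non-neutral state per
  sample; BP-score: breakpoint locations per sample (on the
  enrichment-filtered panel). Score comparisons between mutation strata
  use two-sided Mann-Whitney U tests — exact enumeration for combined
  n ≤ 20 without ties, tie-corrected normal approximation otherwise;
  fully tied inputs return p = 1.
- **Clustering.** Sample dissimilarity is the mean over regions of the
  total-variation distance between 4-class posterior vectors — a
  genuine metric that preserves calling uncertainty rather than hard
  calls — agglomerated with Ward linkage (deterministic; scipy's
  ordering resolves ties). Dendrograms export to Newick.
- **Fisher exact tests** (mutation co-occurrence/exclusivity) use the
  conditional hypergeometric two-sided convention; the raw sample odds
  ratio is reported, with a 0.5-continuity version provided separately
  for display only. Zero margins return p = 1 with a degeneracy flag.

## Survival

Kaplan-Meier product-limit estimation; two-sided log-rank test with the
hypergeometric variance at each distinct event time; Cox proportional
hazards for a binary covariate by Newton iteration on the Breslow
partial likelihood (tolerance 1e−8), Wald 95% CIs. Breslow tie handling
was chosen because it makes the log-rank statistic exactly equal to the
Cox score test at beta = 0 on tie-free data — an identity the test suite
asserts to 1e−8; Efron weighting is not needed at the tie rates the
continuous-time generator produces. Monotone likelihoods (all events on
one covariate level, or a diverging Newton path) are flagged as
separated and reported as an infinite/zero hazard ratio rather than a
spurious finite estimate. Region-level DFS association uses per-region
log-rank statistics with survival-tuple permutations (vectorized across
regions and batches of permutations) and the same averaged-exceedance
FDR estimator and 10% frequency filter as the two-group tests.

## Mutations

A gene is mutated in a sample iff at least one variant record passes all
three filters: variant allele fraction ≥ 0.20 (strict at the boundary),
non-synonymous, and not a known polymorphism (dbSNP membership is an
input flag, not a lookup). Pathway columns (MAPK = KRAS|NRAS|BRAF,
APC_or_MAPK) are recomputed ORs, never stored state. Co-occurrence and
exclusivity screens run per gene pair through the Fisher machinery;
the oncoprint export orders genes by mutation frequency and samples by
mutation burden (ties by name) so the output is canonical regardless of
input order. Samples failing sequencing QC are handled as an explicit
exclusion list upstream; no QC metric is modeled.

## Numerical and design choices

- Internal coordinates are 1-based inclusive; BED I/O converts at the
  boundary. Chromosome ordering is natural (1..22, X, Y).
- Missing log2 ratios are rejected rather than imputed (v1).
- Mixture EM convergence: relative log-likelihood change < 1e−9, max
  500 iterations; SD floor 0.02 prevents zero-variance collapse on
  noise-free fixtures.
- `compare_groups` and the DFS permutation tests derive all randomness
  from a single integer seed; identical seeds give bit-identical
  outputs.
- Permutation p-values are bounded below by 1/(B+1); with B = 10000 the
  smallest reportable p is ~1e−4.
- Modal-state ties in region consensus resolve toward the lower state
  code (loss before neutral), deterministically.

## Problem sizes used in tests and the acceptance script

Recovery checks run on the generator's default 114-sample, 2000-probe
cohort (segmentation recall, calling accuracy, mixture recovery);
fragile-site power and null calibration use 25 replicates of a
114-sample two-chromosome genome with ground-truth breakpoints feeding
the gene-recurrence statistics directly (segmentation exactness is
established separately, so the statistical stage is exercised at full
replicate counts in seconds); permutation-FDR calibration uses 50 null
cohorts of 200 regions x 60 samples at B = 1000; Cox recovery uses
n = 31 strata with ~55% events and 1000–2000 replicates. These sizes
give Monte-Carlo standard errors comfortably below each check's
tolerance.

## Known limitations

- The segmentation permutation test assumes exchangeable noise within a
  window; autocorrelated waves (detrending disabled) inflate splits on
  real data.
- Mode normalization mis-centers genomes whose dominant state decisively
  outweighs neutral (near-triploid tumors).
- The breakpoint null treats probes as exchangeable after enrichment
  filtering; residual spacing irregularities would mis-calibrate r on
  real array designs.
- The averaged-exceedance permutation FDR is an estimator, not a proven
  control procedure; on null cohorts its empirical FDR hovers at the
  nominal level within Monte-Carlo error rather than strictly below it.
- Survival modeling is univariate by design; no covariate adjustment or
  competing risks.
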