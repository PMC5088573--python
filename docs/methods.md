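# Methods

This note documents the models implemented in `colisurf`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Fingerprint similarity

A band profile is a list of ladder-normalized fragment sizes (bp) with
non-negative densitometric intensities.  Analysis is restricted to the
closed window [300, 5000] bp; bands strictly outside are discarded as
artefacts (a strain with nothing left in the window is excluded from the
similarity analysis with a warning, and the pipeline manifest records it).

Similarity is the whole-curve Pearson coefficient used by gel-analysis
software rather than a band-matching (Dice/Jaccard) coefficient: each
profile is rasterized onto 1000 points uniform in log₁₀(bp) — gel migration
is approximately logarithmic in fragment size — as a sum of Gaussians, one
per band, weighted by intensity.  The band-matching **tolerance** (default
0.005) sets the kernel standard deviation as a fraction of the log-size
span, and the **optimization** value (default 0.005) sets the half-range of
a global circular shift search over which the correlation is maximized.
Circular shifts keep the statistic exactly symmetric in its arguments;
identical curves return exactly 1.  A curve with zero variance (only
zero-intensity bands) has no defined correlation and is an error.

The maximum-over-shifts step means the matrix is not guaranteed positive
semi-definite; that is handled at the covariance-repair stage (below).

**UPGMA** operates on d = 1 − s (the simplest monotone transform; heights
are only compared internally) with size-weighted average linkage.  Ties are
broken by merging the lexicographically smallest pair of cluster labels
(a cluster is labelled by its smallest strain id), which makes the merge
sequence fully deterministic; tied configurations produce the same heights
in any order.  Newick output writes branch length = parent height − child
height.  **Screening** at the 90 % criterion forms single-linkage
components of the graph with edges s ≥ 0.90 and keeps the lowest strain id
of each component, so every discarded strain is connected to its
representative's component at ≥ 0.90.  Retention is monotone in the
threshold.

**Phylotyping** is a deterministic lookup in the revised quadruplex
decision table.  Ambiguous genotypes without the relevant allele-specific
screen keep the composite labels A/C and D/E; a positive group-E screen
resolves to E; contradictory screens give `unknown`.  The label vocabulary
is {A, B1, B2, F, A/C, D/E, E, clade, unknown}; no separate C or D labels
are emitted.

## Assays

**Hydrophobicity** is the MATH partitioning fraction
(ODᵢ − ODₐq)/ODᵢ, clamped to [0, 1]; an aqueous reading above the initial
one is measurement noise and clamps to 0 with a warning.

**Charge accounting.** With C_A, C_B the cumulative acid/base (mmol/L),
[H⁺] = 10^(3−pH) and [OH⁻] = 10^(pH−pKw+3) mmol/L (pKw = 14 at room
temperature), the net charge per 10⁸ cells is the acid/base balance of the
sample minus the blank, divided by N_bact/10⁸ and scaled by 10⁻³.  Both
the sample and blank terms use +[OH⁻]: the defining property of the
quantity is that a suspension indistinguishable from the blank has zero
charge at every pH, which forces the same sign in both brackets.  The
variant with −[OH⁻] in the sample term is available behind a
`literal_sign` flag.  Sample and blank are aligned by piecewise-linear
interpolation in pH (titrator records are dense and monotone); replicate
charge profiles can be averaged with `average_charge_profiles` before
deriving quantities.  Derived values: net charge at pH 8.0 (linear
interpolation, no extrapolation), total acidity q(4) − q(10) (invariant to
adding a constant to the profile), and the PZC as the first zero crossing
scanning from pH 4 upward, linearly interpolated between bracketing grid
points.  A profile that never changes sign has no PZC; it is recorded as
missing (never as zero) and later analyses drop it pairwise.  Additional
crossings are reported as warnings.

**EPS** protein and sugar come from ordinary least-squares standard lines
(absorbance vs total μg in the assayed extract); readings below the
calibration intercept clamp to zero with a warning, and totals are
normalized per 10⁸ cells by the extract's cell count.  Zeta potential is an
instrument output and passes through unchanged.

## Inference

- **Rank-sum test** (two independent groups, midranks for ties): exact
  p by full enumeration of rank splits when n₁+n₂ ≤ 12 and there are no
  ties, otherwise the normal approximation with tie and continuity
  corrections.  Identical constant groups give p = 1.  The two-group design
  of the habitat comparison (44 vs 33 strains) requires the independent-
  samples form; a paired signed-rank test cannot apply to unequal groups.
- **Kendall tau-b** with tie corrections; exact p for tie-free n ≤ 8.
  Correlation matrices drop missing values pairwise and flag significance
  at α = 0.05; p-values are reported raw (matching a per-property
  reporting convention), with a Benjamini–Hochberg-adjusted column
  alongside for reference.
- **Mantel test**: the habitat structure matrix is co-membership coded
  (H_ij = 1 for same habitat), so positive r literally reads "similarity is
  larger within habitat"; distance coding is available and only flips the
  sign.  r is the Pearson correlation over strictly-upper-triangle entries;
  p permutes strains jointly over rows and columns, one-sided (greater) by
  default, with the observed statistic included in the count
  ((1+hits)/(1+n_perm)).  Note that for perfectly block-structured
  similarity the attainable p is bounded below by the probability that a
  random permutation preserves the partition, not by 1/(1+n_perm), unless
  the groups are large.
- **Covariance repair**: the similarity matrix is symmetrized, its diagonal
  forced to 1, and eigenvalues below ε = 10⁻⁸·λ_max are clipped up to ε
  before reconstruction.  The smallest eigenvalue before/after repair is
  reported with every GLS fit.
- **Relatedness-corrected GLS**: X = [1, 1{sediment}], residual covariance
  σ²V with V fixed (no estimated mixing parameter), solved by whitening
  through the Cholesky factor of V; σ̂² = whitened RSS/(n−2); two-sided
  t-test on n−2 degrees of freedom for the habitat coefficient.  With
  V = I this reduces exactly to OLS.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
every latent recorded in a `TruthBundle`:

- **Fingerprints.** A pool of `n_band_positions` (default 30) candidate
  band positions, log-uniform in [350, 4800] bp, is split into a shared
  core (`shared_band_fraction`, default 0.9) and habitat-specific
  positions.  Each strain carries each band of its habitat pool with
  probability 0.75, log-normal intensity (σ = 0.35), per-band log-position
  jitter (0.003 of the log-span — lane-to-lane migration noise, the reason
  the similarity computation needs a matching tolerance), plus a Poisson
  (mean 12) number of lane-specific spurious bands at random positions.
  The spurious bands give every lane an idiosyncratic component, which is
  what keeps realized similarity matrices comfortably positive definite at
  moderate cohort sizes — the regime the fixed-V GLS needs (see
  Limitations).  The default shared fraction is high because the study
  system shows only weak habitat clustering of fingerprints; with
  `shared_band_fraction = 1` the expected within/between-habitat similarity
  gap is zero (the Mantel null).
- **Traits.** Five latent traits (hydrophobicity, zeta potential, EPS
  protein, EPS sugar, and a log charge-density factor) follow
  y = μ + β·1{sediment} + scale·(g + ε), with g ~ MVN(0, σ_g²·V) drawn
  through the Cholesky factor of the repaired realized similarity matrix V,
  and ε iid N(0, σ_r²).  Defaults: σ_g = 0.1, σ_r = 0.05; sediment effects
  β = (0.15, 0, 0.08, 0.12, −0.35); means (0.35, −20 mV, 0.55, 1.25, 0);
  scales (1, 60, 1, 1.6, 1) chosen so simulated property ranges match
  field-observed ranges (hydrophobicity ≈ 0.0–0.9, zeta ≈ −7…−40 mV, EPS
  protein ≈ 0.3–0.9 μg/10⁸ cells).  A sediment-only coupling (slope 0.75)
  adds the hydrophobicity deviation into EPS protein for sediment strains,
  reproducing the observed one-habitat correlation (Kendall tau ≈ 0.4 in
  sediment, ≈ 0 in water).
- **Titrations.** Per-strain surface model
  q(pH) = offset − Σ dᵢ/(1+10^(pKaᵢ−pH)) with base sites
  (1.2·10⁻⁴ meq/10⁸ cells at pKa 5.0; 0.8·10⁻⁴ at pKa 8.5), fixed positive
  offset 0.9·10⁻⁴, and per-strain site densities scaled by
  exp(charge-factor trait).  One latent therefore moves total acidity,
  net charge at pH 8 and PZC coherently — sediment strains get lower
  acidity, less negative charge and higher PZC.  Titration records are the
  closed-form inverse of the charge-accounting equation on a pH 4–10 grid
  (step 0.05), noise-free by default so recovery is exact; a `noise_sd`
  knob jitters recorded pH values.  MATH ODs and EPS absorbances are
  back-computed from the true traits through the same formulas the assay
  module inverts.

What the generator does **not** emulate: gel-image optics and ladder-lane
normalization (profiles are born normalized), growth-phase and storage
effects, replicate assay noise (defaults are noise-free so round-trip tests
are exact), multi-modal or skewed trait distributions (all noise is normal
on the trait's scale — the field data's true shapes are unknown), and
sampling-campaign structure (site, season).  Passing tests therefore
demonstrate correctness of the computations and calibration of the
inference under the assumed structure, not robustness to real-gel
artefacts.

## Calibration properties (verified by the test suite)

- UPGMA, Kendall tau-b and the exact rank-sum p match independent
  brute-force oracles; GLS with V = I matches the OLS closed form to 1e-10.
- On null cohorts (shared band pool, β = 0, residual σ_r = 0 so the trait
  covariance is exactly σ_g²V), the Mantel test (199 permutations) and the
  GLS habitat t-test both reject at the nominal 5 % rate (95 % Wilson
  interval over 500 cohorts).
- On 12+12 cohorts with β = 0.2, σ_g = 0.1, σ_r = 0.05, the GLS habitat
  estimate is unbiased (Monte-Carlo mean within its CI of 0.2) and 95 % CI
  coverage is ≈ 0.95.  The recovery study uses 12+12 cohorts because that
  is the regime where realized similarity matrices are well conditioned
  (smallest eigenvalue ≈ 0.14) and the iid residual is a mild perturbation
  of the assumed covariance.
- Naive OLS on relatedness-clustered data rejects a true β = 0 far above
  the nominal rate where the V-weighted GLS stays calibrated — the reason
  for correcting the habitat comparison for genomic similarity at all.

## Limitations

- **Conditioning of the similarity covariance.**  The maximum-over-shifts
  Pearson similarity is not a PSD kernel, and smoothed densitometric curves
  of many strains become nearly linearly dependent; at study-sized cohorts
  (n ≈ 77) the realized matrix has near-zero (even negative) eigenvalues.
  The eigenvalue clip makes V usable, but a fixed-V GLS puts weight 1/λ on
  those repaired directions, so its estimates degrade sharply when trait
  noise has any component not proportional to V.  The per-fit conditioning
  report (`v_conditioning`) exposes this; results from poorly conditioned
  fits should be read with caution, and mixing-parameter extensions
  (estimating a V-vs-identity blend) are deliberately out of scope.
- The Mantel p resolution is 1/(1+n_perm); the permutation count (default
  9999, 199 in Monte-Carlo studies) trades resolution for runtime.
- Exact rank-sum enumeration is limited to n₁+n₂ ≤ 12 without ties; beyond
  that the corrected normal approximation is used.
- PZC reporting assumes a single biologically meaningful crossing; profiles
  with multiple crossings (possible under measurement noise) report the
  first and warn.
- Problem sizes in the test suite (500 null cohorts of 20+20; 300 recovery
  cohorts of 12+12; oracle checks at n ≤ 7–50) were chosen so the whole
  suite runs in a few minutes on one core while keeping Monte-Carlo
  intervals tight enough to be informative.
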