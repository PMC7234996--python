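# Methods

## Model and procedure

The quantity under test is the association between a binary species-level
factor (KEAP1 functional status: 1 = basal Aves, 0 = Neoaves, where the
factor is by construction a clade) and a continuous trait (MS-BMR in
kJ h⁻¹ · mass⁻¹, or maximum lifespan in years), within strata of a second
trait. The test statistic is the tie-corrected Kruskal–Wallis H

H = [ 12/(N(N+1)) Σᵢ Rᵢ²/nᵢ − 3(N+1) ] / C,  C = 1 − Σ_g (t_g³ − t_g)/(N³ − N),

with Rᵢ the rank sum of group i and t_g the tie-group sizes. Under
exchangeability H is asymptotically chi-square(k−1); under phylogenetic
structure it is not, and the package replaces the reference distribution with
an empirical null: replicate characters are simulated under Brownian motion
(BM) on the stratum-pruned time tree and each replicate's H is computed
against the real factor labels. BM on a tree means trait increments along
each edge are independent Gaussians with variance σ²·(branch length), so tip
values are jointly Gaussian with covariance σ² times the shared root-to-MRCA
path length (the shared-path matrix). The 95th nearest-rank percentile of
1000 simulated H values is the significance threshold; the observed H must
strictly exceed it (ties are conservative). Both an add-one empirical p,
(1 + #{h ≥ H_obs})/(1 + n_sims), and the raw proportion are reported, since
the estimator behind published PI p-values is ambiguous.

Strata are screened first with the conventional chi-square KW test at
α = 0.05 and only screened strata can be declared significant; because
phylogenetic structure inflates the null, the empirical threshold virtually
always exceeds the chi-square quantile, so in practice the screen is implied
by the percentile rule and the overall procedure operates at the empirical
test's level.

## Key choices and their rationale

- **Scale-free null.** Increments are generated as standard normal draws
  scaled by sqrt(σ²·branch) and shifted by the root state, so the
  within-replicate rank ordering — hence the null H vector — is bit-identical
  for any σ² > 0 and any root state. The unstated simulation parameters of
  the original analysis therefore cannot matter; defaults are σ² = 1,
  root = 0.
- **Labels fixed, trait resampled.** The factor is an attribute of the
  species' phylogenetic positions; simulating the trait on the same tree is
  what makes the simulated characters "originate from the same phylogenetic
  position" as the real ones. Label permutation is used only as an
  independent check on star trees, where both schemes are exchangeable.
- **Reproducibility.** One RNG substream per replicate, derived from
  (seed, replicate index), so replicate r is stable under changes of
  n_reps; one stream per stratum, derived from (master seed,
  SHA-256(stratum id)), so adding strata never perturbs existing nulls.
  All result writers emit deterministic bytes.
- **Percentile and p-value estimators.** Nearest-rank percentile
  (m = ⌈q/100·n⌉-th order statistic): well-defined at n = 1000 with no
  interpolation scheme to invent. Add-one p avoids p = 0 from finite
  simulation.
- **Pruning preserves depths.** Pruning a tree to a stratum keeps the
  original root position by folding suppressed basal segments into the stem,
  so root-to-tip depths and the shared-path (BM covariance) structure of the
  retained tips are exactly unchanged.
- **Polytomies** are resolved deterministically into caterpillars of
  zero-length edges with children ordered by smallest descendant label. The
  original polytomies were resolved from literature node dates that are not
  available; the zero-length rule is the unique resolution that leaves the
  BM covariance unchanged, and it is logged when applied.
- **Mann–Whitney switch.** Exact enumeration p when the combined sample is
  ≤ 12 without ties (small strata need exactness), otherwise the
  tie-adjusted normal approximation with continuity correction. Balance
  checks read p ≥ 0.05 as "indistinguishable"; accepting a null this way is
  logically weak and is reported as a per-bin flag rather than hidden.
- **Stratification bins** are left-closed right-open with open-ended outer
  bins; default edges 10,20,30,40,50 y (lifespan) and 2..8 (MS-BMR)
  reconstruct the named groups of the source analysis ("<10 years",
  "10–19.9", ">8 MS-BMR", ...). MS-BMR is the raw BMR/mass ratio with no
  unit conversion: every downstream statistic is rank-based, so units cancel.
- **ARE scanning** matches the IUPAC consensus TGASWMAKCN (64 expansions) on
  both strands by default (AREs act orientation-independently), reports all
  overlapping hits in 0-based half-open forward-strand coordinates, and
  treats sequence 'N' as matching only pattern 'N'. Windows are the 1000 bp
  upstream of the BED locus start, strand-aware, truncated (not dropped) at
  contig edges. Whether the anchor is a TSS or CDS start is delegated to the
  supplied BED intervals.

## What the synthetic data emulates — and what it does not

`synthetic_data` generates pure-birth (Yule) trees rescaled to depth 1.0
(time is expressed in units of total tree depth; with rank-based statistics
only relative branch lengths matter), labels the internal clade whose size is
closest to 85% of tips as KEAP1-nonfunctional — mirroring the ~180/205
Neoaves share of the real cohort — and evolves two independent BM traits
(σ² = 1), the response receiving an optional clade shift expressed in units
of the root-to-tip BM standard deviation. Traits are mapped through exp() so
MS-BMR-like and lifespan-like columns are positive and right-skewed (the
lifespan column is scaled to a 20-year median); body mass is a random power
of two so BMR/mass reproduces the MS-BMR column exactly in floating point.
Promoters are i.i.d.-background sequences with non-overlapping consensus
expansions planted at recorded positions.

This emulates the *statistical structure* of the real inputs, not their
content: no real taxonomy, no fossil calibration, no measurement error, no
trait-dependent sampling, no correlation between mass and BMR beyond the
constructed ratio, and a single clean clade shift rather than whatever
mixture of processes produced the real trait distributions. Passing tests
demonstrate that the machinery is calibrated and recovers planted structure
under its own model; they do not certify conclusions about real birds, whose
data (a curated BMR compendium, the AnAge lifespan database, fossil-dated
phylogenies) are not distributed with this package. For the same reason the
published per-stratum p-values (e.g. 0.03 and 0.02 for MS-BMR in the two
youngest lifespan groups) are not machine targets here, though the worked
example reproduces p-values of the same order under a comparable effect.

## Operating characteristics (recomputed by `scripts/acceptance.py`)

- On a 200-tip star tree the PI threshold agrees with the chi-square(1)
  0.95 quantile (3.841) and with a label-permutation threshold to within
  Monte-Carlo error (~0.23 SE at 1000 simulations).
- On null clade-structured cohorts (80 tips, no effect) the stratified
  pipeline rejects ~3.5–4.5% of strata, while the conventional KW test
  rejects ~40–55%: the inflation the method exists to remove.
- Power rises monotonically with the clade shift but is limited by design:
  a monophyletic factor means the clade-mean contrast is effectively a
  single independent observation, so the empirical null itself carries that
  contrast's variance. Measured power is ~0.5–0.6 at a 2-SD shift and
  ~0.95 only near 5 SD, roughly independent of tip count (80 vs 150). This
  is the statistical price of immunity to the confound, not an
  implementation artifact — the star-tree calibration shows the engine is
  exact where exchangeability holds. The companion test suite asserts a
  near-complete-recovery condition at 2 SD that this analysis shows to be
  unattainable; it is left failing deliberately rather than weakened.

## Problem sizes

Validation studies use 200 null datasets × 500 simulations (type-I/inflation),
100 datasets per shift level (power), 1000 simulations for single-threshold
calibration, and 10,000 replicates for simulator moment checks — sizes chosen
so every Monte-Carlo tolerance (3 SE, binomial bands) is meaningful while the
whole suite runs in well under a minute.

## Known limitations

- The pipeline is nonparametric by construction; it does not implement
  normality screening or parametric PCM alternatives (e.g. PGLS).
- k > 2 factor levels are accepted by the KW machinery but only the binary
  case is validated against the study design.
- No multiple-testing correction across strata is applied (matching the
  source analysis); strata failing the balance check are flagged and
  reported, with exclusion left to the caller.
- Empirical p-values are bounded below by 1/(1 + n_sims); at the default
  1000 simulations the smallest reportable p is ≈ 0.001.
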