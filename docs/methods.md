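# Methods

## Scope and data model

The pipeline analyses plot tables on an integer 1-km lattice: one row per
plot with coordinates in km, a canopy-cover percentage `cover_pct` in
[0, 100], and one nonnegative integer stem-count column per species. Counts
are modelled as Poisson; per-hectare densities must be rounded to counts by
the caller explicitly — the fitter rejects non-integer counts rather than
rounding silently. A rooted phylogeny with branch lengths in Myr (Newick) and
an optional species → clade table complete the inputs.

## Landscape averaging

Landscape cover at radius *r* is the unweighted mean of `cover_pct` over all
existing plots whose lattice nodes lie within the closed disc of radius *r*
around the focal node, the focal plot included. On a 1-km lattice the discs
of radius 1.6, 3.2 and 6.4 km hold at most 9, 37 and 129 nodes; lattice
intersections without a plot are skipped and `n_available` records how many
plots each mean actually used. Discs are closed (`distance ≤ r`) and offsets
are enumerated in row-major order for determinism.

Border handling: plots closer than a margin (default 6.4 km, the largest
radius) to the axis-aligned bounding rectangle of the coordinates are dropped
before any averaging, so no retained plot has a neighbourhood truncated by
the domain edge. Real-geometry borders (coastlines, country borders) are an
adapter concern; the library only knows the bounding rectangle, and exposes
`n_available` so downstream users can audit incomplete circles.

## Occurrence model and the Ω statistic

For species *j*, counts are Poisson with rate `λ = M_j + C_j·F` under the
default identity link. The identity link can propose non-positive rates, so
the likelihood is evaluated with the rate clipped below at 1e-10; plots in
the clipped region contribute no curvature and the line search keeps the
iterates in the supported region. The solver is a damped Newton iteration
vectorised across bootstrap replicates, with a Nelder–Mead fallback on the
identical clipped objective for replicates that fail to converge. A log link
(`λ = exp(M + C·F)`) is available throughout; the log-link fit is verified
against statsmodels' Poisson GLM in the test suite.

Model screening uses AICc with `k = 2` against the intercept-only model
(`k = 1`, whose MLE is the sample mean); `ΔAICc > 10` marks the cover model
informative. Fits use **all** plots (zeros included) by default, because the
zero class is what the occurrence probability `P(ρ>0) = 1 − e^(−λ)` is about;
an `occupied_only` flag provides the alternative of fitting only occupied
plots, since field protocols differ on this point.

Ω is `ln[P(F=5)/P(F=75)]`. Because P is strictly increasing in λ and λ is
monotone in F with slope C, sign(Ω) = −sign(C) for every informative fit —
this invariant is asserted in the tests under both links. The bootstrap
resamples plots with replacement (same n), refits, and takes the 95% CI at
the ranked positions `floor((B+1)·0.025)` and `ceil((B+1)·0.975)` — ranks 25
and 976 at B = 1000. Failed replicates are refit with the robust fallback
and, if still degenerate, redrawn so B stays fixed; more than 20% cumulative
failures aborts the species with a diagnostic. Classification is by CI
position: strictly below zero → negative, strictly above → positive,
otherwise neutral (a bound exactly at zero counts as including zero). Across
scales, the best scale is the informative fit with minimum AICc, ties broken
toward the more local scale for deterministic output.

Per-species bootstrap streams are seeded from the master seed plus a CRC-32
hash of the species name (plus the scale index), so results are invariant to
the order in which species are processed.

## Pagel's λ

The trait covariance is `σ²·V(λ)` where `V(λ)` multiplies the off-diagonal
entries of the phylogenetic VCV (root-to-MRCA shared path lengths) by λ and
keeps the diagonal. For each λ the mean is profiled by GLS and σ² by its ML
estimator (divisor *n*); λ is then maximised on [0, 1] by a 21-point coarse
grid followed by bounded scalar search (tolerance 1e-8), with the interval
endpoints always kept as candidates so boundary optima are exact. The search
is restricted to [0, 1] even though some implementations allow λ up to a
tree-dependent maximum — the statistic is interpreted on that range and
published medians typically sit at the λ = 1 boundary. The LRT against λ = 0
uses the χ²₁ upper tail; with λ̂ on the boundary this is conservative, which
we accept to match the convention of the standard R implementation
(`phytools::phylosig`, against which the fit is cross-checked to ~1e-5 in λ
and exactly in log-likelihood on a frozen dataset).

Ω-uncertainty propagation: per iteration *i*, one Ω per species is drawn
uniformly from its 95% CI with a generator seeded `[master_seed, i]` (stable
under parallel or out-of-order execution), λ is refit, and medians of λ and
*p* over iterations are reported together with the full per-iteration table
for histogramming. Raw (not log) *p*-values are medianed. Species whose
occurrence model was uninformative have no Ω and are pruned from the tree
before estimation, with a logged prune; clade subsets with fewer than 3
usable tips are reported as not estimable rather than failing the run.
Pruning preserves root-to-tip path lengths, so a clade's VCV equals the
corresponding submatrix of the full-tree VCV (tested against a brute-force
path-overlap oracle).

## Synthetic generator

The generator emulates inventory-like data, not any real geography:

- **Cover field** — Gaussian white noise on the grid smoothed with a
  Gaussian kernel (σ = `cover_smoothing_scale` km, periodic boundaries) and
  mapped through the normal CDF onto [0, 100]. This meets the correlation
  contract (near plots more similar than far plots) while giving a roughly
  uniform cover histogram; it does not reproduce topographic gradients,
  fragmentation patterns or coastlines.
- **Phylogeny** — a pure-birth (Yule) tree: exponential waiting times with
  rate `birth_rate × lineages`, uniform choice of the splitting lineage, all
  tips extended to the present, hence exactly ultrametric. Default birth
  rate 0.05/Myr gives ~60–100 Myr deep trees at 40–64 tips.
- **Response parameters** — a trait evolves under Brownian motion with rate
  `bm_sigma2` (default 1.0/Myr) from root state 0; the slope `C_j` is an
  affine map of the tip trait onto `c_range` (default [−0.02, 0.02]), which
  preserves phylogenetic signal exactly (λ is affine-invariant) and
  guarantees both response signs are present. `M_j` is uniform on `m_range`
  (default [1, 3] stems/plot). The two children of the root define two
  labelled clades standing in for major lineages.
- **Counts** — Poisson draws at `λ = M_j + C_j·F` (clipped at 1e-10; a log
  link is available as an alternate generating model), followed by
  structural-zero thinning: occupied plots are zeroed at random until each
  species' occupied fraction matches the target `occupancy` (default 0.10).
  The defaults keep the pre-thinning occupancy above the target for every
  slope in `c_range`, so thinning can always reach it. Thinning emulates
  range limits and habitat filters that the occurrence model ignores — as
  with real data, the fitted (M, C) are then attenuated relative to the
  generating values while the sign and ordering of responses are preserved.
  Parameter-recovery tests therefore use `occupancy = 1`.

What passing tests on this generator show: the estimators recover generating
parameters, CI coverage is calibrated, and the λ contrast between Brownian
and shuffled traits is detected. What they do not show: robustness to spatial
autocorrelation of residuals, observation error in cover, zero-inflation
beyond simple thinning, or non-Brownian trait evolution — none of which the
analysis models.

## Numerical choices and defaults

| Parameter | Default | Notes |
| --- | --- | --- |
| landscape radii | 1.6, 3.2, 6.4 km | closed discs on the 1-km lattice |
| border margin | 6.4 km | largest radius |
| F_low / F_high | 5% / 75% | Ω evaluation points |
| min occupied plots | 25 | species selection, with tree-tip matching |
| ΔAICc threshold | 10 | vs intercept-only |
| bootstrap B | 1000 | CI ranks 25 / 976 |
| signal iterations | 1000 | uniform draws within Ω CIs |
| rate floor | 1e-10 | identity-link clipping |
| λ search tolerance | 1e-8 | bounded scalar search after coarse grid |

Reported example and acceptance runs use scaled-down sizes (grids of
~30–60 km, 100–200 bootstrap replicates, 50 signal iterations) chosen so a
full run completes in minutes on one CPU while leaving every Monte-Carlo
margin comfortable; all sizes are configurable back to the defaults above.

## Known limitations

- No zero-inflated or negative-binomial count models, and no spatial
  autocorrelation correction in the occurrence fits.
- The identity link can propose negative rates; the clipped-likelihood
  constraint handles this but makes the likelihood flat wherever all
  observed F fall in the clipped region.
- χ²₁ reference for the LRT is conservative at the λ boundary.
- Planar-km lattice only; no projected or great-circle coordinates.
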