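# canopyresponse

Tools for quantifying how tree species respond to forest canopy loss across
spatial scales, and whether that response carries phylogenetic signal.

The package is aimed at forest ecologists working with inventory-style data:
plots on the intersections of a 1-km grid, each with a locally measured canopy
cover percentage and per-species stem counts, together with a dated phylogeny
of the species pool. Because large national inventories are rarely
redistributable, the package ships a first-class synthetic generator that
emulates such data with known ground truth, so every stage of the analysis has
a parameter-recovery test.

## The method

1. **Multi-scale cover.** For each plot, canopy cover is averaged over all
   existing plots inside closed discs of radius 1.6, 3.2 and 6.4 km centred on
   its lattice node (at most 9, 37 and 129 nodes on a 1-km lattice; missing
   nodes are skipped). Plots within 6.4 km of the domain border are excluded.

2. **Occurrence models.** Stem counts ρ of species *j* in a plot with cover
   *F* are Poisson with rate

       λ(j, F) = M_j + C_j · F        (identity link, default; a log link is available)

   fitted by maximum likelihood per species and scale. A cover model is kept
   only when its AICc beats the intercept-only model by more than 10. The
   occurrence probability is P(ρ > 0) = 1 − e^(−λ), and the response statistic

       Ω_j = ln [ P(j, F = 5%) / P(j, F = 75%) ]

   is positive for species favoured by open canopies and negative for
   forest-affiliated ones. A nonparametric bootstrap (1000 resamples of plots
   with replacement; CI bounds at ranked positions 25 and 976) classifies each
   species as negative, neutral or positive depending on whether the 95% CI
   lies below, spans, or lies above zero. AICc compared across scales gives
   each species a best explanatory scale.

3. **Phylogenetic signal.** Pagel's λ is estimated for the Ω values by
   maximum likelihood on the phylogenetic variance–covariance matrix
   (off-diagonals scaled by λ ∈ [0, 1]), with a χ²₁ likelihood-ratio test
   against λ = 0. Uncertainty in Ω is propagated by drawing, in each of 1000
   iterations, one Ω per species uniformly from its 95% CI and refitting λ;
   medians over iterations are reported, for all species together and per
   clade (e.g. angiosperms vs gymnosperms).

## Worked example

```python
from canopyresponse import SyntheticConfig, PipelineConfig, run_pipeline, summarize

syn = SyntheticConfig(grid_nx=34, grid_ny=34, n_species=12, occupancy=0.5, seed=0)
cfg = PipelineConfig(radii=(1.6,), min_occupied=10, n_boot=200, n_iter=50,
                     seed=0, synthetic=syn)
result = run_pipeline(cfg)
table, text = summarize(result)
print(text)
```

prints

```
scale local: 4 negative (33%), 0 neutral (0%), 4 positive (33%), 4 unexplained
scale 1p6: 4 negative (33%), 0 neutral (0%), 4 positive (33%), 4 unexplained
best scale local: 4/8 species (50%)
best scale 1p6: 4/8 species (50%)
```

i.e. of the 12 simulated species, 8 had an informative cover model at both
scales, split evenly between forest-affiliated (negative Ω) and open-habitat
(positive Ω) responders — matching the generating slopes, whose sign always
opposes Ω. The signal table from the same run shows strong phylogenetic
structure in Ω (the generating slopes evolved under Brownian motion):

```
scale  scope  n_tips  n_iter  median_lambda  median_p
local    all       8      50       0.945041  0.036461
local cladeA       3      50       0.000000  1.000000
local cladeB       5      50       0.891867  0.123910
```

(with only 3–5 tips per clade the within-clade tests are underpowered, as
expected). The same stages are available on the command line:

```sh
canopyresponse simulate --config syn.yaml --seed 3 --out data/
canopyresponse landscape --plots data/plots.csv --radii 1.6,3.2,6.4 --margin 6.4 --out cover.csv
canopyresponse fit --plots data/plots.csv --cover cover.csv --tree data/tree.nwk --out results/
canopyresponse phylosig --tree data/tree.nwk --omega results/omega.csv --clades data/clades.csv --out signal/
canopyresponse run --config pipeline.yaml --out out/
```

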