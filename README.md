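# dielfd

Functional-diversity analysis across the diel cycle: how would the loss of
threatened mammals reshape the trait space of night-active versus day-active
faunas?

Species in decline may stop exerting their ecological function long before
they go extinct.  `dielfd` implements a progressive *functional-extinction*
framework over a species × trait table: species are removed from trait space
in order of IUCN threat status (CR, then CR+EN, then CR+EN+VU, then
CR+EN+VU+NT plus Data Deficient species predicted threatened), separately
within each diel niche (nocturnal, crepuscular, cathemeral, diurnal), and the
consequences are measured three ways:

1. **Risk summaries** — per-niche removal proportions and log-odds contrasts
   against the nocturnal baseline.
2. **Global trait spectra** — each niche's five traits (log₁₀ body mass,
   log₁₀ litter size, √habitat breadth, ordinal foraging stratum, and a
   continuous diet score from a Gower + principal-coordinates ordination of
   10 diet categories) are reduced to 2-D by PCA; a bivariate Gaussian KDE
   with an unconstrained 2-stage plug-in bandwidth H estimates the occurrence
   probability f̂(x) = n⁻¹ Σᵢ φ_H(x − xᵢ) of trait combinations, with
   highest-density contours at the 0.5/0.95/0.99 quantiles of {f̂(xᵢ)}.
   Removing the threatened species and refitting yields the mean absolute
   change of max-normalized density inside the full spectrum's 0.99 region,
   and the *volume loss* — the fraction of that region falling outside the
   survivors' 0.99 boundary.  Both are compared against 100 random removals
   of the same number of species from the niche.
3. **FD maps** — over a presence–absence grid, functional diversity per pixel
   and niche is the total branch length of a global Gower/UPGMA dendrogram
   pruned to the species present (FD = Σ branch lengths, hclust height
   convention).  Proportional FD loss under each scenario, its 75th-percentile
   (UIQ) summary, and a per-pixel randomization null separate losses of
   functionally *dispersed* species (observed − null > 0) from *redundant*
   ones (< 0).  Pixels with ≤ 5 species in the niche are excluded.

A synthetic-data generator produces species tables, diet-category tables and
contiguous-range presence–absence grids with the statistical structure the
analysis assumes (realistic niche shares, right-skewed masses, a fast–slow
life-history axis, optionally trait-clustered threat), so the entire pipeline
is testable without any downloads.

## Worked example

Simulate a 600-species world and measure spectrum reorganization for the
diurnal and nocturnal niches under all four scenarios:

```sh
dielfd spectra --n-species 600 --seed 7 --reps 50 \
    --bandwidth normal_scale --niche diurnal --niche nocturnal --out demo/
```

```
    niche scenario   n  n_removed  mean_abs_density_change  volume_loss  null_lo_change  null_hi_change  null_lo_volume  null_hi_volume
  diurnal       CR 111          6                 0.017239     0.011770        0.012127        0.028464        0.000000        0.148501
  diurnal       EN 111         20                 0.035253     0.071491        0.024404        0.065320        0.009462        0.183184
  diurnal       VU 111         32                 0.067219     0.162019        0.031037        0.065314        0.003831        0.216994
  diurnal       NT 111         46                 0.111608     0.338099        0.038211        0.102880        0.043939        0.277127
nocturnal       CR 399         21                 0.010193     0.000664        0.006254        0.013302        0.000931        0.024465
nocturnal       EN 399         47                 0.021675     0.038580        0.010737        0.027640        0.002545        0.065015
nocturnal       VU 399         86                 0.034876     0.081391        0.015576        0.036927        0.013246        0.102103
nocturnal       NT 399        126                 0.063916     0.130341        0.018220        0.047171        0.009591        0.120449
```

Reading the NT rows: losing all threatened diurnal species would shift the
relative density of occupied diurnal trait space by 11.2% on average —
well above the null interval [0.038, 0.103] for 46 random removals, because
threatened species cluster in trait space — and erase 33.8% of the spectrum's
0.99-quantile footprint.  The speciose nocturnal niche is buffered by
functional redundancy: its density change (6.4%) is roughly half the diurnal
one despite nearly three times as many removals.  Change statistics grow
monotonically along the nested CR → NT gradient.

Other subcommands: `dielfd simulate` (write a synthetic dataset),
`dielfd riskstats`, `dielfd fdmaps`, `dielfd congruence`.  All accept
`--config cfg.yaml` plus flag overrides and write a JSON run manifest; fixed
seeds give byte-identical outputs.

The same functionality is available as a library:

```python
from dielfd import (GeneratorParams, generate_species, transform_traits,
                    fit_pca, spectrum_null, SCENARIOS)

table, diet = generate_species(GeneratorParams(n_species=300, beta_mass=1.5), seed=0)
scores = fit_pca(transform_traits(table)).scores.to_numpy()
removed = SCENARIOS["NT"].removal_mask(table)
res = spectrum_null(scores, removed, reps=100, seed=1)
res["mean_abs_density_change"].observed, res["mean_abs_density_change"].interval
```

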