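# nichetrack

Reconstructing the **lived seasonal climate niche** of annual plants from
herbarium specimens, and testing whether that niche is evolutionarily
conserved across a clade.

Annual plants in Mediterranean climates do not experience the year-round
climate of their home sites: they germinate with the first substantial fall
rains and die by early summer. A species' realized climate is therefore set
jointly by *where* it grows and *when* it grows. `nichetrack` reconstructs,
for every herbarium specimen, the window from its estimated germination
month to its collection month, summarizes monthly climate (mean temperature,
summed precipitation, summed climatic water deficit, CWD) over that window,
and asks whether species across a phylogeny track similar growing-season
conditions despite occupying very different annual climates — the signature
of phylogenetic niche conservatism expressed through phenology and
microhabitat choice rather than through physiological adaptation.

## What it computes

For specimens with collection date in year *Y*, the water year runs
September 1 of *Y*−1 through August 30 of *Y*. Three windows are built per
specimen:

- **specimen-specific** — first water-year month (Sep–Feb) with rainfall
  > 25 mm (else the wettest pre-March month) through the collection month;
- **annual** — the full water year (12 months);
- **clade-seasonal** — the fixed October–April growing season (7 months).

Species-level niche values (specimen means) then feed:

- **window-variance comparisons** — Brown–Forsythe/Levene tests of whether
  across-species variance in the lived niche is smaller than in the fixed
  seasonal niche;
- **ΔCWD tracking statistic** — per-species difference between lived and
  clade-seasonal summed CWD, regressed on mean latitude by PGLS;
- **phylogenetic comparative tests**, implemented from first principles:
  Felsenstein's independent contrasts and their correlations, Blomberg's
  *K* (variance ratio, *K* = 1 under Brownian motion) with a
  tip-permutation signal test and a Brownian-simulation test of *K* > 1,
  and generalized least squares with covariance Cov(εᵢ, εⱼ) = σ²·Cᵢⱼ where
  Cᵢⱼ is the shared root-to-MRCA branch length;
- **evolutionary model fits** — Brownian motion (BM), Ornstein–Uhlenbeck
  (OU, dx = −α(x − θ)dt + σ dW), and bounded Brownian motion (BBM, BM
  between reflecting bounds, fit on a discretized trait interval), compared
  by AIC with a 2-unit support rule;
- **soil-refugia statistics** — occupied-cell water-holding capacity minus
  the mean of 100 random points in a 20-km buffer, per-species means, a
  two-tailed exact sign test, and PGLS of the deltas (and of field-soil
  coarse fractions) against annual temperature and CWD.

A first-class synthetic-data generator produces trees (Yule, unit height),
latitudinally structured Mediterranean monthly climates, specimen records
(98 % collected March–July), spatially autocorrelated soil grids and field
soil samples — including a **niche-tracking scenario** in which collection
phenology compensates for the latitudinal CWD gradient, used to verify that
the full pipeline recovers a planted conservatism signal.

## Worked example

Run the niche-tracking scenario (14 species × 50 specimens) through QC,
phenology, window summaries and the window-variance statistics:

```python
import nichetrack as nt
from nichetrack.phylo_comparative import pgls
from nichetrack.synthetic_data import gen_tree

res = nt.run_full_pipeline(
    {"scenario": {"n_species": 14, "n_specimens_per_species": 50,
                  "tracking_strength": 1.0},
     "stages": ["qc", "phenology", "windows", "stats"]},
    seed=1)

sw = res["stats_windows"]
print(sw[["variable", "variance_A", "variance_B", "levene_F", "levene_p"]]
      .to_string(index=False))

d = res["delta_cwd"]
tree = gen_tree(14, 1)
fit = pgls(tree, dict(zip(d.species, d.delta_cwd_mm)),
           [dict(zip(d.species, d.mean_latitude))])
print(f"PGLS slope of delta-CWD on latitude: {fit.beta[1]:.1f} mm/degree "
      f"(p = {fit.p[1]:.4f})")
```

Output:

```
variable  variance_A  variance_B  levene_F  levene_p
 tmean_c    3.105978    4.579299  0.314485  0.579742
  ppt_mm   11.875885   12.072413  0.010210  0.920291
  cwd_mm   36.500475 2198.960027 20.135870  0.000130
PGLS slope of delta-CWD on latitude: 15.3 mm/degree (p = 0.0058)
```

Column `variance_A` is the across-species variance of the specimen-specific
(lived) niche, `variance_B` that of the fixed clade-seasonal niche. Under
full tracking the lived CWD niche is ~60× less variable than the
clade-seasonal one (36.5 vs 2199 mm², Levene *F* = 20.1, *p* = 1.3 × 10⁻⁴):
species at different latitudes shift their growing seasons so that they
live through nearly the same cumulative water deficit. The positive PGLS
slope (+15.3 mm per degree latitude) shows how: northern species extend
into drier months (ΔCWD > 0) while southern species retreat into cooler
ones (ΔCWD < 0). Temperature and precipitation show no such compression,
as expected — all windows sample the same wet season.

There is also a thin CLI over the same pipeline:

```bash
nichetrack --config config.yml --seed 1 --out-dir out all
```

with subcommands `simulate`, `qc`, `phenology`, `windows`, `stats`,
`evolve`, `soil`, `all`; the YAML config holds either an `inputs:` section
(specimens/climate CSVs, Newick tree, ESRI ASCII soil grid, field-soil CSV
— schemas in `nichetrack.io_formats`) or a `scenario:` section for
synthetic data.

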