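# phylodecline

Phylogenetic comparative analysis of the correlates of population decline.

Conservation status assessments assign species a population **trend**
(increasing, stable, decreasing, unknown). Given a phylogeny, species range
maps on a gridded world, climate layers, and body sizes, this package asks:
which phenotypic, geographic and climatic factors are associated with a
species being in decline, once phylogenetic non-independence is accounted
for? It is written for comparative biologists and conservation macroecologists
who want the full workflow — predictor construction, environmental
prevalence, phylogenetically informed imputation of missing data, a Bayesian
phylogenetic binary mixed model, exhaustive DIC model selection, and
validation across alternative tree topologies — as tested, scriptable Python
rather than a one-off analysis script.

Because the real inputs (IUCN-style range polygons, global climate rasters, a
published mega-phylogeny) are external downloads, the package includes a
synthetic-world generator that emulates their statistical structure with
known ground truth. Every claim in the test suite is a checked property of
the method (oracle equivalence, closed-form limits, parameter recovery), not
a reproduction of published numbers.

## The model

For species *i* with binary trend *y<sub>i</sub>* (decline = 1):

```
l_i = x_i' β + u_i + e_i,   e_i ~ N(0, 1)          (residual variance fixed)
y_i = 1{l_i > 0}
u   ~ N(0, σ²_p A)
```

where **A** is the tree's variance–covariance matrix scaled to unit diagonal
and *x* holds log body size, log range size, |latitudinal midpoint|, range
means of annual mean temperature (AMT), temperature annual range (TAR) and
climate moisture index (CMI), and the environmental prevalences of AMT and
CMI (the fraction of land cells sharing the species' climate). The model is
sampled by a fully conjugate Gibbs scheme (truncated-normal data
augmentation, parameter-expanded variance, an exact scale-group move); a
coefficient is significant when its 95% credible interval excludes zero.
All 2⁸ = 256 predictor subsets are compared by DIC, models with ΔDIC < 2 form
the candidate set, and the selected model is refitted across a topology
ensemble with pooled posterior draws. See `docs/methods.md` for the complete
account.

## Worked example

```python
from phylodecline import (
    WorldConfig, generate_dataset, PhyloProbitMM,
)
from phylodecline.geo import PREDICTOR_ORDER, build_predictors, filter_trends

ds = generate_dataset(WorldConfig(n_tips=300, grid_shape=(24, 24), seed=7))
table, _ = filter_trends(ds.table)          # keep stable/decreasing species
design = build_predictors(ds.table).data.loc[table.index]
design["decline"] = table["decline"]

model = PhyloProbitMM.from_dataframe(
    design, "decline", PREDICTOR_ORDER, ds.tree
)
result = model.fit(iterations=50_000, burnin=10_000, thin=20, seed=1)
print(result.summary().round(2))
```

```
                post_mean  post_sd  ci_low  ci_high      ess  significant
intercept            0.68     0.36   -0.05     1.41  1967.87        False
log_body_size        0.14     0.34   -0.53     0.80  1857.67        False
log_range_size      -1.03     0.22   -1.51    -0.68   913.39         True
abs_lat_mid          0.72     1.76   -2.66     4.22  1588.87        False
amt_mean             1.20     0.83   -0.39     2.84  1491.03        False
tar_mean            -0.90     1.19   -3.26     1.49  1678.05        False
cmi_mean             0.18     0.16   -0.12     0.51  1884.09        False
prev_amt            -0.05     0.24   -0.52     0.44  1770.37        False
prev_cmi             0.00     0.15   -0.31     0.30  1767.33        False
sigma2_p             0.61     1.04    0.01     3.02   545.97        False
```

This dataset was generated with β = (0.5, 0, −0.8, −0.4, 0.5, −0.5, 0.2, 0, 0)
and σ²_p = 1, and 185 of the 300 species survive the trend filter. The fit
recovers the dominant range-size effect (posterior mean −1.03, 95% CI
excluding zero — smaller ranges mean higher decline probability) with a
phylogenetic variance credible interval covering 1; the weaker climate
effects are not separable at this sample size because latitude, temperature
and seasonality are strongly collinear by construction, exactly the behavior
the model-selection stage is for. Coefficients are on the probit scale per
unit of the transformed predictor.

The same analysis end to end, from a shell:

```
phylodecline run-all --seed 42 --out-dir run42
```

writes the tree, climate grids, species table, prevalence profiles, imputed
table with leave-one-out validation, threat-category association, the
256-model DIC table, the topology-ensemble coefficient summary, and the
descriptive trend reports into `run42/` (every figure-level result as
machine-readable TSV/JSON). Rerunning with the same seed is byte-identical;
completed stages are cached.

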