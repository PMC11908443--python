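# allomkit

Height–diameter allometry and aboveground-biomass uncertainty for tropical
forest inventories.

Tropical biomass estimates hinge on tree height, yet height is rarely
measured for every stem. The usual workaround — predicting height from
diameter with a regional or pantropical equation — imports that equation's
bias into every downstream biomass and carbon number. `allomkit` implements
the complete workflow a forest ecologist needs to quantify that trade-off
on their own inventory:

1. **Local height–diameter models.** Ten candidate forms H = f(D) + ε from
   the forest-science literature (log-scale quadratic, Michaelis–Menten,
   Weibull, two- and three-parameter exponentials, Gompertz, power,
   modified exponential, logistic, log-linear), fitted by unweighted
   nonlinear least squares on the natural height scale and ranked by
   adjusted pseudo-R² (descending), then RSE, then AIC
   (AIC = 2k − 2 lnL with Gaussian likelihood, k counting the error
   variance).
2. **Validation diagnostics.** Graybill's simultaneous F test that the
   observed-vs-predicted regression has (intercept, slope) = (0, 1); a
   Theil-style exact partition of Σ(obs − pred)² into bias, consistency
   and residual lack-of-fit; linear mixed models with a species random
   intercept (marginal/conditional R²); and phylogenetic GLS of
   per-species (Hmax, Dmax) maxima under Brownian covariance with an
   optional Pagel's λ.
3. **Published height models.** The regional Guyana-shield Weibull
   H = 42.845·(1 − exp(−0.0433·D^0.9372)) and the pantropical climate
   model H = exp(0.893 − E + 0.760·lnD − 0.0340·ln²D), where E is an
   environmental-stress index.
4. **Biomass propagation.** Six published allometric biomass equations
   (with/without height, for terra-firme, várzea and pantropical use),
   each carrying its printed log-bias correction factor CF = exp(RSE²/2);
   plot-level Mg ha⁻¹ with size-stratified expansion factors and
   cumulative size-class curves.
5. **Error decomposition.** Total, systematic and random error
   (TE = RMSE, SE = mean error, RE = SD of errors; TE² = SE² +
   ((n−1)/n)·RE²) and their per-tree proportional analogues
   CVTE/CVSE/CVRE, stratified by DBH class.
6. **Carbon accounting.** ΔC = area × mean AGB × correction × carbon
   fraction, in Pg C and (optionally) USD.

A synthetic stand generator (`allomkit.synthetic_data`) emulates the
statistical structure of contrasting Amazonian forest inventories — two
presets, `terra_firme_like` and `varzea_like`, wire published best-fit
height laws, realistic diameter distributions, dominance-skewed species
pools and nested-subplot sampling into reproducible test beds with known
ground truth.

## Worked example

```python
import allomkit as ak

# generate a várzea-like stand and recover its height-diameter law
stand, truth = ak.generate_stand(ak.varzea_like(seed=42))
fits = ak.fit_all_models(stand)
for rank, fit in enumerate(ak.rank_models(fits)[:3], start=1):
    print(f"{rank}. {fit.name:<18} RSE={fit.rse:.3f} m  "
          f"adj pseudo-R2={fit.adj_pseudo_r2:.3f}  AIC={fit.aic:.1f}")

# how would the regional model have done here?
best = ak.rank_models(fits)[0]
table = ak.compare_height_models(stand, [best], [ak.GUYANA_SHIELD],
                                 breakpoints=(30.0,))
rows = table[table.size_class == "all"].set_index("model")
for m in (best.name, "guyana_shield"):
    print(f"{m:<18} TE={rows.loc[m,'te']:.2f} m  SE={rows.loc[m,'se']:+.2f} m")

# carbon implication of a +22% biomass revision over the Guyana shield
res = ak.carbon_accounting(mean_agb=299.0, area_ha=148e6, correction=0.22,
                           carbon_fraction=0.485, price_usd_per_mg_c=7.13)
print(f"carbon gain: {res['delta_c_pg']:.2f} Pg C "
      f"(US$ {res['value_usd']/1e9:.1f} billion)")
```

Output:

```
1. michaelis_menten   RSE=4.281 m  adj pseudo-R2=0.634  AIC=4635.7
2. quadratic          RSE=4.284 m  adj pseudo-R2=0.634  AIC=4637.7
3. weibull            RSE=4.286 m  adj pseudo-R2=0.633  AIC=4638.2
michaelis_menten   TE=4.28 m  SE=+0.01 m
guyana_shield      TE=7.94 m  SE=+5.85 m
carbon gain: 4.72 Pg C (US$ 33.7 billion)
```

Reading it: the asymptotic models are statistically tied at the top (the
stand was generated from a quadratic law with 4.2 m of height noise, and
over 5–140 cm the leading forms are near-indistinguishable — the fitted
local curve is unbiased, SE ≈ 0). Applying the regional Guyana-shield
equation to this short-statured floodplain stand instead would
overestimate heights by 5.9 m on average and nearly double the total
error. Revising the Guyana-shield biomass stock upward by 22% corresponds
to 4.72 Pg of carbon, about US$34 billion at $7.13 per Mg C.

The same pipeline is scriptable from the shell:

```
allomkit simulate --preset varzea_like --seed 42 --out run/
allomkit fit --inventory run/inventory.csv --out run/
allomkit compare --inventory run/inventory.csv --eq-with-height varzea_H \
    --eq-without-height varzea_D --wood-density run/wood_density.csv --out run/
allomkit carbon --area-ha 148e6 --mean-agb 299 --correction 0.22 --price 7.13
```

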