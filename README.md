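# altinull

Null-model analysis of invertebrate species distributions and species
richness across altitudinal lake gradients.

## The problem

Mountain-lake surveys ask whether species assemblages track the
environmental gradient that altitude imposes (temperature, ice cover,
chemistry, catchment vegetation) or mostly reflect the spatial layout of
the habitat itself — hard domain boundaries and lake density peaking at
mid elevations, both of which generate unimodal richness patterns with no
environmental filtering at all (the mid-domain effect). Passively
dispersing, broadly tolerant taxa such as free-living nematodes can serve
as an empirical null against which environmentally filtered groups
(oligochaetes, chironomids, other insects) are compared.

`altinull` packages the statistical chain this comparison needs, for
anyone with a site table (lakes × altitude + environmental variables) and
one community matrix (sites × species counts) per taxonomic group:

1. **Occupancy filter** — analyses use species present in ≥ 4 lakes.
2. **Altitudinal bias tests** — per species, a two-tailed Welch *t*-test
   comparing altitudes of occupied vs unoccupied lakes.
3. **Range-given-occupancy null** — for a species in *k* lakes, the null
   altitudinal range distribution from drawing *k* survey altitudes
   without replacement (9,999 randomizations, or exact enumeration);
   species below the lower 95% envelope bound are *narrow-ranging*.
4. **Group contrasts** — two-sided Fisher exact tests on the proportions
   of biased / narrow-ranging species between groups.
5. **Constrained ordination** — Hellinger-transformed RDA of the
   community on environmental predictors, with permutation pseudo-*F*
   tests, Ezekiel adjusted R² = 1 − (1 − R²)(n − 1)/(n − m − 1), forward
   selection under the double-stopping criterion (partial permutation
   *p* < α **and** cumulative adjusted R² ≤ the global model's), and
   vector fitting of altitude onto the ordination.
6. **Richness–altitude models** — linear vs quadratic OLS compared by
   small-sample AICc and a deviance χ² test, with peak-altitude
   estimation when a concave quadratic wins.

A synthetic metacommunity generator (`altinull.synthetic`) produces lake
districts and communities of three archetypes — environment-filtered
(Gaussian niche), range-cohesive (random altitudinal window; the
mid-domain construction) and neutral (random occupancy) — with full ground
truth, so every stage is testable without field data.

## Worked example

```python
import numpy as np
import altinull as an

sites = an.generate_lakes(an.DistrictConfig(seed=11))   # 82 lakes, 1620-2990 m
rng = np.random.default_rng(12)
cm, truth = an.generate_species(
    [an.SpeciesArchetype("filtered", 12, occupancy=(6, 20), niche_sigma=200.0),
     an.SpeciesArchetype("range_cohesive", 12, range_width=(300.0, 900.0)),
     an.SpeciesArchetype("neutral", 12, occupancy=(6, 20))],
    sites, seed=rng, group="demo")

kept, report = an.filter_by_occupancy(cm, min_sites=4)
bias = an.bias_test_table(kept, sites)
summ = an.species_altitude_summary(kept, sites)
calls = an.classify_narrow_ranging(summ, sites.altitude.to_numpy(),
                                   n_rep=9999, seed=rng)

Y = an.hellinger(kept)
trace = an.forward_select(Y, sites.env, n_perm=999, seed=rng)
fit = an.rda(Y, sites.env[trace.selected].to_numpy())
vf = an.fit_vector(fit.site_scores[:, :2], sites.altitude.to_numpy(),
                   n_perm=999, seed=rng)

alt = sites.altitude.to_numpy()
r = an.species_richness(kept)
pair = an.compare_models(an.fit_polynomial_richness(r, alt, 1),
                         an.fit_polynomial_richness(r, alt, 2),
                         altitude_range=(alt.min(), alt.max()))
```

Output for this seed:

```
retained 36/36 species present in >= 4 lakes
biased species: 20/36
narrow-ranging species: 22/36
group mean-altitude span: 770 m
forward selection: ['temperature', 'calcium', 'ph'] (global adjR2 0.158, p 0.0010)
altitude vector fit: r2 0.754, p 0.0010
richness model: quadratic (delta AICc -51.79, deviance p 0.0000), peak 2206 m
```

Reading it: 20 of 36 species occupy lakes at altitudes biased away from
random (the filtered and cohesive archetypes), 22 are narrower-ranging
than their occupancy predicts, forward selection keeps three environmental
variables explaining ~16% of community variance (adjusted), altitude
projects strongly onto the ordination, and richness is hump-shaped with
its fitted maximum at 2,206 m — near the domain center, as the mid-domain
construction predicts.

The same chain is available from the shell:

```sh
altinull simulate --seed 11 --out-dir district/
altinull richness district/sites.csv district/community_cohesive.csv \
    --group cohesive --out richness.csv
altinull run-all --config run.yaml
```

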