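# phenosynch

Quantitative flowering-phenology analysis for weekly census data.

Field studies of flowering phenology often record, for each individual plant
(or flowering shoot), the first and last census dates on which it was seen in
flower over a season of weekly visits. `phenosynch` turns such
individual-level records into the species- and community-level statistics
ecologists use to compare life forms (trees vs. perennial herbs vs. annuals):

* **Species-level variables** — total flowering length (TFL), mean and
  variance of individual flowering length (MFL, VFL), skewness/kurtosis of
  the length distribution, onset-date variance, and Morisita's aggregation
  index *Iδ* = *q* Σ *nᵢ*(*nᵢ*−1) / (*N*(*N*−1)) over census-date bins —
  larger *Iδ* means individuals flower more synchronously.
* **Community-wide synchrony** — the Loreau–de Mazancourt index
  φ = Var_t[x_T(t)] / (Σᵢ SD_t[xᵢ(t)])², where xᵢ(t) counts individuals of
  species *i* in flower at census *t*; φ = 1 for perfectly synchronous
  species, ≈ 1/S for S independent ones.  Onset-date skewness is tested with
  D'Agostino's K², and group differences summarized by 1000-replicate
  species bootstraps.
* **Sample-size standardization** — bootstrap rarefaction–extrapolation
  curves per species and variable, a four-model (linear / quadratic /
  logarithmic / logistic) fit selected by BIC on pooled max-rescaled curves,
  and evaluation at standardized sample sizes (5, 7, 12, 18, 22
  individuals).
* **Life-form comparisons** — Student's *t*, Wilcoxon rank-sum, or the
  Fligner–Policello robust rank-order test chosen from the samples'
  normality and variance homogeneity, with Holm correction; gamma GLMMs
  (log link) and Gaussian LMMs with a genus random intercept for
  year/sample-size effects.
* **Phylogenetic signal** — Felsenstein's independent contrasts, Blomberg's
  *K* (K = 1 under Brownian motion), and a tip-shuffling permutation test on
  a user-supplied newick tree.
* **Synthetic data** — a generator of weekly-census record sets with known
  life-form-specific synchrony and duration parameters, plus Yule trees and
  Brownian traits, so every stage can be exercised against ground truth.

## Worked example

```python
import phenosynch as pn

# a synthetic two-year community under the default study conditions
ds, manifest = pn.simulate_records(seed=1)
ds = pn.filter_species(ds, min_flowering_days=2, min_individuals=5)

summaries = pn.summarize_dataset(ds)
merged = summaries.merge(ds.meta[["species", "life_form"]], on="species")
print(merged.groupby("life_form")[["VFL", "morisita_idelta"]]
      .median().round(2))
```

prints

```
              VFL  morisita_idelta
life_form
annual     101.59             2.73
perennial   49.85             3.65
tree        13.86             6.68
```

i.e. the simulated trees flower with far smaller duration variance (VFL)
and much higher intraspecific synchrony (*Iδ*) than the simulated annuals —
the community structure the generator's defaults encode.  Community-wide
synchrony for one group-year:

```python
M = pn.build_matrix(ds, life_form="tree", year=2016)
print(round(pn.phi(M), 3))            # 0.125
print(pn.phi_ci(M, B=1000, seed=1))   # (0.104, 0.427, 1000)
```

The full workflow (filter → stats → rarefy → standardize → compare →
synchrony → signal) runs from one config:

```bash
phenosynch run --config run.yaml
```

or programmatically via `pn.run_all(pn.RunConfig(...))`.

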