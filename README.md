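# robustscreen

Quantifying **phenotypic robustness** — how stable a measured function of a
microbial strain is under perturbation — during strain-characterisation
screenings.

Strain selection for bioproduction is usually driven by performance (growth
rate, titres, yields), while the *stability* of that performance across media,
strains, time, and the cells of a population is rarely quantified.
`robustscreen` implements a Fano-factor-based robustness statistic and the
surrounding analysis pipeline for screening data: growth-curve feature
extraction, fermentation yield computation, fluorescent-biosensor
normalisation, and a synthetic screening generator with full ground truth so
the whole pipeline can be verified end to end.

## The statistic

For a function *f* (e.g. specific growth rate, a product yield, or a biosensor
ratio) measured within a group of observations,

```
R = −(σ² / x̄) · (1 / m)
```

where σ² and x̄ are the within-group variance and mean (σ²/x̄ is the Fano
factor) and *m* is the grand mean of the function over all groups, which makes
R dimensionless and scale-invariant. R is 0 for a perfectly stable function
and decreases as dispersion grows; it is always relative to the systems and
conditions analysed, never absolute. Four groupings answer the standard
questions:

| mode | one R per | σ², x̄ run over | question |
|------|-----------|-----------------|----------|
| R(c) | system (strain) | conditions (media), replicate-averaged | how condition-stable is a strain? |
| R(s) | condition | systems, replicate-averaged | how similarly do strains behave in a medium? |
| R(t) | system × condition × replicate | timepoints | how stable is a signal over a screening? |
| R(p) | system × condition × timepoint | single cells | how homogeneous is the population? |

Low R(p) is an indirect, quantitative readout of population heterogeneity
(subpopulation structure). Any other grouping can be expressed with
`GroupingScheme` / `robustness_generic`. Conventions: sample (n−1) variance by
default; zero-variance groups score exactly 0 — including an all-zero group
such as "no strain grew in this medium", which is maximally *stable* even
though performance is nil; zero mean with nonzero variance is undefined and
reported as missing.

## Worked example

Simulate a screening of three strain archetypes (a sensitive lab strain, a
robust industrial strain, a heterogeneous industrial strain) across a control
medium and seven lignocellulosic-hydrolysate media, extract growth features,
and compute robustness across conditions:

```bash
robustscreen simulate --seed 7 --replicates 3 --out sim
robustscreen features sim/measurements.csv --out features.csv
robustscreen robustness features.csv --mode c --mode s \
    --function mu_max --function lag_h --out rob
```

`rob/robustness_c.csv` then contains, for the maximum specific growth rate:

```
system  n     xbar         R
 IND-H  8 0.316288 -0.024225
 IND-R  8 0.335580 -0.007837
 LAB-1  8 0.290411 -0.058679
```

Each row is one strain: `n` media entered the group, `xbar` is its mean
growth rate (1/h) across media, and `R` its robustness across conditions.
IND-R — generated with the lowest inhibitor sensitivity — has both the
highest mean rate and the R closest to 0 (most stable across media), while
the lab strain LAB-1 is the least condition-robust, exactly the ordering the
generator injected. The same library calls are available in Python
(`robustness_across_conditions(table, "mu_max")`, etc.), and
`robustscreen report` pairs each group's mean performance with its R for
performance-vs-robustness trade-off analysis.

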