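# famclust

Sex-specific familial aggregation of cancer from registry-style data.

`famclust` is for epidemiologists and biostatisticians who want to ask, at
population scale, whether cancers cluster in families — and whether that
clustering differs between men and women — when no pedigree is available.
Families are inferred from shared **birth municipality + surname + sex (MNS)
combinations**, a practical proxy for same-sex family lines in populations
where surnames follow the paternal line. The package provides the full
pipeline as an importable library: a synthetic registry generator with known
ground truth, eligibility filtering and MNS tabulation, expected-count and
SCIR computation, a hierarchical Bayesian risk mixture fitted by MCMC, and
posterior summaries including male–female comparisons and cluster flags. A
thin `famclust` command runs the same stages from the shell.

## The statistic and the model

For an inferred family *j* and a cancer site, the observed count
*O<sub>j</sub>* is compared with an expected count

  *E<sub>j</sub>* = Σ<sub>members i</sub> Λ(site, sex, cohort<sub>i</sub>, a<sub>i</sub>),

where Λ is the reference cumulative incidence from birth to the member's
attained age *a<sub>i</sub>* = min(80, follow-up end − birth year). The ratio
**SCIR = O/E** is a cumulative analogue of the standardised incidence ratio,
used because registry extracts of this kind lack the death/emigration dates
needed for person-years.

Raw SCIRs from small families are wildly unstable, so they are smoothed with
a hierarchical two-component Poisson–gamma mixture, fitted separately per
site and sex:

    O_j | θ_j      ~ Poisson(E_j · θ_j)
    θ_j | z_j = k  ~ Gamma(a_k, b_k),   k ∈ {low, high}
    z_j            ~ Bernoulli(π),      π ~ Beta(1, 1)
    a_k/b_k        ~ Gamma(1, 0.01),    b_k ~ log-uniform,  mean_high > mean_low

Posterior quantities reported per analysis: the **risk-coefficient group
proportion** (share of families using the high coefficient), **SCIR
averages** overall and in the high group, their ratio (**SCIR ratio**),
male–female ratios of these with 95% credible intervals, per-family
**P(high)** and **normalised SCIRs** (SD units above the analysis-set median
of posterior medians), and the subset of sexless municipality+surname (MN)
families with **concordant cancer** in both sexes.

## Worked example

Generate 2,000 family-level records from the count model (10% of families
carry a five-fold risk) and recover the generating parameters
(`examples/03_fit_risk_mixture.py`):

```python
import famclust as fc
from famclust.mixture import MixtureModelSpec

records = fc.simulate_scir_records(2000, 0.10, 1.0, 5.0, seed=7)
draws = fc.fit(records, MixtureModelSpec(seed=11))
means = draws.component_means().mean(axis=0)
print(draws.pi.mean(), means)
```

prints

```
posterior mean of pi (truth 0.10):        0.0845
posterior mean, low component (truth 1):  1.055
posterior mean, high component (truth 5): 4.961
mean P(high) among truly high groups: 0.519
mean P(high) among truly low groups:  0.036
```

The mixture weight and both component means land on the generating values;
truly high-risk families receive a much larger posterior probability of the
high coefficient than background families, while shrinkage keeps the many
small noisy families from being called clusters. The other scripts in
`examples/` walk through registry simulation, filtering and SCIR tables,
planted-cluster detection (`P(high) = 1.0000` for a family with six observed
cases against 0.04 expected), and the end-to-end male–female comparison.

The same pipeline is available from the shell:

```bash
famclust init-config cfg.yaml
famclust all --config cfg.yaml --out run1 --seed 11
```

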