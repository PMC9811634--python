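# reefcontests

Statistical analysis of **agonistic encounters between coral-reef fish
species** around a rapid resource-loss event (mass coral mortality), built
for behavioural ecologists testing competitor-recognition theory on field
encounter data.

When two fish come within 1 m of each other, an observer records how close
they approach (four 25 cm proximity bins), whether the encounter stays
passive, is resolved by visual **signalling**, or escalates to a **chase**
(with chase distance in metres as a proxy for energy invested). Contest
theory predicts that conspecifics — who share signals and fighting ability —
should (1) approach each other more closely, (2) resolve contests by
signalling more often, (3) show less variable attack intensity, and (4) that
these behaviours should scale with phylogenetic distance and body-size
difference between heterospecifics. This package implements a reusable,
fully seeded version of the analysis for each prediction:

1. **Proximity** — per-individual mean proximity categories (removing
   pseudoreplication from repeated encounters) compared between classes with
   a permutation Mann–Whitney U test: the mid-rank sum *T* of one group is
   standardized as *Z* = (*T* − E[*T*]) / sd[*T*] under random relabelling,
   with a Monte-Carlo reference distribution and tie-corrected variance.
2. **Signalling** — the signal : chase split of aggressive encounters is
   compared with Pearson's *X*² under a permutation null; pseudoreplication
   is handled by bootstrapping one encounter per focal individual 1000 times
   and reporting mean statistics, mean *p* and 95% percentile intervals.
3. **Chase variability** — dispersion of capped (≥10 m grouped) chase
   distances is measured by the coefficient of variation CV = sd/mean and
   compared between groups with the signed likelihood-ratio test for a
   common CV, plus its small-sample **modified** version
   Λ_M = (k−1)·Λ / E[Λ_sim] referred to χ²(k−1).
4. **Comparative models** — per species pair: OLS of mean proximity and
   chase CV, and a binomial GLM of aggregated (signal, chase) counts with
   McFadden's *R*² = 1 − ℓ̂/ℓ̂₀, on patristic distance (path length in the
   phylogeny) and |body length difference|.

A first-class synthetic generator (`reefcontests.simulate`) produces
encounter tables, trait tables and Yule trees with known ground truth, so
every stage can be calibrated and tested without field data.

## Worked example

```python
from reefcontests import simulate
from reefcontests.encounters import individual_mean_proximity
from reefcontests.resampling import mwu_permutation_test

records, traits, tree = simulate.generate_dataset(simulate.field_scenario(seed=1))
means = individual_mean_proximity(records)
sub = means[means["period"] == "before"]
res = mwu_permutation_test(
    sub.loc[sub["class"] == "heterospecific", "mean_proximity"],
    sub.loc[sub["class"] == "conspecific", "mean_proximity"],
    n_resamples=10_000, seed=7,
)
print(res.statistic, res.p_value)
```

Running `python examples/02_proximity_rank_test.py` prints:

```
before: conspecific mean 1.92 vs heterospecific 2.89  ->  Z = 19.786, p = 0.0001
 after: conspecific mean 1.92 vs heterospecific 2.34  ->  Z = 7.707, p = 0.0001
```

Mean proximity category 1.92 vs 2.89 means conspecifics typically interact
within ~25–50 cm while heterospecifics stay further apart; the positive *Z*
with the smallest attainable Monte-Carlo *p* (1/10001 rounded) says the
difference survives relabelling in essentially no permutation. The other
`examples/` scripts walk through signalling bootstrap contrasts, CV equality
(e.g. before: CV 0.76 conspecific vs 1.20 heterospecific, MSLR = 8.8,
p = 0.003), the comparative regressions and the full pipeline.

A thin CLI wraps the same code:

```bash
reefcontests simulate --scenario field --outdir data/
reefcontests run --scenario field --seed 1 --outdir out/
reefcontests report out/report.json
```

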