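"""Do phylogenetic distance and body-size difference predict contest behaviour?

Builds one row per heterospecific species pair (mean proximity, signal/chase
counts, chase CV), joins patristic distances from the phylogeny and absolute
body-length differences, and fits the three models: OLS for proximity and
chase CV, a binomial GLM (with McFadden's pseudo-R²) for signalling.
"""

from reefcontests import simulate
from reefcontests.comparative import (
    build_pair_observations,
    fit_binomial_glm,
    fit_linear_model,
    patristic_distances,
)

records, traits, tree = simulate.generate_dataset(simulate.field_scenario(seed=1))
distances = patristic_distances(tree)
pairs = build_pair_observations(records, distances=distances, traits=traits, min_chases=5)
print(f"{len(pairs)} heterospecific pairs "
      f"({pairs['chase_cv'].notna().sum()} with a defined chase CV)\n")

prox = fit_linear_model(pairs, "mean_proximity")
print(f"proximity : beta_phylo = {prox.coefficients['phylo_distance']:+.3f}, "
      f"beta_size = {prox.coefficients['size_difference_cm']:+.3f}, "
      f"adj R2 = {prox.adjusted_r2:.3f}, p = {prox.model_p:.3f}, n = {prox.n}")

sig = fit_binomial_glm(pairs)
print(f"signalling: beta_phylo = {sig.coefficients['phylo_distance']:+.3f}, "
      f"beta_size = {sig.coefficients['size_difference_cm']:+.3f}, "
      f"McFadden R2 = {sig.mcfadden_r2:.3f}, n = {sig.n}")

print("\nThe generator plants no phylogeny or body-size effect, so both models")
print("should explain essentially nothing (R2 near zero) - the same outcome as")
print("observed in real butterflyfish communities.")
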