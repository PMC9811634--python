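"""Comparative regressions: do phylogeny and body size predict contest behaviour?

Builds one response row per heterospecific species pair (mean approach
proximity, signalling/chase counts, chase-distance CV) joined to two
predictors: the patristic distance between the species in a phylogeny (sum
of branch lengths along the connecting path) and the absolute difference in
maximum body length (cm). Three models are fitted: ordinary least squares
for mean proximity and for chase CV, and a binomial (logit) GLM on
aggregated (signal, chase) counts for the signalling proportion, whose
predictive ability is summarised by McFadden's pseudo-R²
(1 − llf/llnull).  Conspecific pairs are excluded so the phylogenetic
predictor is not dominated by zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .encounters import add_pair_columns, cap_chase_distance
from .cv import coefficient_of_variation

__all__ = [
    "RegressionResult",
    "patristic_distances",
    "read_traits",
    "body_size_difference",
    "build_pair_observations",
    "fit_linear_model",
    "fit_binomial_glm",
]

PREDICTORS = ("phylo_distance", "size_difference_cm")


@dataclass(frozen=True)
class RegressionResult:
    """Fitted-model summary shared by the OLS and binomial GLM paths.

    ``adjusted_r2`` is reported raw (it may be negative) for linear models
    and is None for the GLM; ``mcfadden_r2`` is the reverse. ``model_p`` is
    the overall F-test p for OLS and the likelihood-ratio p against the
    intercept-only model for the GLM.
    """

    coefficients: dict
    intercept: float
    model_p: float
    n: int
    adjusted_r2: float | None = None
    mcfadden_r2: float | None = None
    warnings: tuple[str, ...] = ()


def patristic_distances(tree, species=None, default_branch_length=None) -> pd.DataFrame:
    """Pairwise patristic distances between leaves of a Newick tree.

    The patristic distance between two species is the sum of branch lengths
    along the unique path connecting their leaves; d(a, a) = 0.

    Parameters
    ----------
    tree
        Newick text, or a path to a Newick file.
    species
        Labels to include (default: all leaves). Missing labels raise a
        ``KeyError`` naming them.
    default_branch_length
        Substitute for edges without a length; by default such edges are an
        error.

    Returns
    -------
    Symmetric non-negative DataFrame indexed by species label.
    """
    text = tree
    if isinstance(tree, str) and "(" not in tree:
        with open(tree, encoding="utf-8") as fh:
            text = fh.read()
    t = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    leaf_names = [lf.taxon.label for lf in t.leaf_node_iter()]
    if species is None:
        species = leaf_names
    missing = sorted(set(species) - set(leaf_names))
    if missing:
        raise KeyError(f"species missing from tree: {missing}")

    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            if default_branch_length is None:
                raise ValueError(
                    "tree has edges without branch lengths and no default_branch_length was given"
                )
            edge.length = default_branch_length

    pdm = t.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in t.taxon_namespace}
    species = list(species)
    mat = np.zeros((len(species), len(species)))
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if j > i:
                mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
    return pd.DataFrame(mat, index=species, columns=species)


def read_traits(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a species trait table with columns ``species, max_length_cm``."""
    df = pd.read_csv(path, sep=delimiter)
    if not {"species", "max_length_cm"}.issubset(df.columns):
        raise ValueError("trait table must have columns species, max_length_cm")
    if df["species"].duplicated().any():
        raise ValueError("trait table has duplicate species rows")
    if (df["max_length_cm"] <= 0).any():
        raise ValueError("max_length_cm must be positive")
    return df


def body_size_difference(traits: pd.DataFrame, a: str, b: str) -> float:
    """Absolute difference in maximum body length (cm) between two species."""
    table = traits.set_index("species")["max_length_cm"]
    for s in (a, b):
        if s not in table.index:
            raise KeyError(f"species {s!r} missing from trait table")
    return float(abs(table[a] - table[b]))


def build_pair_observations(
    records: pd.DataFrame,
    distances: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    min_chases: int = 5,
    cap: float = 10.0,
) -> pd.DataFrame:
    """One response row per heterospecific species pair.

    Responses: ``mean_proximity`` over all the pair's encounters;
    ``n_signal``/``n_chase`` over its aggressive encounters; ``chase_cv``
    (CV of capped chase distances), present only when the pair has at least
    ``min_chases`` chases. Rows lacking a response simply carry NaN there, so
    the three downstream models can have different n.

    Predictors ``phylo_distance`` and ``size_difference_cm`` are joined when
    a distance table / trait table is supplied.
    """
    df = add_pair_columns(records)
    df = df[df["pair_class"] == "heterospecific"]
    rows = []
    for (a, b), grp in df.groupby(["species_a", "species_b"], sort=True):
        n_signal = int((grp["outcome"] == "signal").sum())
        n_chase = int((grp["outcome"] == "chase").sum())
        chases = grp.loc[grp["outcome"] == "chase", "chase_distance_m"].to_numpy()
        cv = np.nan
        if n_chase >= max(min_chases, 2):
            cv = coefficient_of_variation(cap_chase_distance(chases, cap))
        row = {
            "species_a": a,
            "species_b": b,
            "n_encounters": len(grp),
            "mean_proximity": float(grp["proximity_cat"].mean()),
            "n_signal": n_signal,
            "n_chase": n_chase,
            "chase_cv": cv,
        }
        if distances is not None:
            row["phylo_distance"] = float(distances.loc[a, b])
        if traits is not None:
            row["size_difference_cm"] = body_size_difference(traits, a, b)
        rows.append(row)
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame, predictors) -> pd.DataFrame:
    X = df[list(predictors)].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_linear_model(
    df: pd.DataFrame, response: str, predictors=PREDICTORS
) -> RegressionResult:
    """Ordinary least squares of a pair-level response on the predictors.

    Reports coefficients, the overall F-test p and the adjusted R² (raw;
    negative values mean the predictors explain less than chance).
    """
    data = df.dropna(subset=[response, *predictors])
    if len(data) < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} complete rows, got {len(data)}"
        )
    X = _design(data, predictors)
    fit = sm.OLS(data[response].astype(float), X).fit()
    warns = []
    if np.linalg.cond(np.asarray(X)) > 1e8:
        warns.append("predictors nearly collinear (condition number > 1e8)")
    coefs = {p: float(fit.params[p]) for p in predictors}
    return RegressionResult(
        coefficients=coefs,
        intercept=float(fit.params["const"]),
        model_p=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0,
        n=int(fit.nobs),
        adjusted_r2=float(fit.rsquared_adj) if np.isfinite(fit.rsquared_adj) else 0.0,
        warnings=tuple(warns),
    )


def fit_binomial_glm(df: pd.DataFrame, predictors=PREDICTORS) -> RegressionResult:
    """Binomial (logit) GLM of aggregated (n_signal, n_chase) counts per pair.

    Aggregated counts respect the proportional nature of the response.
    McFadden's R² = 1 − llf/llnull; exactly 0 for an intercept-only fit, and
    approaches 1 only as the model nears a saturated fit.  Complete
    separation is flagged rather than fatal.
    """
    data = df.dropna(subset=["n_signal", "n_chase", *predictors])
    data = data[(data["n_signal"] + data["n_chase"]) >= 1]
    if len(data) < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} rows with aggressive encounters"
        )
    y = data[["n_signal", "n_chase"]].astype(float)
    X = _design(data, predictors)
    warns = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        fit = model.fit()
    for w in caught:
        if "separation" in str(w.message).lower():
            warns.append("possible complete separation")
    if np.abs(fit.params.to_numpy()).max() > 50:
        warns.append("extreme coefficients; possible separation")

    llf = float(fit.llf)
    llnull = float(sm.GLM(y, X[["const"]], family=sm.families.Binomial()).fit().llf)
    mcfadden = 0.0 if llnull == 0 else 1.0 - llf / llnull
    mcfadden = float(min(max(mcfadden, 0.0), 1.0 - 1e-12))
    # LR test against intercept-only
    lr = max(2 * (llf - llnull), 0.0)
    from scipy import stats as _st

    model_p = float(_st.chi2.sf(lr, len(predictors)))
    coefs = {p: float(fit.params[p]) for p in predictors}
    return RegressionResult(
        coefficients=coefs,
        intercept=float(fit.params["const"]),
        model_p=model_p,
        n=int(len(data)),
        mcfadden_r2=mcfadden,
        warnings=tuple(warns),
    )
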