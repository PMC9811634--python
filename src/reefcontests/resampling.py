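"""Monte-Carlo permutation and bootstrap inference for encounter data.

Two permutation tests are provided, both with Monte-Carlo reference
distributions and the add-one convention (the observed permutation is
counted, so p >= 1/(n_resamples+1)):

* a permutation Mann-Whitney U (standardized linear rank statistic Z,
  mid-ranks with tie-corrected permutation variance) for comparing
  per-individual mean proximities between encounter classes, and
* a Pearson chi-squared permutation test on 2x2 signal/chase contingency
  tables for comparing signalling proportions between groups.

Pseudoreplication from repeated encounters on the same focal individual is
handled by :func:`bootstrap_one_per_individual`, which repeatedly draws one
encounter per individual and aggregates the inner test's statistic and
p-value across replicates (means and 95% percentile intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationTestResult",
    "BootstrapTestResult",
    "mwu_permutation_test",
    "pearson_chisq",
    "chisq_permutation_test",
    "bootstrap_one_per_individual",
    "signalling_proportion",
]


@dataclass(frozen=True)
class PermutationTestResult:
    """Observed statistic and Monte-Carlo permutation p-value.

    ``statistic`` is the standardized rank statistic Z for the rank test and
    the Pearson X² for the contingency test. ``degenerate`` marks inputs on
    which the statistic is undefined by margins (all values tied / a zero
    table margin); such tests return statistic 0 and p 1.
    """

    statistic: float
    p_value: float
    n_resamples: int
    seed: int
    alternative: str = "two-sided"
    degenerate: bool = False


@dataclass(frozen=True)
class BootstrapTestResult:
    """Aggregate of an inner test over one-encounter-per-individual replicates."""

    mean_statistic: float
    mean_p: float
    ci95_statistic: tuple[float, float]
    ci95_p: tuple[float, float]
    n_bootstrap: int
    seed: int
    per_replicate: np.ndarray = field(repr=False)  # shape (B, 2): statistic, p


def _rank_sum_z(ranks: np.ndarray, nx: int, take_sum: np.ndarray) -> np.ndarray:
    """Standardize rank sums of the first group under the permutation null.

    Mean and variance of a sum of ``nx`` ranks drawn without replacement from
    the pooled mid-ranks; ties enter through the rank variance itself.
    """
    n = ranks.size
    rbar = ranks.mean()
    # Var(S) = nx*ny/(n*(n-1)) * sum((r - rbar)^2)
    var = nx * (n - nx) / (n * (n - 1)) * np.sum((ranks - rbar) ** 2)
    if var <= 0:
        return np.zeros_like(take_sum, dtype=float)
    return (take_sum - nx * rbar) / np.sqrt(var)


def mwu_permutation_test(
    x,
    y,
    alternative: str = "two-sided",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation Mann-Whitney U test with a Monte-Carlo reference distribution.

    The statistic is the standardized linear rank statistic
    Z = (T - E[T]) / sd[T], where T is the mid-rank sum of ``x`` and the
    moments are taken over random relabellings of the pooled sample.  A
    positive Z means ``x`` has the larger ranks.  The p-value is the
    Monte-Carlo proportion of permutations at least as extreme as observed
    (|Z| for two-sided), with the observed permutation counted.

    Parameters
    ----------
    x, y
        The two samples (e.g. per-individual mean proximities of the two
        encounter classes); each must be non-empty.
    alternative
        "two-sided", "greater" (x larger) or "less".
    n_resamples
        Number of Monte-Carlo permutations (>= 999).
    seed
        Seed for the permutation stream; results are reproducible bit-for-bit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_resamples < 999:
        raise ValueError("n_resamples must be >= 999")

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks
    nx = x.size
    obs_z = float(_rank_sum_z(ranks, nx, np.asarray(ranks[:nx].sum())))

    if np.ptp(pooled) == 0:  # every value tied across both groups
        return PermutationTestResult(0.0, 1.0, n_resamples, seed, alternative, degenerate=True)

    rng = np.random.default_rng(seed)
    # vectorized label permutation: row-wise shuffle of the rank vector
    perm = np.tile(ranks, (n_resamples, 1))
    perm = rng.permuted(perm, axis=1)
    perm_z = _rank_sum_z(ranks, nx, perm[:, :nx].sum(axis=1))

    if alternative == "two-sided":
        extreme = np.abs(perm_z) >= abs(obs_z) - 1e-12
    elif alternative == "greater":
        extreme = perm_z >= obs_z - 1e-12
    else:
        extreme = perm_z <= obs_z + 1e-12
    p = (1 + int(extreme.sum())) / (n_resamples + 1)
    return PermutationTestResult(obs_z, float(p), n_resamples, seed, alternative)


def pearson_chisq(table, return_flag: bool = False):
    """Pearson X² of a contingency table, without continuity correction.

    X² = sum (observed - expected)² / expected with expected counts from the
    row/column margins. A table with any zero margin is degenerate: the
    statistic is defined as 0 and, with ``return_flag=True``, flagged.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    n = t.sum()
    if n <= 0:
        raise ValueError("table total must be positive")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    degenerate = bool(np.any(rows == 0) or np.any(cols == 0))
    if degenerate:
        stat = 0.0
    else:
        expected = np.outer(rows, cols) / n
        stat = float(((t - expected) ** 2 / expected).sum())
    return (stat, degenerate) if return_flag else stat


def chisq_permutation_test(
    labels,
    outcomes,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation chi-squared test of outcome frequencies between two groups.

    Cross-tabulates two binary-ish vectors (e.g. encounter class against
    signal/chase resolution), takes the Pearson X² as the observed statistic
    and compares it with X² values under random permutations of the labels
    (upper tail, observed counted).  For a 2x2 table the permutation law of
    the statistic depends only on one cell count, which is hypergeometric;
    the Monte-Carlo draw uses that equivalence directly.

    Robust to small or skewed counts because no asymptotic reference is used.
    """
    labels = np.asarray(labels)
    outcomes = np.asarray(outcomes)
    if labels.shape != outcomes.shape:
        raise ValueError("labels and outcomes must have equal length")
    lab_levels = np.unique(labels)
    out_levels = np.unique(outcomes)
    if lab_levels.size != 2:
        raise ValueError("labels must have exactly two levels")
    if out_levels.size > 2:
        raise ValueError("outcomes must have at most two levels")
    n = labels.size

    lab0 = labels == lab_levels[0]
    out0 = outcomes == out_levels[0]
    n_lab0, n_out0 = int(lab0.sum()), int(out0.sum())

    def stat_from_a(a):
        """X² of the 2x2 table as a function of the (lab0, out0) cell."""
        a = np.asarray(a, dtype=float)
        t11 = a
        t12 = n_lab0 - a
        t21 = n_out0 - a
        t22 = n - n_lab0 - n_out0 + a
        # closed form n(ad-bc)^2/(r1 r2 c1 c2); margins fixed by construction
        r1, r2 = n_lab0, n - n_lab0
        c1, c2 = n_out0, n - n_out0
        if min(r1, r2, c1, c2) == 0:
            return np.zeros_like(a, dtype=float)
        return n * (t11 * t22 - t12 * t21) ** 2 / (r1 * r2 * c1 * c2)

    if out_levels.size < 2:  # one outcome level: degenerate margin
        return PermutationTestResult(0.0, 1.0, n_resamples, seed, "greater", degenerate=True)

    obs = float(stat_from_a(int((lab0 & out0).sum())))
    rng = np.random.default_rng(seed)
    a_perm = rng.hypergeometric(n_out0, n - n_out0, n_lab0, size=n_resamples)
    perm = stat_from_a(a_perm)
    p = (1 + int((perm >= obs - 1e-12).sum())) / (n_resamples + 1)
    return PermutationTestResult(obs, float(p), n_resamples, seed, "greater")


def bootstrap_one_per_individual(
    records: pd.DataFrame,
    inner_test,
    B: int = 1000,
    seed: int = 0,
    indiv_col: str = "indiv",
) -> BootstrapTestResult:
    """Bootstrap an inner test over one-encounter-per-individual subsamples.

    Each of the ``B`` replicates draws, independently and uniformly, exactly
    one encounter per focal individual, applies ``inner_test`` to the reduced
    table and records its (statistic, p). The replicate statistics and
    p-values are summarised by their means and 95% percentile intervals
    (2.5th/97.5th percentiles).

    Parameters
    ----------
    records
        Encounter table carrying an individual-identity column.
    inner_test
        Callable mapping a single-encounter-per-individual DataFrame to an
        object with ``statistic`` and ``p_value`` attributes (or a
        (statistic, p) tuple).
    B
        Number of bootstrap replicates (the study used 1000).
    seed
        Master seed; each replicate's selection is derived from it.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if indiv_col not in records.columns:
        raise ValueError(f"records lack the individual column {indiv_col!r}")
    rng = np.random.default_rng(seed)

    codes, _ = pd.factorize(records[indiv_col], sort=True)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    group_starts = np.searchsorted(sorted_codes, np.arange(sorted_codes.max() + 1))
    group_ends = np.append(group_starts[1:], len(sorted_codes))
    sizes = group_ends - group_starts
    row_index = records.index.to_numpy()[order]

    out = np.empty((B, 2), dtype=float)
    for b in range(B):
        offsets = (rng.random(sizes.size) * sizes).astype(np.int64)
        chosen = row_index[group_starts + offsets]
        res = inner_test(records.loc[chosen])
        if hasattr(res, "statistic"):
            out[b] = (res.statistic, res.p_value)
        else:
            out[b] = res

    lo_s, hi_s = np.percentile(out[:, 0], [2.5, 97.5])
    lo_p, hi_p = np.percentile(out[:, 1], [2.5, 97.5])
    return BootstrapTestResult(
        mean_statistic=float(out[:, 0].mean()),
        mean_p=float(out[:, 1].mean()),
        ci95_statistic=(float(lo_s), float(hi_s)),
        ci95_p=(float(lo_p), float(hi_p)),
        n_bootstrap=B,
        seed=seed,
        per_replicate=out,
    )


def signalling_proportion(records: pd.DataFrame) -> float:
    """Proportion of aggressive encounters resolved by signalling.

    Passive encounters are excluded: the proportion is
    n_signal / (n_signal + n_chase). Returns NaN (the missing flag) when the
    table contains no aggressive encounter.
    """
    n_signal = int((records["outcome"] == "signal").sum())
    n_chase = int((records["outcome"] == "chase").sum())
    if n_signal + n_chase == 0:
        return float("nan")
    return n_signal / (n_signal + n_chase)
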