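"""Encounter data model: reading, validation, inclusion filters and per-individual summaries.

An *encounter* is a single observed interaction in which a congeneric
individual came within 1 m of a focal fish. Each record carries where and
when it happened (region, reef, period relative to the mass coral mortality
event), who was involved (focal individual and the two species labels), how
close the fish came (an ordinal proximity category on four 25 cm bins within
1 m), and how the interaction resolved (passive, visual signalling only, or
an escalated chase with its distance in metres).

The analysis unit downstream is the unordered species *pair*; this module
implements the inclusion rules used throughout the analysis: a pair enters
only with at least ``min_encounters`` encounters across at least
``min_individuals`` distinct focal individuals, and the stricter "matched"
subset keeps only species that pass those thresholds in both conspecific and
heterospecific encounters.

Records are held in a :class:`pandas.DataFrame` with the canonical columns
in :data:`COLUMNS`; :func:`validate_encounters` enforces the row invariants.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "PERIODS",
    "OUTCOMES",
    "ConfigurationError",
    "ValidationError",
    "EncounterRecord",
    "PairKey",
    "FilterCriteria",
    "canonical_species",
    "read_encounters",
    "validate_encounters",
    "classify_encounter",
    "add_pair_columns",
    "apply_pair_filter",
    "build_matched_subset",
    "exclude_after_period",
    "individual_mean_proximity",
    "cap_chase_distance",
]

#: Canonical column order for an encounter table.
COLUMNS = [
    "region",
    "reef",
    "period",
    "focal_id",
    "focal_species",
    "partner_species",
    "proximity_cat",
    "outcome",
    "chase_distance_m",
]

PERIODS = ("before", "after")
OUTCOMES = ("passive", "signal", "chase")

#: Accepted textual proximity labels (bin edges in cm) mapped to ordinal codes.
#: Both ASCII hyphen and en-dash are accepted, with or without a "cm" suffix.
_PROXIMITY_LABELS = {
    "0-24": 1,
    "25-49": 2,
    "50-74": 3,
    "75-100": 4,
}


class ConfigurationError(ValueError):
    """A problem with the input layout (missing columns, bad column map)."""


class ValidationError(ValueError):
    """One or more rows violate the encounter-record invariants."""

    def __init__(self, message: str, rejects: pd.DataFrame | None = None):
        super().__init__(message)
        self.rejects = rejects


@dataclass(frozen=True)
class EncounterRecord:
    """A single validated encounter (convenience scalar view of one table row)."""

    region: str
    reef: str
    period: str
    focal_id: str
    focal_species: str
    partner_species: str
    proximity_cat: int
    outcome: str
    chase_distance_m: float | None = None


@dataclass(frozen=True, init=False)
class PairKey:
    """Unordered species pair; ``PairKey(x, y) == PairKey(y, x)``."""

    species_a: str
    species_b: str

    def __init__(self, species_a: str, species_b: str):
        a, b = sorted((canonical_species(species_a), canonical_species(species_b)))
        object.__setattr__(self, "species_a", a)
        object.__setattr__(self, "species_b", b)

    @property
    def is_conspecific(self) -> bool:
        return self.species_a == self.species_b


@dataclass(frozen=True)
class FilterCriteria:
    """Pair inclusion thresholds.

    The defaults (five encounters across five distinct focal individuals)
    reproduce the study's inclusion rule.
    """

    min_encounters: int = 5
    min_individuals: int = 5

    def __post_init__(self):
        if self.min_encounters < 1 or self.min_individuals < 1:
            raise ValueError("filter thresholds must be >= 1")


def canonical_species(label: str) -> str:
    """Canonicalize a species label: strip, collapse internal whitespace, casefold.

    No taxonomic synonym resolution is attempted.
    """
    return re.sub(r"\s+", " ", str(label).strip()).casefold()


def classify_encounter(focal_species: str, partner_species: str) -> str:
    """Return ``"conspecific"`` or ``"heterospecific"`` for one encounter."""
    a, b = canonical_species(focal_species), canonical_species(partner_species)
    if not a or not b:
        raise ValueError("species labels must be non-empty")
    return "conspecific" if a == b else "heterospecific"


def _parse_proximity(value) -> int | None:
    """Parse a proximity cell: ordinal code 1-4 or a bin label like '0-24 cm'."""
    if pd.isna(value):
        return None
    if isinstance(value, (int, np.integer)):
        return int(value) if value in (1, 2, 3, 4) else None
    if isinstance(value, float):
        return int(value) if value in (1.0, 2.0, 3.0, 4.0) else None
    text = str(value).strip().casefold()
    if text in {"1", "2", "3", "4"}:
        return int(text)
    # label dialect: normalize dashes, drop a trailing "cm"
    text = text.replace("–", "-").replace("—", "-")
    text = re.sub(r"\s*cm$", "", text).replace(" ", "")
    return _PROXIMITY_LABELS.get(text)


def validate_encounters(
    df: pd.DataFrame, on_invalid: str = "raise"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate an encounter table against the record invariants.

    Checks, per row: period in {before, after}; outcome in
    {passive, signal, chase}; proximity parses to an ordinal 1-4;
    chase_distance_m present, non-negative iff outcome == chase.
    Species labels are canonicalized in the returned frame.

    Parameters
    ----------
    df
        Table with the columns of :data:`COLUMNS` (chase_distance_m may be
        missing entirely if no chases occur).
    on_invalid
        ``"raise"`` raises :class:`ValidationError` naming the offending rows;
        ``"collect"`` drops them and returns them in the rejects frame.

    Returns
    -------
    (valid, rejects)
        ``valid`` has canonical dtypes and species labels; ``rejects`` holds
        the invalid input rows with a ``reason`` column and original row
        numbers in its index.
    """
    if on_invalid not in ("raise", "collect"):
        raise ValueError("on_invalid must be 'raise' or 'collect'")
    df = df.copy()
    if "chase_distance_m" not in df.columns:
        df["chase_distance_m"] = np.nan
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")

    reasons = pd.Series("", index=df.index, dtype=object)

    period = df["period"].astype(str).str.strip().str.casefold()
    bad = ~period.isin(PERIODS)
    reasons[bad] += "invalid period;"

    outcome = df["outcome"].astype(str).str.strip().str.casefold()
    bad = ~outcome.isin(OUTCOMES)
    reasons[bad] += "invalid outcome;"

    prox = df["proximity_cat"].map(_parse_proximity)
    reasons[prox.isna()] += "invalid proximity_cat;"

    dist = pd.to_numeric(df["chase_distance_m"], errors="coerce")
    is_chase = outcome == "chase"
    reasons[is_chase & dist.isna()] += "chase without chase_distance_m;"
    reasons[is_chase & (dist < 0)] += "negative chase_distance_m;"
    reasons[~is_chase & dist.notna()] += "chase_distance_m on non-chase;"

    for col in ("focal_species", "partner_species"):
        canon = df[col].astype(str).map(canonical_species)
        reasons[canon == ""] += f"empty {col};"
        df[col] = canon

    bad_mask = reasons != ""
    if bad_mask.any() and on_invalid == "raise":
        rows = [f"row {i}: {r}" for i, r in reasons[bad_mask].items()]
        rejects = df.loc[bad_mask].assign(reason=reasons[bad_mask])
        raise ValidationError(
            f"{bad_mask.sum()} invalid encounter row(s): " + " | ".join(rows[:10]),
            rejects=rejects,
        )

    rejects = df.loc[bad_mask].assign(reason=reasons[bad_mask])
    valid = df.loc[~bad_mask].copy()
    valid["period"] = period[~bad_mask]
    valid["outcome"] = outcome[~bad_mask]
    valid["proximity_cat"] = prox[~bad_mask].astype(int)
    valid["chase_distance_m"] = dist[~bad_mask]
    for col in ("region", "reef", "focal_id"):
        valid[col] = valid[col].astype(str)
    return valid[COLUMNS], rejects


def read_encounters(
    path,
    delimiter: str | None = None,
    column_map: dict[str, str] | None = None,
    on_invalid: str = "raise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited encounter table and validate it.

    Parameters
    ----------
    path
        UTF-8 delimited text file with a header row.
    delimiter
        Field separator; sniffed between comma and tab when ``None``.
    column_map
        Optional mapping of file column name -> canonical column name, for
        tables whose headers differ from :data:`COLUMNS`.
    on_invalid
        Passed to :func:`validate_encounters`.

    Returns
    -------
    (records, rejects) as in :func:`validate_encounters`.
    """
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            head = fh.readline()
        delimiter = "\t" if head.count("\t") > head.count(",") else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=object, encoding="utf-8")
    if column_map:
        unknown = [c for c in column_map if c not in raw.columns]
        if unknown:
            raise ConfigurationError(f"column_map names absent from file: {unknown}")
        raw = raw.rename(columns=column_map)
    return validate_encounters(raw, on_invalid=on_invalid)


def write_encounters(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write an encounter table as delimited text (inverse of :func:`read_encounters`)."""
    df.to_csv(path, sep=delimiter, index=False)


def _individual_key(df: pd.DataFrame) -> pd.Series:
    # identity is only defined within reef+period: the field protocol cannot
    # link individuals across periods (or reefs), so keys never span them
    return df["reef"].astype(str) + "\x1f" + df["period"] + "\x1f" + df["focal_id"].astype(str)


def add_pair_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append species_a/species_b (sorted), pair class and individual-key columns."""
    df = df.copy()
    a = df["focal_species"].where(df["focal_species"] <= df["partner_species"], df["partner_species"])
    b = df["partner_species"].where(df["focal_species"] <= df["partner_species"], df["focal_species"])
    df["species_a"] = a
    df["species_b"] = b
    df["pair_class"] = np.where(a == b, "conspecific", "heterospecific")
    df["indiv"] = _individual_key(df)
    return df


def apply_pair_filter(
    records: pd.DataFrame,
    criteria: FilterCriteria = FilterCriteria(),
    per_period: bool = False,
) -> tuple[pd.DataFrame, set[PairKey], pd.DataFrame]:
    """Keep species pairs with enough encounters across enough focal individuals.

    A pair is kept iff its encounter count >= ``criteria.min_encounters`` and
    its number of distinct focal individuals >= ``criteria.min_individuals``.
    Individuals are counted as focal individuals only (the only identified
    party) and are scoped to reef+period.

    Parameters
    ----------
    records
        Validated encounter table.
    criteria
        Thresholds; defaults reproduce the study rule (5 and 5).
    per_period
        When True the thresholds are applied within each period separately;
        the default pools both periods when counting.

    Returns
    -------
    (kept_records, kept_pairs, audit)
        ``audit`` has one row per (pair, period-scope) with columns
        species_a, species_b, class, period, n_encounters, n_individuals, kept.
    """
    if records.empty:
        audit = pd.DataFrame(
            columns=["species_a", "species_b", "class", "period", "n_encounters", "n_individuals", "kept"]
        )
        return records.copy(), set(), audit

    df = add_pair_columns(records)
    keys = ["species_a", "species_b"] + (["period"] if per_period else [])
    grouped = df.groupby(keys, sort=True)
    audit = grouped.agg(
        n_encounters=("indiv", "size"), n_individuals=("indiv", "nunique")
    ).reset_index()
    audit["class"] = np.where(
        audit["species_a"] == audit["species_b"], "conspecific", "heterospecific"
    )
    if not per_period:
        audit["period"] = "pooled"
    audit["kept"] = (audit["n_encounters"] >= criteria.min_encounters) & (
        audit["n_individuals"] >= criteria.min_individuals
    )
    audit = audit[
        ["species_a", "species_b", "class", "period", "n_encounters", "n_individuals", "kept"]
    ]

    kept_keys = set(
        map(tuple, audit.loc[audit["kept"], ["species_a", "species_b"] + (["period"] if per_period else [])].itertuples(index=False))
    )
    row_keys = list(map(tuple, df[keys].itertuples(index=False)))
    mask = np.fromiter((k in kept_keys for k in row_keys), bool, len(row_keys))
    kept = records.loc[df.index[mask]].copy()
    kept_pairs = {PairKey(a, b) for a, b, *_ in kept_keys}
    return kept, kept_pairs, audit


def build_matched_subset(
    records: pd.DataFrame,
    criteria: FilterCriteria = FilterCriteria(),
    per_period: bool = False,
) -> pd.DataFrame:
    """Restrict to species passing the pair filter in *both* encounter classes.

    A species qualifies when, among the pairs kept by
    :func:`apply_pair_filter`, it appears in at least one conspecific pair and
    at least one heterospecific pair. Kept records are those of kept pairs
    whose focal species qualifies. The reduction is applied repeatedly until
    it stabilises, so the operation is idempotent by construction.
    """
    current = records
    while True:
        kept, kept_pairs, _ = apply_pair_filter(current, criteria, per_period=per_period)
        con_species = {p.species_a for p in kept_pairs if p.is_conspecific}
        het_species = set()
        for p in kept_pairs:
            if not p.is_conspecific:
                het_species.update((p.species_a, p.species_b))
        qualified = con_species & het_species
        out = kept.loc[kept["focal_species"].isin(qualified)].copy()
        if len(out) == len(current):
            return out
        current = out


def exclude_after_period(records: pd.DataFrame, regions) -> pd.DataFrame:
    """Drop after-period records from the given regions (unchanged elsewhere).

    Used for regions that did not experience significant coral mortality and
    therefore have no meaningful "after" condition. Unknown region labels
    trigger a warning, not an error.
    """
    regions = set(regions)
    unknown = regions - set(records["region"].unique())
    if unknown:
        warnings.warn(f"exclude_after_period: unknown region label(s) {sorted(unknown)}")
    mask = (records["period"] == "after") & records["region"].isin(regions)
    return records.loc[~mask].copy()


def individual_mean_proximity(records: pd.DataFrame) -> pd.DataFrame:
    """Per-individual mean proximity category, split by encounter class and period.

    Repeated encounters by the same focal individual are not independent; the
    downstream rank test therefore runs on one mean per individual per class.
    The mean is taken on the 1-4 ordinal codes, which is defensible here
    because the four bins have equal width (25 cm).

    Returns a frame with columns indiv, focal_id, period, class,
    mean_proximity, n_encounters.
    """
    df = add_pair_columns(records)
    out = (
        df.groupby(["indiv", "focal_id", "period", "pair_class"], sort=True)
        .agg(mean_proximity=("proximity_cat", "mean"), n_encounters=("proximity_cat", "size"))
        .reset_index()
        .rename(columns={"pair_class": "class"})
    )
    return out


def cap_chase_distance(d, cap: float = 10.0):
    """Cap chase distances at ``cap`` metres (rare very long chases are grouped).

    Accepts a scalar or array; negative distances are invalid.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("chase distances must be non-negative")
    capped = np.minimum(arr, float(cap))
    return float(capped) if np.isscalar(d) or arr.ndim == 0 else capped
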