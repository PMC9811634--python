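"""End-to-end orchestration of the four-prediction contest analysis.

Given an encounter table, a phylogeny and a trait table — or a synthetic
scenario from :mod:`reefcontests.simulate` — this module applies the
inclusion filters and runs:

1. proximity: permutation Mann-Whitney U on per-individual mean proximity,
   conspecific vs heterospecific, per period (plus aggressive-only
   proximity histograms);
2. signalling: bootstrap-wrapped (one encounter per individual) permutation
   chi-squared contrasts of signal/chase resolution — class within each
   period, and period within each class;
3. chase variability: CV-equality (SLRT/MSLRT) comparisons of capped chase
   distances by class per period and by period per class, on both the main
   (≥5) and the matched subsets, plus class mean chase distances;
4. comparative models: OLS for mean proximity and chase CV and a binomial
   GLM for signalling proportion against patristic distance and body-size
   difference, heterospecific pairs only.

Every random procedure's seed and resample count is derived from one master
seed and recorded in the report; the machine report is byte-identical across
runs with the same inputs and seed.  Stages are independent after
filtering: a failure in one prediction is recorded and the others still run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative, cv, encounters, resampling, simulate

__all__ = ["RunConfig", "prepare_inputs", "run_prediction1", "run_prediction2",
           "run_prediction3", "run_prediction4", "run_all", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one full analysis run.

    Exactly one of (``encounters_path``) or (``scenario``) must be set;
    a scenario may be the name ``"field"``/``"null"`` or a
    :class:`~reefcontests.simulate.GeneratorConfig`.
    """

    encounters_path: str | None = None
    tree_path: str | None = None
    traits_path: str | None = None
    scenario: object | None = None
    criteria: encounters.FilterCriteria = field(default_factory=encounters.FilterCriteria)
    pair_filter_per_period: bool = False
    exclude_after_regions: tuple = ()
    n_permutations: int = 10_000
    n_bootstrap: int = 1000
    mslr_n_sim: int = 2000
    cap_m: float = 10.0
    min_chases: int = 5
    cv_on_capped: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if (self.encounters_path is None) == (self.scenario is None):
            raise ValueError("set exactly one of encounters_path or scenario")


def _spawn_seeds(master: int, names) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {name: int(rng.integers(2**31 - 1)) for name in names}


_SEED_NAMES = ("generator", "prediction1", "prediction2", "prediction2_inner", "prediction3")


def prepare_inputs(config: RunConfig) -> dict:
    """Load or generate inputs, validate, and build the analysis subsets."""
    seeds = _spawn_seeds(config.seed, _SEED_NAMES)
    if config.scenario is not None:
        scen = config.scenario
        if scen == "field":
            scen = simulate.field_scenario(seed=seeds["generator"])
        elif scen == "null":
            scen = simulate.null_scenario(seed=seeds["generator"])
        elif isinstance(scen, simulate.GeneratorConfig):
            scen = dataclasses.replace(scen, seed=seeds["generator"])
        else:
            raise ValueError(f"unknown scenario {scen!r}")
        raw, traits, tree = simulate.generate_dataset(scen)
        records, _ = encounters.validate_encounters(raw)
    else:
        records, _ = encounters.read_encounters(config.encounters_path)
        traits = comparative.read_traits(config.traits_path) if config.traits_path else None
        tree = None
        if config.tree_path:
            tree = Path(config.tree_path).read_text(encoding="utf-8")

    if config.exclude_after_regions:
        records = encounters.exclude_after_period(records, config.exclude_after_regions)

    main, kept_pairs, audit = encounters.apply_pair_filter(
        records, config.criteria, per_period=config.pair_filter_per_period
    )
    matched = encounters.build_matched_subset(
        records, config.criteria, per_period=config.pair_filter_per_period
    )
    distances = None
    if tree is not None:
        species = sorted(set(main["focal_species"]) | set(main["partner_species"]))
        distances = comparative.patristic_distances(tree, species)
    return {
        "records": records,
        "main": main,
        "matched": matched,
        "kept_pairs": kept_pairs,
        "audit": audit,
        "traits": traits,
        "tree": tree,
        "distances": distances,
        "seeds": seeds,
    }


def _perm_result_dict(res: resampling.PermutationTestResult) -> dict:
    return {
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n_resamples": res.n_resamples,
        "seed": res.seed,
        "alternative": res.alternative,
        "degenerate": res.degenerate,
    }


def run_prediction1(data: dict, config: RunConfig) -> dict:
    """Class contrast of per-individual mean proximity, per period.

    The first sample passed to the rank test is the heterospecific group, so
    a positive Z means heterospecific encounters happen at larger distances
    (conspecifics approach closer).
    """
    out = {}
    means = encounters.individual_mean_proximity(data["main"])
    aggro = data["main"][data["main"]["outcome"].isin(["signal", "chase"])]
    aggro = encounters.add_pair_columns(aggro)
    for period in ("before", "after"):
        sub = means[means["period"] == period]
        con = sub.loc[sub["class"] == "conspecific", "mean_proximity"].to_numpy()
        het = sub.loc[sub["class"] == "heterospecific", "mean_proximity"].to_numpy()
        block: dict = {
            "n_individuals": {"conspecific": con.size, "heterospecific": het.size},
            "mean_of_means": {
                "conspecific": float(con.mean()) if con.size else None,
                "heterospecific": float(het.mean()) if het.size else None,
            },
        }
        if con.size and het.size:
            res = resampling.mwu_permutation_test(
                het, con, n_resamples=config.n_permutations, seed=data["seeds"]["prediction1"]
            )
            block["test"] = _perm_result_dict(res)
        else:
            block["note"] = "a class is empty in this period; comparison skipped"
        hist = {}
        asub = aggro[aggro["period"] == period]
        for cls in ("conspecific", "heterospecific"):
            counts = (
                asub.loc[asub["pair_class"] == cls, "proximity_cat"]
                .value_counts()
                .reindex([1, 2, 3, 4], fill_value=0)
            )
            hist[cls] = [int(c) for c in counts]
        block["aggressive_proximity_hist"] = hist
        out[period] = block
    return out


def _boot_result_dict(res: resampling.BootstrapTestResult) -> dict:
    return {
        "mean_statistic": res.mean_statistic,
        "mean_p": res.mean_p,
        "ci95_statistic": list(res.ci95_statistic),
        "ci95_p": list(res.ci95_p),
        "n_bootstrap": res.n_bootstrap,
        "seed": res.seed,
    }


def run_prediction2(data: dict, config: RunConfig) -> dict:
    """Bootstrap-wrapped chi-squared contrasts of signalling proportions."""
    aggro = encounters.add_pair_columns(
        data["main"][data["main"]["outcome"].isin(["signal", "chase"])]
    )
    inner_seed_rng = np.random.default_rng(data["seeds"]["prediction2_inner"])

    def make_inner(label_col):
        def inner(df):
            if df[label_col].nunique() < 2 or df["outcome"].nunique() < 1:
                return (0.0, 1.0)
            seed = int(inner_seed_rng.integers(2**31 - 1))
            res = resampling.chisq_permutation_test(
                df[label_col].to_numpy(),
                df["outcome"].to_numpy(),
                n_resamples=config.n_permutations,
                seed=seed,
            )
            return (res.statistic, res.p_value)

        return inner

    out: dict = {"signalling_proportions": {}, "n_aggressive": {}}
    for period in ("before", "after"):
        for cls in ("conspecific", "heterospecific"):
            sub = aggro[(aggro["period"] == period) & (aggro["pair_class"] == cls)]
            out["n_aggressive"][f"{cls}_{period}"] = int(len(sub))
            out["signalling_proportions"][f"{cls}_{period}"] = (
                resampling.signalling_proportion(sub) if len(sub) else None
            )

    contrasts = [
        ("class_before", aggro[aggro["period"] == "before"], "pair_class"),
        ("class_after", aggro[aggro["period"] == "after"], "pair_class"),
        ("period_conspecific", aggro[aggro["pair_class"] == "conspecific"], "period"),
        ("period_heterospecific", aggro[aggro["pair_class"] == "heterospecific"], "period"),
    ]
    for name, sub, label_col in contrasts:
        if sub.empty or sub[label_col].nunique() < 2:
            out[name] = {"note": "empty contrast cell; skipped"}
            continue
        res = resampling.bootstrap_one_per_individual(
            sub,
            make_inner(label_col),
            B=config.n_bootstrap,
            seed=data["seeds"]["prediction2"],
        )
        out[name] = _boot_result_dict(res)
    return out


def _cv_dict(res: cv.CVComparison) -> dict:
    return {
        "group_labels": list(res.group_labels),
        "group_cvs": [float(x) for x in res.group_cvs],
        "statistic_slrt": res.statistic_slrt,
        "statistic_mslrt": res.statistic_mslrt,
        "df": res.df,
        "p_slrt": res.p_slrt,
        "p_mslrt": res.p_mslrt,
        "n_per_group": list(res.n_per_group),
        "n_sim": res.n_sim,
        "seed": res.seed,
    }


def run_prediction3(data: dict, config: RunConfig) -> dict:
    """CV comparisons of capped chase distances, per period/class and subset."""
    out = {}
    for subset_name in ("ge5", "matched"):
        records = data["main"] if subset_name == "ge5" else data["matched"]
        chases = encounters.add_pair_columns(records[records["outcome"] == "chase"])
        dist = chases["chase_distance_m"].to_numpy()
        if config.cv_on_capped:
            dist = encounters.cap_chase_distance(dist, config.cap_m)
        chases = chases.assign(dist=dist)
        block: dict = {"mean_chase_distance_m": {}, "n_chases": {}}
        groups = {}
        for period in ("before", "after"):
            for cls in ("conspecific", "heterospecific"):
                g = chases.loc[
                    (chases["period"] == period) & (chases["pair_class"] == cls), "dist"
                ].to_numpy()
                groups[(cls, period)] = g
                key = f"{cls}_{period}"
                block["n_chases"][key] = int(g.size)
                block["mean_chase_distance_m"][key] = float(g.mean()) if g.size else None

        def compare(name, g1, l1, g2, l2):
            if g1.size < 2 or g2.size < 2:
                block[name] = {"note": "a class has < 2 chases; comparison skipped"}
                return
            res = cv.mslr_test(
                [g1, g2], labels=[l1, l2],
                n_sim=config.mslr_n_sim, seed=data["seeds"]["prediction3"],
            )
            block[name] = _cv_dict(res)

        for period in ("before", "after"):
            compare(
                f"class_{period}",
                groups[("conspecific", period)], "conspecific",
                groups[("heterospecific", period)], "heterospecific",
            )
        for cls in ("conspecific", "heterospecific"):
            compare(
                f"period_{cls}",
                groups[(cls, "before")], "before",
                groups[(cls, "after")], "after",
            )
        out[subset_name] = block
    return out


def _reg_dict(res: comparative.RegressionResult) -> dict:
    return {
        "coefficients": res.coefficients,
        "intercept": res.intercept,
        "model_p": res.model_p,
        "n_pairs": res.n,
        "adjusted_r2": res.adjusted_r2,
        "mcfadden_r2": res.mcfadden_r2,
        "warnings": list(res.warnings),
    }


def run_prediction4(data: dict, config: RunConfig) -> dict:
    """Comparative regressions on heterospecific pair observations."""
    if data["distances"] is None or data["traits"] is None:
        return {"note": "tree and/or trait table unavailable; models skipped"}
    pairs = comparative.build_pair_observations(
        data["main"],
        distances=data["distances"],
        traits=data["traits"],
        min_chases=config.min_chases,
        cap=config.cap_m,
    )
    out: dict = {"n_heterospecific_pairs": int(len(pairs))}
    try:
        out["proximity"] = _reg_dict(comparative.fit_linear_model(pairs, "mean_proximity"))
    except ValueError as exc:
        out["proximity"] = {"note": str(exc)}
    try:
        out["signalling"] = _reg_dict(comparative.fit_binomial_glm(pairs))
    except ValueError as exc:
        out["signalling"] = {"note": str(exc)}
    try:
        out["chase_cv"] = _reg_dict(comparative.fit_linear_model(pairs, "chase_cv"))
    except ValueError as exc:
        out["chase_cv"] = {"note": str(exc)}
    return out


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and return the machine report (a plain dict).

    With ``config.outdir`` set, also writes ``report.json``, a human-readable
    ``report.txt`` and the pair-filter ``audit.csv``.
    """
    data = prepare_inputs(config)
    report: dict = {
        "meta": {
            "package": "reefcontests",
            "master_seed": config.seed,
            "child_seeds": data["seeds"],
            "n_permutations": config.n_permutations,
            "n_bootstrap": config.n_bootstrap,
            "mslr_n_sim": config.mslr_n_sim,
            "cap_m": config.cap_m,
            "min_chases": config.min_chases,
            "pair_filter_per_period": config.pair_filter_per_period,
            "criteria": dataclasses.asdict(config.criteria),
        },
        "data": {
            "n_records": int(len(data["records"])),
            "n_records_main": int(len(data["main"])),
            "n_records_matched": int(len(data["matched"])),
            "n_pairs_kept": int(len(data["kept_pairs"])),
            "n_encounters_by_period": {
                p: int((data["main"]["period"] == p).sum()) for p in ("before", "after")
            },
        },
        "errors": {},
    }
    stages = {
        "prediction1_proximity": run_prediction1,
        "prediction2_signalling": run_prediction2,
        "prediction3_chase_cv": run_prediction3,
        "prediction4_comparative": run_prediction4,
    }
    for name, fn in stages.items():
        try:
            report[name] = fn(data, config)
        except Exception as exc:  # stages independent: record and continue
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
    report = _jsonify(report)
    if config.outdir:
        write_report(report, data["audit"], config.outdir)
    return report


def report_json(report: dict) -> str:
    """Canonical machine serialization (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=1, separators=(",", ": "))


def _fmt(v, nd=3):
    return "NA" if v is None else f"{v:.{nd}f}"


def render_report_text(report: dict) -> str:
    """Small human-readable summary of the machine report."""
    lines = [
        "reefcontests run report",
        f"  master seed: {report['meta']['master_seed']}",
        f"  records: {report['data']['n_records']} (main subset {report['data']['n_records_main']}, "
        f"matched {report['data']['n_records_matched']})",
        "",
        "P1 proximity (permutation MWU, het first: Z > 0 means conspecifics closer)",
    ]
    p1 = report.get("prediction1_proximity", {})
    for period, block in p1.items():
        t = block.get("test", {})
        lines.append(
            f"  {period}: Z = {_fmt(t.get('statistic'))}, p = {_fmt(t.get('p_value'), 4)}"
        )
    lines.append("")
    lines.append("P2 signalling (bootstrap x permutation chi-squared)")
    p2 = report.get("prediction2_signalling", {})
    for key in ("class_before", "class_after", "period_conspecific", "period_heterospecific"):
        b = p2.get(key, {})
        if "mean_statistic" in b:
            lines.append(
                f"  {key}: X2 = {_fmt(b['mean_statistic'])} "
                f"[{_fmt(b['ci95_statistic'][0])}, {_fmt(b['ci95_statistic'][1])}], "
                f"p = {_fmt(b['mean_p'], 4)}"
            )
    lines.append("")
    lines.append("P3 chase-distance CV (MSLR)")
    p3 = report.get("prediction3_chase_cv", {})
    for subset, block in p3.items():
        for key, b in block.items():
            if isinstance(b, dict) and "statistic_mslrt" in b:
                cvs = ", ".join(
                    f"{l}={_fmt(c)}" for l, c in zip(b["group_labels"], b["group_cvs"])
                )
                lines.append(
                    f"  [{subset}] {key}: CV {cvs}; MSLR = {_fmt(b['statistic_mslrt'])}, "
                    f"p = {_fmt(b['p_mslrt'], 4)}"
                )
    lines.append("")
    lines.append("P4 comparative models (phylo distance + size difference)")
    p4 = report.get("prediction4_comparative", {})
    for key in ("proximity", "signalling", "chase_cv"):
        b = p4.get(key, {})
        if "coefficients" in b:
            r2 = b.get("adjusted_r2")
            r2name = "adjR2"
            if r2 is None:
                r2, r2name = b.get("mcfadden_r2"), "McFaddenR2"
            lines.append(
                f"  {key}: beta_phylo = {_fmt(b['coefficients'].get('phylo_distance'))}, "
                f"beta_size = {_fmt(b['coefficients'].get('size_difference_cm'))}, "
                f"{r2name} = {_fmt(r2)}, p = {_fmt(b['model_p'], 4)}, n = {b['n_pairs']}"
            )
    if report.get("errors"):
        lines.append("")
        lines.append(f"stage errors: {report['errors']}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, audit: pd.DataFrame, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report), encoding="utf-8")
    (out / "report.txt").write_text(render_report_text(report), encoding="utf-8")
    audit.to_csv(out / "audit.csv", index=False)
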