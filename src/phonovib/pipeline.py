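"""Five-step boosted-stump feature-selection protocol.

Given a subject feature table with healthy/disordered groups per sex, the
pipeline (after redundancy pruning and age screening):

1. compares the three boosting algorithms, with and without two injected
   random parameters (one standard normal, one uniform), and flags any
   algorithm that rates a random parameter important;
2. sweeps the ensemble size and picks the smallest size whose AUC is within
   a tolerance of the curve maximum;
3. ranks parameters by feature importance for the female comparison and
   evaluates nested models of increasing size, choosing the smallest model
   within tolerance of the best AUC;
4. does the same for the male comparison;
5. evaluates combinations of the two chosen sets (union, per-sex sets,
   PVG-only and GAW-only members, user-supplied subsets) and returns the
   smallest subset whose worst-sex AUC is within tolerance of the best.

The visual "knee" choices of the original protocol are formalized as
explicit tolerance rules so every decision is reproducible from the seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .boosting import (BoostConfig, crossval_evaluate, feature_importance,
                       make_estimator)
from .registry import REGISTRY
from .screen import CorrelationPruner, age_screen
from .tables import FeatureTable

__all__ = [
    "Comparison",
    "StepwiseCurve",
    "SelectionReport",
    "step1_compare_algorithms",
    "step2_stump_sweep",
    "stepwise_select",
    "step5_combine",
    "run_pipeline",
]

ALGORITHMS = ("AdaBoost", "LogitBoost", "RUSBoost")


@dataclass(frozen=True)
class Comparison:
    """One healthy-vs-disordered group comparison."""

    name: str
    healthy: str
    disordered: str


def default_comparisons(table: FeatureTable) -> List[Comparison]:
    out = []
    groups = set(table.data["group"])
    for name, h, d in (("females", "N_F", "FD_F"), ("males", "N_M", "FD_M")):
        if h in groups and d in groups:
            out.append(Comparison(name, h, d))
    if not out:
        raise ValueError("no healthy/disordered group pairs found "
                         "(expected N_F/FD_F and/or N_M/FD_M)")
    return out


def comparison_arrays(table: FeatureTable, comp: Comparison,
                      parameters: Sequence[str]):
    """(X, y) with y = 1 for the disordered group."""
    sub = table.select_groups([comp.healthy, comp.disordered])
    X = sub.values(parameters)
    y = (sub.data["group"] == comp.disordered).astype(int).to_numpy()
    return X, y


def complete_parameters(table: FeatureTable,
                        comparisons: Sequence[Comparison]) -> List[str]:
    """Parameters without NaN in any comparison's subjects."""
    keep = []
    groups = sorted({g for c in comparisons
                     for g in (c.healthy, c.disordered)})
    sub = table.select_groups(groups)
    for p in table.parameters:
        if np.all(np.isfinite(sub.data[p].to_numpy(dtype=float))):
            keep.append(p)
    return keep


# --------------------------------------------------------------------------
# Step 1: algorithm comparison with injected random parameters
# --------------------------------------------------------------------------

def step1_compare_algorithms(table: FeatureTable,
                             comparisons: Sequence[Comparison],
                             n_stumps: int = 300,
                             learning_rate: float = 0.1,
                             k: int = 10, repeats: int = 10,
                             seed: int = 0,
                             unsuitable_fi: float = 0.5):
    """Compare the three algorithms with and without random parameters.

    Returns ``(results_df, winner)``.  The winner has the highest mean of
    AUC and ACC averaged over comparisons and over the with/without-random
    variants, excluding algorithms flagged unsuitable (a random parameter's
    normalized feature importance exceeding ``unsuitable_fi``).
    """
    rng = np.random.default_rng(seed)
    params = complete_parameters(table, comparisons)
    aug = table.subset(params)
    aug_data = aug.data.copy()
    aug_data["RAND_N"] = rng.normal(size=len(aug_data))
    aug_data["RAND_U"] = rng.uniform(size=len(aug_data))
    aug = FeatureTable(data=aug_data, parameters=params + ["RAND_N",
                                                           "RAND_U"])
    rows = []
    for algo in ALGORITHMS:
        cfg = BoostConfig(algorithm=algo, n_stumps=n_stumps,
                          learning_rate=learning_rate, seed=seed)
        for comp in comparisons:
            for with_random, tab in ((False, table), (True, aug)):
                pars = (params + ["RAND_N", "RAND_U"]) if with_random \
                    else params
                X, y = comparison_arrays(tab, comp, pars)
                perf = crossval_evaluate(X, y, cfg, k=k, repeats=repeats,
                                         seed=seed)
                est = make_estimator(cfg)
                est.fit(X, y)
                fi = feature_importance(est).normalized
                max_rand = float(np.max(fi[-2:])) if with_random else np.nan
                rows.append({
                    "algorithm": algo, "comparison": comp.name,
                    "with_random": with_random,
                    "auc_mean": perf.auc_mean, "auc_std": perf.auc_std,
                    "acc_mean": perf.acc_mean, "acc_std": perf.acc_std,
                    "max_random_fi": max_rand})
    df = pd.DataFrame(rows)
    unsuitable = set(
        df.loc[df["max_random_fi"] > unsuitable_fi, "algorithm"])
    score = (df.groupby("algorithm")[["auc_mean", "acc_mean"]].mean()
             .mean(axis=1))
    ranked = [a for a in score.sort_values(ascending=False).index
              if a not in unsuitable]
    winner = ranked[0] if ranked else None
    df.attrs["unsuitable"] = sorted(unsuitable)
    return df, winner


# --------------------------------------------------------------------------
# Step 2: ensemble-size sweep
# --------------------------------------------------------------------------

def step2_stump_sweep(table: FeatureTable,
                      comparisons: Sequence[Comparison],
                      algorithm: str = "LogitBoost",
                      sizes: Sequence[int] = (1, 10, 50, 100, 200, 300,
                                              400, 500),
                      learning_rate: float = 0.1,
                      k: int = 10, repeats: int = 10, seed: int = 0,
                      tolerance: float = 0.005,
                      override_size: Optional[int] = None):
    """AUC/ACC vs ensemble size; the chosen size is the smallest whose AUC
    (averaged over comparisons) is within ``tolerance`` of the curve
    maximum, unless ``override_size`` is given."""
    params = complete_parameters(table, comparisons)
    rows = []
    for size in sizes:
        cfg = BoostConfig(algorithm=algorithm, n_stumps=int(size),
                          learning_rate=learning_rate, seed=seed)
        aucs, accs = [], []
        for comp in comparisons:
            X, y = comparison_arrays(table, comp, params)
            perf = crossval_evaluate(X, y, cfg, k=k, repeats=repeats,
                                     seed=seed)
            aucs.append(perf.auc_mean)
            accs.append(perf.acc_mean)
            rows.append({"n_stumps": int(size), "comparison": comp.name,
                         "auc_mean": perf.auc_mean,
                         "acc_mean": perf.acc_mean})
        rows.append({"n_stumps": int(size), "comparison": "average",
                     "auc_mean": float(np.mean(aucs)),
                     "acc_mean": float(np.mean(accs))})
    df = pd.DataFrame(rows)
    avg = df[df["comparison"] == "average"].sort_values("n_stumps")
    best = avg["auc_mean"].max()
    ok = avg[avg["auc_mean"] >= best - tolerance]
    chosen = int(ok["n_stumps"].iloc[0])
    if override_size is not None:
        chosen = int(override_size)
    return df, chosen


# --------------------------------------------------------------------------
# Steps 3/4: stepwise nested-model selection by feature importance
# --------------------------------------------------------------------------

@dataclass
class StepwiseCurve:
    """Nested-model curve for one comparison."""

    comparison: str
    order: List[str]            # parameters by decreasing feature importance
    sizes: List[int]
    auc_mean: List[float]
    auc_std: List[float]
    acc_mean: List[float]
    acc_std: List[float]
    chosen_size: int
    chosen_subset: List[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes, "added_parameter": self.order,
            "auc_mean": self.auc_mean, "auc_std": self.auc_std,
            "acc_mean": self.acc_mean, "acc_std": self.acc_std})


def stepwise_select(table: FeatureTable, comparison: Comparison,
                    algorithm: str = "LogitBoost", n_stumps: int = 300,
                    learning_rate: float = 0.1, k: int = 10,
                    repeats: int = 10, seed: int = 0,
                    tolerance: float = 0.005,
                    max_size: Optional[int] = None) -> StepwiseCurve:
    """Rank parameters by feature importance, evaluate nested models of
    sizes 1..n, and choose the smallest size whose AUC is within
    ``tolerance`` of the maximum."""
    params = complete_parameters(table, [comparison])
    if not params:
        raise ValueError("no complete parameters for stepwise selection")
    cfg = BoostConfig(algorithm=algorithm, n_stumps=n_stumps,
                      learning_rate=learning_rate, seed=seed)
    X, y = comparison_arrays(table, comparison, params)
    est = make_estimator(cfg)
    est.fit(X, y)
    fi = feature_importance(est).raw
    order_idx = np.argsort(-fi, kind="stable")
    order = [params[i] for i in order_idx]
    n = len(order) if max_size is None else min(max_size, len(order))

    sizes, auc_m, auc_s, acc_m, acc_s = [], [], [], [], []
    for size in range(1, n + 1):
        sub = order[:size]
        Xs, ys = comparison_arrays(table, comparison, sub)
        perf = crossval_evaluate(Xs, ys, cfg, k=k, repeats=repeats,
                                 seed=seed)
        sizes.append(size)
        auc_m.append(perf.auc_mean)
        auc_s.append(perf.auc_std)
        acc_m.append(perf.acc_mean)
        acc_s.append(perf.acc_std)
    best = max(auc_m)
    chosen = next(s for s, a in zip(sizes, auc_m) if a >= best - tolerance)
    return StepwiseCurve(comparison=comparison.name, order=order[:n],
                         sizes=sizes, auc_mean=auc_m, auc_std=auc_s,
                         acc_mean=acc_m, acc_std=acc_s, chosen_size=chosen,
                         chosen_subset=order[:chosen])


# --------------------------------------------------------------------------
# Step 5: combination search
# --------------------------------------------------------------------------

def _family_members(params: Sequence[str], family: str) -> List[str]:
    known = [p for p in params if p in REGISTRY]
    if family == "pvg":
        return [p for p in known if REGISTRY[p].family == "pvg"]
    return [p for p in known
            if REGISTRY[p].family in ("gaw_t", "symmetry")]


def step5_combine(curves: Dict[str, StepwiseCurve], table: FeatureTable,
                  comparisons: Sequence[Comparison],
                  algorithm: str = "LogitBoost", n_stumps: int = 300,
                  learning_rate: float = 0.1, k: int = 10,
                  repeats: int = 10, seed: int = 0,
                  tolerance: float = 0.01,
                  extra_subsets: Optional[Dict[str, Sequence[str]]] = None,
                  greedy_backward: bool = False):
    """Evaluate candidate parameter combinations across both comparisons.

    The final subset is the smallest candidate whose minimum-over-
    comparisons AUC is within ``tolerance`` of the best such minimum.
    Returns ``(combinations_df, final_subset, performance_by_comparison)``.
    """
    sets = [c.chosen_subset for c in curves.values()]
    union: List[str] = []
    for s in sets:
        for p in s:
            if p not in union:
                union.append(p)
    candidates: Dict[str, List[str]] = {"union": union}
    for name, c in curves.items():
        candidates[f"only_{name}"] = list(c.chosen_subset)
    pvg = _family_members(union, "pvg")
    gaw = _family_members(union, "gaw")
    if pvg:
        candidates["pvg_only"] = pvg
    if gaw:
        candidates["gaw_only"] = gaw
    candidates["all_pruned"] = complete_parameters(table, comparisons)
    for name, subset in (extra_subsets or {}).items():
        unknown = [p for p in subset if p not in table.parameters]
        if unknown:
            raise KeyError(f"subset {name!r} contains unknown parameters "
                           f"{unknown}")
        candidates[name] = list(subset)

    cfg = BoostConfig(algorithm=algorithm, n_stumps=n_stumps,
                      learning_rate=learning_rate, seed=seed)

    def evaluate(subset):
        perfs = {}
        for comp in comparisons:
            X, y = comparison_arrays(table, comp, subset)
            perfs[comp.name] = crossval_evaluate(X, y, cfg, k=k,
                                                 repeats=repeats, seed=seed)
        return perfs

    rows = []
    perf_cache = {}
    for name, subset in candidates.items():
        if not subset:
            continue
        perfs = evaluate(subset)
        perf_cache[name] = perfs
        row = {"candidate": name, "n_parameters": len(subset),
               "parameters": "; ".join(subset),
               "min_auc": min(p.auc_mean for p in perfs.values())}
        for cname, p in perfs.items():
            row[f"auc_{cname}"] = p.auc_mean
            row[f"acc_{cname}"] = p.acc_mean
        rows.append(row)

    if greedy_backward and len(union) > 1:
        current = list(union)
        current_min = perf_cache["union"] if "union" in perf_cache else None
        best_min = min(p.auc_mean for p in current_min.values())
        improved = True
        while improved and len(current) > 1:
            improved = False
            for p in list(current):
                trial = [q for q in current if q != p]
                perfs = evaluate(trial)
                m = min(x.auc_mean for x in perfs.values())
                if m >= best_min - 1e-12:
                    current, best_min = trial, m
                    improved = True
                    break
        name = "greedy_backward"
        perfs = evaluate(current)
        perf_cache[name] = perfs
        row = {"candidate": name, "n_parameters": len(current),
               "parameters": "; ".join(current),
               "min_auc": min(p.auc_mean for p in perfs.values())}
        for cname, p in perfs.items():
            row[f"auc_{cname}"] = p.auc_mean
            row[f"acc_{cname}"] = p.acc_mean
        rows.append(row)
        candidates[name] = current

    df = pd.DataFrame(rows)
    best_min = df["min_auc"].max()
    ok = df[df["min_auc"] >= best_min - tolerance]
    ok = ok.sort_values(["n_parameters", "candidate"], kind="stable")
    final_name = ok["candidate"].iloc[0]
    final_subset = candidates[final_name]
    return df, final_subset, perf_cache[final_name]


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Everything the pipeline decides, plus the seeds to regenerate it."""

    step1: Optional[pd.DataFrame]
    winner: str
    step2: Optional[pd.DataFrame]
    chosen_stumps: int
    curves: Dict[str, StepwiseCurve]
    combinations: pd.DataFrame
    final_subset: List[str]
    final_performance: Dict[str, dict]
    pruning_discards: pd.DataFrame
    age_reports: Dict[str, pd.DataFrame]
    ledger: List[str]
    seed: int


def _load_table(cfg: dict, seed: int) -> FeatureTable:
    src = cfg.get("table", {})
    if "csv" in src:
        path = Path(src["csv"])
        if not path.exists():
            raise FileNotFoundError(f"feature table not found: {path}")
        return FeatureTable.from_csv(path)
    if "sample" in src:
        from .synth import sample_feature_table, TABLE_GROUP_STATS
        npg = src["sample"].get("n_per_group", {g: 30 for g in
                                                ("N_F", "FD_F", "N_M",
                                                 "FD_M")})
        return sample_feature_table(TABLE_GROUP_STATS, npg,
                                    seed=src["sample"].get("seed", seed))
    if "cohort" in src:
        from .synth import CohortSpec, RecordingSpec, iter_cohort
        from .features import extract_feature_table
        c = src["cohort"]
        spec = CohortSpec(
            n_per_group=c["n_per_group"],
            distributions={g: {k: tuple(v) for k, v in d.items()}
                           for g, d in c["distributions"].items()},
            base=RecordingSpec(**c.get("base", {})),
            n_cycles=c.get("n_cycles"),
            seed=c.get("seed", seed))
        recs, groups = [], []
        for rec, grp in iter_cohort(spec):
            recs.append(rec)
            groups.append(grp)
        return extract_feature_table(recs, groups)
    raise ValueError("config must provide table.csv, table.sample or "
                     "table.cohort")


def run_pipeline(config, output_dir=None) -> SelectionReport:
    """Run prune -> age screen -> steps 1-5 from a YAML config (path or
    dict) and write all reports to the output directory.  Fully
    reproducible from the config and its seeds."""
    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    cfg = config
    seed = int(cfg.get("seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "phonovib_out"))
    out.mkdir(parents=True, exist_ok=True)
    ledger: List[str] = [f"seed={seed}"]

    table = _load_table(cfg, seed)
    table.to_csv(out / "feature_table.csv")
    comparisons = default_comparisons(table)
    ledger.append("comparisons=" + ",".join(c.name for c in comparisons))

    # Redundancy pruning
    prune_cfg = cfg.get("prune", {})
    pruner = CorrelationPruner(threshold=prune_cfg.get("threshold", 0.9))
    pruned = pruner.fit_transform(table)
    discards = pruner.report_.to_frame()
    discards.to_csv(out / "correlation_discards.csv", index=False)
    pruned.to_csv(out / "pruned_table.csv")
    ledger.append(f"pruned {len(discards)} parameters at "
                  f"|PCC|>={pruner.threshold}")

    # Age screening (disordered groups, per sex) — advisory only
    age_reports: Dict[str, pd.DataFrame] = {}
    for comp in comparisons:
        sub = pruned.select_groups([comp.disordered])
        ages = sub.data["age"].to_numpy(dtype=float)
        if sub.n_subjects >= 4 and np.all(np.isfinite(ages)) \
                and np.all(ages > 0):
            rep = age_screen(sub)
            age_reports[comp.disordered] = rep.table
            rep.table.to_csv(out / f"age_screen_{comp.disordered}.csv",
                             index=False)
            n_non = int((~rep.table["negligible"]).sum())
            ledger.append(f"age screen {comp.disordered}: "
                          f"{n_non} non-negligible correlations")
        else:
            ledger.append(f"age screen {comp.disordered}: skipped "
                          "(no usable ages)")

    cv = cfg.get("cv", {})
    k, repeats = int(cv.get("k", 10)), int(cv.get("repeats", 10))
    boost = cfg.get("boosting", {})
    lr = float(boost.get("learning_rate", 0.1))
    n_stumps = int(boost.get("n_stumps", 300))

    # Step 1
    step1_df, winner = None, boost.get("algorithm")
    if cfg.get("step1", {}).get("enabled", True):
        step1_df, auto_winner = step1_compare_algorithms(
            pruned, comparisons, n_stumps=n_stumps, learning_rate=lr,
            k=k, repeats=repeats, seed=seed)
        step1_df.to_csv(out / "step1_algorithms.csv", index=False)
        if winner is None:
            winner = auto_winner
        ledger.append(f"step1 winner={auto_winner} "
                      f"(used: {winner})")
    if winner is None:
        winner = "LogitBoost"

    # Step 2
    step2_df, chosen_stumps = None, n_stumps
    s2 = cfg.get("step2", {})
    if s2.get("enabled", True):
        step2_df, chosen_stumps = step2_stump_sweep(
            pruned, comparisons, algorithm=winner,
            sizes=s2.get("grid", (1, 10, 50, 100, 200, 300, 400, 500)),
            learning_rate=lr, k=k, repeats=repeats, seed=seed,
            tolerance=float(s2.get("tolerance", 0.005)),
            override_size=s2.get("override_size"))
        step2_df.to_csv(out / "step2_stump_sweep.csv", index=False)
        ledger.append(f"step2 chosen_stumps={chosen_stumps}")

    # Steps 3 & 4
    sel = cfg.get("select", {})
    tol = float(sel.get("auc_tolerance", 0.005))
    curves: Dict[str, StepwiseCurve] = {}
    for comp in comparisons:
        curve = stepwise_select(pruned, comp, algorithm=winner,
                                n_stumps=chosen_stumps, learning_rate=lr,
                                k=k, repeats=repeats, seed=seed,
                                tolerance=tol,
                                max_size=sel.get("max_size"))
        curves[comp.name] = curve
        curve.to_frame().to_csv(out / f"stepwise_{comp.name}.csv",
                                index=False)
        ledger.append(f"step3/4 {comp.name}: chose {curve.chosen_size} "
                      "parameters")

    # Step 5
    comb_df, final_subset, final_perf = step5_combine(
        curves, pruned, comparisons, algorithm=winner,
        n_stumps=chosen_stumps, learning_rate=lr, k=k, repeats=repeats,
        seed=seed, tolerance=float(sel.get("combine_tolerance", 0.01)),
        extra_subsets=sel.get("extra_subsets"),
        greedy_backward=bool(sel.get("greedy_backward", False)))
    comb_df.to_csv(out / "step5_combinations.csv", index=False)
    ledger.append(f"step5 final subset of {len(final_subset)} parameters")

    report = SelectionReport(
        step1=step1_df, winner=winner, step2=step2_df,
        chosen_stumps=chosen_stumps, curves=curves, combinations=comb_df,
        final_subset=final_subset,
        final_performance={c: p.as_dict() for c, p in final_perf.items()},
        pruning_discards=discards, age_reports=age_reports, ledger=ledger,
        seed=seed)

    summary = {
        "seed": seed, "winner": winner, "chosen_stumps": chosen_stumps,
        "final_subset": final_subset,
        "final_performance": report.final_performance,
        "chosen_sizes": {n: c.chosen_size for n, c in curves.items()},
        "ledger": ledger,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2,
                                                sort_keys=True))

    if cfg.get("plots", False):
        _write_plots(report, out)
    return report


def _write_plots(report: SelectionReport, out: Path):
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:          # plotting is optional
        warnings.warn("matplotlib unavailable; skipping plots")
        return
    for name, curve in report.curves.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.errorbar(curve.sizes, curve.auc_mean, yerr=curve.auc_std,
                    label="AUC")
        ax.errorbar(curve.sizes, curve.acc_mean, yerr=curve.acc_std,
                    label="ACC")
        ax.axvline(curve.chosen_size, ls="--", color="grey")
        ax.set_xlabel("number of included parameters")
        ax.set_ylabel("performance")
        ax.set_title(f"Stepwise selection: {name}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"stepwise_{name}.png", dpi=120)
        plt.close(fig)
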