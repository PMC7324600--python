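"""Correlation-based redundancy pruning and age-covariate screening.

Parameters whose pairwise Pearson correlation (absolute value, pooled over
all subjects regardless of group) reaches the "very high" threshold of 0.9
are treated as redundant: the thresholded correlation graph is partitioned
into connected components, and within each component redundancy groups are
formed by greedy cover around representatives chosen from an explicit
priority list of widely-applied parameters (so every discarded parameter
correlates above threshold with the representative kept in its place).  A
small set of additional manual removals covers pairs known to be redundant
from prior work despite correlating just below the threshold.

Age screening computes per-parameter Pearson correlation against subject
age with a two-sided p-value and a Fisher-z 95% confidence interval; a
correlation is flagged negligible when |r| <= 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.sparse.csgraph import connected_components

from .tables import FeatureTable

__all__ = [
    "DEFAULT_PRIORITY",
    "DEFAULT_MANUAL_REMOVALS",
    "CorrelationReport",
    "AgeScreenReport",
    "CorrelationPruner",
    "correlation_matrix",
    "prune_redundant",
    "age_screen",
]

#: Default representative priority for redundancy groups: widely applied,
#: straightforward perturbation measures first, then the symmetry indices
#: that avoid sign-cancellation, then the contour-angle symmetry index.
DEFAULT_PRIORITY = [
    "MShim",
    "Jit(%)",
    "EPF",
    "PhAI [Mean]",
    "AmSI [Std]",
    "PhAI [Std]",
    "SpAI [Std]",
    "CASI^CA [Std]",
]

#: Manual removals for pairs correlating "high" (0.7-0.9) in clinical data:
#: removed parameter -> kept counterpart.
DEFAULT_MANUAL_REMOVALS = {
    "TP [Std]": "F0 [Std]",
    "DyRS [Mean]": "AmS [Mean]",
    "DyRSI [Mean]": "AmSI [Mean]",
}


@dataclass
class CorrelationReport:
    """Outcome of redundancy pruning."""

    pcc: pd.DataFrame                       # parameters x parameters
    groups: List[List[str]]                 # redundancy groups (size > 1)
    kept: Dict[int, str]                    # group index -> representative
    discarded: List[Dict[str, str]]         # {'parameter', 'kept', 'reason'}
    constant: List[str]                     # excluded undefined columns

    @property
    def discarded_parameters(self) -> List[str]:
        return [d["parameter"] for d in self.discarded]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.discarded,
                            columns=["parameter", "kept", "reason"])


@dataclass
class AgeScreenReport:
    """Per-parameter correlation against subject age."""

    table: pd.DataFrame   # parameter, pcc, p_value, ci_low, ci_high, negligible

    def to_frame(self) -> pd.DataFrame:
        return self.table


def correlation_matrix(table: FeatureTable,
                       parameters: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Pairwise Pearson correlations over all subjects pooled (no group
    split).  Constant (or all-NaN) columns yield NaN rows/columns; the
    caller flags and excludes them from grouping."""
    if table.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    cols = list(parameters) if parameters is not None else table.parameters
    df = table.data[cols].astype(float)
    return df.corr(method="pearson")


class CorrelationPruner:
    """Transformer that removes redundant parameters from a feature table.

    Parameters
    ----------
    threshold : float
        Absolute-correlation threshold for "very high" redundancy.
    priority : list of str, optional
        Representative priority; the first priority member present in a
        component is kept.  Passing an explicit list with names absent from
        the table raises; the default list is filtered silently.
    manual_removals : dict, optional
        Removed-parameter -> kept-parameter pairs applied after component
        pruning (already-absent names are skipped, making pruning
        idempotent).

    Attributes (after :meth:`fit`)
    ------------------------------
    report_ : CorrelationReport
    kept_parameters_ : list of str
    """

    def __init__(self, threshold: float = 0.9,
                 priority: Optional[Sequence[str]] = None,
                 manual_removals: Optional[Dict[str, str]] = None):
        self.threshold = threshold
        self.priority = priority
        self.manual_removals = manual_removals

    # -- sklearn-style parameter plumbing ---------------------------------
    def get_params(self, deep: bool = True):
        return {"threshold": self.threshold, "priority": self.priority,
                "manual_removals": self.manual_removals}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def fit(self, table: FeatureTable) -> "CorrelationPruner":
        pcc = correlation_matrix(table)
        params = list(pcc.columns)

        stds = table.data[params].astype(float).std()
        constant = [p for p in params
                    if not np.isfinite(stds[p]) or stds[p] == 0]
        active = [p for p in params if p not in constant]
        sub = pcc.loc[active, active].to_numpy()
        adj = (np.abs(sub) >= self.threshold) & np.isfinite(sub)
        np.fill_diagonal(adj, False)
        n_comp, labels = connected_components(adj, directed=False)

        if self.priority is not None:
            unknown = [p for p in self.priority if p not in params]
            if unknown:
                raise ValueError(f"priority names absent from table: "
                                 f"{unknown}")
            priority = list(self.priority)
        else:
            priority = [p for p in DEFAULT_PRIORITY if p in params]

        # Within each connected component, representatives are assigned by
        # greedy cover so that every discarded member correlates at
        # |PCC| >= threshold with *its own* representative (a long
        # correlation chain may otherwise link members whose direct
        # correlation is below threshold; such chains split into several
        # redundancy groups).
        groups: List[List[str]] = []
        kept: Dict[int, str] = {}
        discarded: List[Dict[str, str]] = []
        for c in range(n_comp):
            members = [active[i] for i in np.flatnonzero(labels == c)]
            if len(members) < 2:
                continue
            remaining = list(members)
            while remaining:
                rep = next((p for p in priority if p in remaining), None)
                if rep is None:
                    # Most central member: highest mean absolute
                    # correlation to the rest of the component.
                    block = np.abs(
                        pcc.loc[remaining, remaining].to_numpy())
                    rep = remaining[int(np.argmax(np.nansum(block,
                                                            axis=1)))]
                covered = [m for m in remaining if m == rep or
                           abs(pcc.loc[m, rep]) >= self.threshold]
                if len(covered) > 1:
                    gi = len(groups)
                    groups.append(covered)
                    kept[gi] = rep
                    for m in covered:
                        if m != rep:
                            discarded.append({
                                "parameter": m, "kept": rep,
                                "reason": f"|PCC| >= {self.threshold} "
                                          f"within redundancy group {gi} "
                                          f"(representative: {rep})"})
                remaining = [m for m in remaining if m not in covered]

        removed = {d["parameter"] for d in discarded}
        manual = self.manual_removals if self.manual_removals is not None \
            else DEFAULT_MANUAL_REMOVALS
        for rem, keep in manual.items():
            if rem in params and rem not in removed:
                discarded.append({
                    "parameter": rem, "kept": keep,
                    "reason": "manual removal (high correlation with kept "
                              "counterpart in prior clinical data)"})
                removed.add(rem)

        self.report_ = CorrelationReport(pcc=pcc, groups=groups, kept=kept,
                                         discarded=discarded,
                                         constant=constant)
        self.kept_parameters_ = [p for p in table.parameters
                                 if p not in removed]
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if not hasattr(self, "kept_parameters_"):
            raise RuntimeError("CorrelationPruner is not fitted")
        keep = [p for p in table.parameters if p in self.kept_parameters_]
        return table.subset(keep)

    def fit_transform(self, table: FeatureTable) -> FeatureTable:
        return self.fit(table).transform(table)


def prune_redundant(table: FeatureTable, very_high: float = 0.9,
                    manual_removals: Optional[Dict[str, str]] = None,
                    priority: Optional[Sequence[str]] = None
                    ) -> Tuple[CorrelationReport, FeatureTable]:
    """Functional wrapper over :class:`CorrelationPruner`."""
    pruner = CorrelationPruner(threshold=very_high, priority=priority,
                               manual_removals=manual_removals)
    reduced = pruner.fit_transform(table)
    return pruner.report_, reduced


def age_screen(table: FeatureTable,
               ages: Optional[Sequence[float]] = None,
               negligible: float = 0.3) -> AgeScreenReport:
    """Correlate every parameter with subject age.

    Uses the table's ``age`` column unless ``ages`` is given.  Requires at
    least 4 subjects (the Fisher-z confidence interval needs n > 3).
    """
    if ages is None:
        ages = table.data["age"].to_numpy(dtype=float)
    ages = np.asarray(ages, dtype=float)
    if ages.size != table.n_subjects:
        raise ValueError("one age per subject required")
    if np.any(~np.isfinite(ages)) or np.any(ages <= 0):
        raise ValueError("ages must be positive and finite")
    n = ages.size
    if n < 4:
        raise ValueError("need at least 4 subjects for the confidence "
                         "interval")
    rows = []
    for p in table.parameters:
        x = table.data[p].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 4 or np.std(x[ok]) == 0:
            rows.append({"parameter": p, "pcc": np.nan, "p_value": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "negligible": True})
            continue
        r, pval = sstats.pearsonr(x[ok], ages[ok])
        m = int(ok.sum())
        z = np.arctanh(np.clip(r, -0.999999, 0.999999))
        half = 1.959963984540054 / np.sqrt(m - 3)
        # Degenerate |r| ~ 1 would otherwise exclude r from its own CI.
        lo, hi = min(np.tanh(z - half), r), max(np.tanh(z + half), r)
        rows.append({"parameter": p, "pcc": float(r), "p_value": float(pval),
                     "ci_low": float(lo), "ci_high": float(hi),
                     "negligible": bool(abs(r) <= negligible)})
    return AgeScreenReport(table=pd.DataFrame(rows))
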