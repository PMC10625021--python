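"""Stratified descriptive tables with chi-square / one-way ANOVA tests.

Continuous variables are summarised as median (IQR), categorical ones as
count (percent); percentages are displayed rounded half-up to integers
while full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ProfileSpec", "profile", "chi_square", "one_way_anova",
           "charlson_category", "percent", "round_half_up",
           "CHARLSON_BINS", "DEFAULT_CHARLSON_WEIGHTS"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-wards (half-up)."""
    return int(math.floor(x + 0.5))


def percent(numerator: float, denominator: float) -> int:
    """Display-style integer percentage, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator)


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns ``(statistic, df, p)``; no continuity correction.  Zero row or
    column margins are an error (expected counts must be positive).
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (O < 0).any():
        raise ValueError("counts must be non-negative")
    r = O.sum(axis=1)
    c = O.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero marginal in contingency table")
    E = np.outer(r, c) / O.sum()
    stat = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA; returns ``(F, df_between, df_within, p)``."""
    gs = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 non-empty groups")
    N = sum(len(g) for g in gs)
    G = len(gs)
    df1, df2 = G - 1, N - G
    if df2 < 1:
        raise ValueError("ANOVA needs at least 1 residual degree of freedom")
    grand = sum(g.sum() for g in gs) / N
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    F = (ssb / df1) / (ssw / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


CHARLSON_BINS = ("0", "1-2", "3-4", ">=5")

# Weight table for the synthetic comorbidity flags; study scoring inputs
# are not published, so this is configuration, not an assertion.
DEFAULT_CHARLSON_WEIGHTS = {
    "undernutrition": 1,
    "morbid_obesity": 0,
    "sleep_apnoea": 0,
    "hypertension_cvd": 1,
    "diabetes": 1,
    "psychiatric": 1,
}


def charlson_category(flags: Mapping[str, int | bool],
                      weights: Mapping[str, float] = DEFAULT_CHARLSON_WEIGHTS) -> str:
    """Bin a weighted comorbidity sum into {0, 1-2, 3-4, >=5}."""
    total = 0.0
    for name, present in flags.items():
        if name not in weights:
            raise ValueError(f"no weight configured for comorbidity flag {name!r}")
        if present:
            total += float(weights[name])
    if total <= 0:
        return CHARLSON_BINS[0]
    if total <= 2:
        return CHARLSON_BINS[1]
    if total <= 4:
        return CHARLSON_BINS[2]
    return CHARLSON_BINS[3]


@dataclass(frozen=True)
class ProfileSpec:
    """One row-group of the stratified table.

    ``source`` is ``('covariate', column)``, ``('event_count', event_type)``
    (number of episodes of that type in the window) or
    ``('event_days', event_type)`` (total days).  For categorical specs
    either ``levels`` (explicit values) or numeric ``bins``/``bin_labels``
    may be given; continuous specs need neither.
    """

    name: str
    kind: str  # "categorical" | "continuous"
    source: tuple[str, str]
    levels: tuple | None = None
    bins: tuple | None = None          # right-closed edges, e.g. (0, 2, 5, 10, 20)
    bin_labels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown spec kind: {self.kind!r}")
        if self.source[0] not in ("covariate", "event_count", "event_days"):
            raise ValueError(f"unknown spec source: {self.source[0]!r}")


def _spec_values(spec: ProfileSpec, covariates: pd.DataFrame,
                 events: pd.DataFrame | None, ids: pd.Index) -> pd.Series:
    src, key = spec.source
    if src == "covariate":
        if key not in covariates.columns:
            raise KeyError(f"profile spec {spec.name!r}: missing covariate column {key!r}")
        return covariates.set_index("patient_id")[key].reindex(ids)
    if events is None:
        raise ValueError(f"profile spec {spec.name!r} needs an event table")
    ev = events[events["event_type"] == key]
    if src == "event_count":
        agg = ev.groupby("patient_id").size()
    else:
        agg = (ev["end_day"] - ev["start_day"]).groupby(ev["patient_id"]).sum()
    return agg.reindex(ids).fillna(0)


def _categorise(values: pd.Series, spec: ProfileSpec) -> pd.Series:
    if spec.bins is not None:
        edges = [-np.inf, *spec.bins, np.inf]
        labels = spec.bin_labels or [f"bin{i}" for i in range(len(edges) - 1)]
        return pd.cut(values.astype(float), bins=edges, labels=labels, right=True)
    return values


def profile(covariates: pd.DataFrame, events: pd.DataFrame | None,
            labels: pd.Series | pd.DataFrame,
            specs: Sequence[ProfileSpec]) -> pd.DataFrame:
    """Build the stratified descriptive table.

    ``labels`` maps patient_id to a cluster label (Series indexed by
    patient_id, or a DataFrame with ``patient_id``/``cluster`` columns).
    Returns a tidy frame with one row per variable x level (categorical) or
    per variable (continuous), columns per cluster plus overall, and the
    test statistic / df / p-value on the first row of each variable.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("patient_id")["cluster"]
    ids = labels.index
    clusters = sorted(labels.unique())
    rows = []
    for spec in specs:
        values = _spec_values(spec, covariates, events, ids)
        if spec.kind == "continuous":
            groups = [values[labels == c].dropna().to_numpy() for c in clusters]
            F, df1, df2, p = one_way_anova(groups)
            row = {"variable": spec.name, "level": "median (IQR)",
                   "statistic": F, "df": f"{df1},{df2}", "p_value": p}
            for c, g in zip(clusters, groups):
                row[f"cluster_{c}"] = _median_iqr(g)
            row["overall"] = _median_iqr(values.dropna().to_numpy())
            rows.append(row)
        else:
            cats = _categorise(values, spec)
            levels = (list(spec.levels) if spec.levels is not None
                      else list(cats.cat.categories) if hasattr(cats, "cat")
                      else sorted(pd.unique(cats.dropna())))
            table = np.array([[int(((cats == lv) & (labels == c)).sum())
                               for c in clusters] for lv in levels])
            # test on observed levels only; empty levels are still displayed
            occupied = table.sum(axis=1) > 0
            if occupied.sum() >= 2:
                stat, df, p = chi_square(table[occupied])
            else:
                stat, df, p = np.nan, 0, np.nan
            cluster_n = {c: int((labels == c).sum()) for c in clusters}
            for li, lv in enumerate(levels):
                row = {"variable": spec.name, "level": str(lv),
                       "statistic": stat if li == 0 else np.nan,
                       "df": str(df) if li == 0 else "",
                       "p_value": p if li == 0 else np.nan}
                for ci, c in enumerate(clusters):
                    n = table[li, ci]
                    row[f"cluster_{c}"] = f"{n} ({percent(n, cluster_n[c])})"
                total = int(table[li].sum())
                row["overall"] = f"{total} ({percent(total, len(ids))})"
                rows.append(row)
    return pd.DataFrame(rows)


def _median_iqr(x: np.ndarray) -> str:
    if len(x) == 0:
        return "-"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q1:g}, {q3:g})"
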