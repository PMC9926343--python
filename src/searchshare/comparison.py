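"""Group contrasts: two-sample t tests with FDR-adjusted Q values.

One comparison table is one FDR family: a row per requested symptom plus one
composite "overall" row, with Benjamini-Hochberg adjustment computed across
exactly those rows.  Welch's t is the default (the observed group spreads are
grossly unequal); the pooled variant is available.  Counties designated as
partial shortage areas are excluded from two-group contrasts by default but
retained in rankings and time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneracyError, ValidationError
from .types import CountyDesignation, SetShareSeries, ShareTable

logger = logging.getLogger(__name__)

OVERALL_ROW = "overall"

Predicate = Callable[[CountyDesignation], bool]


def _exclude_partial(d: CountyDesignation) -> bool:
    return d.shortage_status == "partial"


@dataclass
class ContrastDesign:
    """Two disjoint county groups defined by predicates over designations.

    ``unit`` selects the observation unit: ``county_period`` (each county
    contributes one observation per biweekly window) or ``county_mean`` (one
    span-averaged observation per county).
    """

    group_a: Predicate
    group_b: Predicate
    name_a: str = "a"
    name_b: str = "b"
    exclude: Predicate = _exclude_partial
    unit: str = "county_period"

    def __post_init__(self) -> None:
        if self.unit not in ("county_period", "county_mean"):
            raise ValidationError(f"unknown observation unit {self.unit!r}")

    def assign(self, designations: Mapping[str, CountyDesignation]) -> pd.Series:
        """Map county fips -> 'a' | 'b' for included counties."""
        labels: dict[str, str] = {}
        for fips, d in designations.items():
            if self.exclude(d):
                continue
            in_a, in_b = self.group_a(d), self.group_b(d)
            if in_a and in_b:
                raise ValidationError(
                    f"group predicates overlap on county {fips} "
                    f"({self.name_a} vs {self.name_b})"
                )
            if in_a:
                labels[fips] = "a"
            elif in_b:
                labels[fips] = "b"
        out = pd.Series(labels, dtype="object")
        if (out == "a").sum() == 0:
            raise DegeneracyError(f"group A is empty (predicate {self.name_a!r})")
        if (out == "b").sum() == 0:
            raise DegeneracyError(f"group B is empty (predicate {self.name_b!r})")
        return out


def _status_pred(status: str) -> Predicate:
    return lambda d: d.shortage_status == status

def _and(p: Predicate, q: Predicate) -> Predicate:
    return lambda d: p(d) and q(d)

def _urban_pred(tier: str) -> Predicate:
    return lambda d: d.urban3 == tier


#: named designs for the standard stratified contrast families.  "urban"
#: means the micropolitan tier; the most-urban comparator is the large
#: central metro tier (nchs6 = 1).
NAMED_CONTRASTS: dict[str, Callable[[], ContrastDesign]] = {
    "shortage_vs_nonshortage": lambda: ContrastDesign(
        _status_pred("shortage"), _status_pred("nonshortage"),
        name_a="shortage", name_b="nonshortage",
    ),
    "rural_shortage_vs_rural_nonshortage": lambda: ContrastDesign(
        _and(_urban_pred("rural"), _status_pred("shortage")),
        _and(_urban_pred("rural"), _status_pred("nonshortage")),
        name_a="rural shortage", name_b="rural nonshortage",
    ),
    "urban_shortage_vs_urban_nonshortage": lambda: ContrastDesign(
        _and(_urban_pred("micropolitan"), _status_pred("shortage")),
        _and(_urban_pred("micropolitan"), _status_pred("nonshortage")),
        name_a="urban shortage", name_b="urban nonshortage",
    ),
    "rural_vs_urban_shortage": lambda: ContrastDesign(
        _and(_urban_pred("rural"), _status_pred("shortage")),
        _and(_urban_pred("micropolitan"), _status_pred("shortage")),
        name_a="rural shortage", name_b="urban shortage",
    ),
    "rural_vs_metro_shortage": lambda: ContrastDesign(
        _and(_urban_pred("rural"), _status_pred("shortage")),
        _and(lambda d: d.is_large_central_metro, _status_pred("shortage")),
        name_a="rural shortage", name_b="metro shortage",
    ),
}


def named_contrast(name: str, unit: str = "county_period") -> ContrastDesign:
    try:
        design = NAMED_CONTRASTS[name]()
    except KeyError as exc:
        raise ValidationError(
            f"unknown contrast {name!r}; known: {sorted(NAMED_CONTRASTS)}"
        ) from exc
    design.unit = unit
    return design


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def two_group_ttest(
    x: Sequence[float], y: Sequence[float], variant: str = "welch"
) -> TTestResult:
    """Two-sided two-sample t test.

    ``variant="welch"`` uses unequal variances with Welch-Satterthwaite
    degrees of freedom; ``"pooled"`` assumes equal variances with
    ``df = n_x + n_y - 2``.  Conventions for the zero-variance degeneracies:
    both variances zero with equal means gives ``t = 0, p = 1``; with unequal
    means, ``p = 0`` and the result is flagged degenerate.
    """
    if variant not in ("welch", "pooled"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise DegeneracyError("each group needs at least 2 observations")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if xa.mean() == ya.mean():
            return TTestResult(t=0.0, df=float(xa.size + ya.size - 2), p=1.0,
                               degenerate=True)
        sign = 1.0 if xa.mean() > ya.mean() else -1.0
        return TTestResult(t=sign * np.inf, df=float(xa.size + ya.size - 2), p=0.0,
                           degenerate=True)
    res = stats.ttest_ind(xa, ya, equal_var=(variant == "pooled"))
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def bh_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR-adjusted Q values by the Benjamini-Hochberg step-up procedure.

    ``q(i) = min_{j >= rank(i)} p(j) * m / j`` over the ascending order,
    capped at 1; ties share ranks stably.  ``method="by"`` applies the
    Benjamini-Yekutieli correction (multiply by the harmonic number) for
    arbitrary dependence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be 1-d")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    scale = float(np.sum(1.0 / np.arange(1, m + 1))) if method == "by" else 1.0
    if method not in ("bh", "by"):
        raise ValidationError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1) * scale
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class ComparisonRow:
    symptom_id: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    df: float
    p_value: float
    q_value: float
    direction: str
    degenerate: bool = False


@dataclass
class ComparisonTable:
    """Ordered rows of one contrast family plus its design metadata."""

    rows: list[ComparisonRow]
    name_a: str
    name_b: str
    n_counties_a: int
    n_counties_b: int
    unit: str
    alpha: float = 0.05
    fdr_method: str = "bh"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        return df.rename(
            columns={"t_stat": "t", "p_value": "p", "q_value": "q"}
        )

    def row(self, symptom_id: str) -> ComparisonRow:
        for r in self.rows:
            if r.symptom_id == symptom_id:
                return r
        raise KeyError(symptom_id)

    def significant(self) -> list[ComparisonRow]:
        return [r for r in self.rows if np.isfinite(r.q_value) and r.q_value < self.alpha]


def _unit_observations(df: pd.DataFrame, value_col: str, unit: str) -> np.ndarray:
    vals = df[value_col]
    if unit == "county_mean":
        vals = df.groupby("county_fips")[value_col].mean()
    return vals.dropna().to_numpy()


def _make_row(
    label: str,
    x: np.ndarray,
    y: np.ndarray,
    variant: str,
    name_a: str,
    name_b: str,
) -> ComparisonRow:
    mean_a = float(np.mean(x)) if x.size else np.nan
    mean_b = float(np.mean(y)) if y.size else np.nan
    sd_a = float(np.std(x, ddof=1)) if x.size > 1 else np.nan
    sd_b = float(np.std(y, ddof=1)) if y.size > 1 else np.nan
    if x.size < 2 or y.size < 2:
        logger.warning("row %r has a group with <2 observations; stats withheld", label)
        return ComparisonRow(label, x.size, y.size, mean_a, sd_a, mean_b, sd_b,
                             np.nan, np.nan, np.nan, np.nan, "none", degenerate=True)
    res = two_group_ttest(x, y, variant=variant)
    if np.isnan(mean_a) or mean_a == mean_b:
        direction = "none"
    else:
        direction = name_a if mean_a > mean_b else name_b
    return ComparisonRow(label, x.size, y.size, mean_a, sd_a, mean_b, sd_b,
                         res.t, res.df, res.p, np.nan, direction,
                         degenerate=res.degenerate)


def _attach_q(rows: list[ComparisonRow], method: str) -> list[ComparisonRow]:
    idx = [i for i, r in enumerate(rows) if np.isfinite(r.p_value)]
    if idx:
        q = bh_fdr([rows[i].p_value for i in idx], method=method)
        for j, i in enumerate(idx):
            r = rows[i]
            qv = float(q[j])
            assert qv >= r.p_value - 1e-12, "BH can only raise p values"
            rows[i] = ComparisonRow(**{**vars(r), "q_value": qv})
    return rows


def compare_groups(
    shares: ShareTable,
    set_series: SetShareSeries,
    design: ContrastDesign,
    designations: Mapping[str, CountyDesignation],
    symptoms: Sequence[str],
    alpha: float = 0.05,
    fdr_method: str = "bh",
    variant: str = "welch",
) -> ComparisonTable:
    """One contrast family: per-symptom rows plus the composite overall row.

    Unit observations come from ``design.unit``; Q values are BH-adjusted
    across all rows of this table only.
    """
    labels = design.assign(designations)
    observed = set(shares.data["county_fips"].unique())
    labels = labels[labels.index.isin(observed)]
    for grp, name in (("a", design.name_a), ("b", design.name_b)):
        if (labels == grp).sum() == 0:
            raise DegeneracyError(
                f"group {grp.upper()} has no observed counties (predicate {name!r})"
            )
    sdf = shares.data.copy()
    sdf["_grp"] = sdf["county_fips"].map(labels)
    sdf = sdf[sdf["_grp"].notna()]
    cdf = set_series.data.copy()
    cdf["_grp"] = cdf["county_fips"].map(labels)
    cdf = cdf[cdf["_grp"].notna()]

    rows: list[ComparisonRow] = []
    for s in symptoms:
        sub = sdf[sdf["symptom_id"] == s]
        x = _unit_observations(sub[sub["_grp"] == "a"], "share", design.unit)
        y = _unit_observations(sub[sub["_grp"] == "b"], "share", design.unit)
        rows.append(_make_row(s, x, y, variant, design.name_a, design.name_b))
    x = _unit_observations(cdf[cdf["_grp"] == "a"], "set_share", design.unit)
    y = _unit_observations(cdf[cdf["_grp"] == "b"], "set_share", design.unit)
    rows.append(_make_row(OVERALL_ROW, x, y, variant, design.name_a, design.name_b))

    rows = _attach_q(rows, fdr_method)
    return ComparisonTable(
        rows=rows,
        name_a=design.name_a,
        name_b=design.name_b,
        n_counties_a=int((labels == "a").sum()),
        n_counties_b=int((labels == "b").sum()),
        unit=design.unit,
        alpha=alpha,
        fdr_method=fdr_method,
    )


def temporal_contrast(
    shares: ShareTable,
    set_series: SetShareSeries,
    designations: Mapping[str, CountyDesignation],
    cutoff: object,
    symptoms: Sequence[str],
    county_predicate: Predicate | None = None,
    unit: str = "county_period",
    alpha: float = 0.05,
    fdr_method: str = "bh",
    variant: str = "welch",
) -> ComparisonTable:
    """Pre vs post contrast at a cutoff date within a county selection.

    Observations with ``period_start < cutoff`` form the pre group, the rest
    the post group; both sides must contain at least 2 biweekly periods.
    """
    cutoff_ts = pd.Timestamp(cutoff)
    if county_predicate is None:
        selected = set(designations)
    else:
        selected = {f for f, d in designations.items() if county_predicate(d)}
    if not selected:
        raise DegeneracyError("county predicate selects no counties")

    sdf = shares.data[shares.data["county_fips"].isin(selected)].copy()
    cdf = set_series.data[set_series.data["county_fips"].isin(selected)].copy()
    periods = pd.DatetimeIndex(pd.to_datetime(sdf["period_start"]).unique())
    n_pre = int((periods < cutoff_ts).sum())
    n_post = int((periods >= cutoff_ts).sum())
    if n_pre < 2 or n_post < 2:
        raise DegeneracyError(
            f"cutoff {cutoff_ts.date()} leaves {n_pre} pre / {n_post} post periods; "
            "need >= 2 on each side"
        )

    def split(df: pd.DataFrame, value_col: str) -> tuple[np.ndarray, np.ndarray]:
        ts = pd.to_datetime(df["period_start"])
        return (
            _unit_observations(df[ts < cutoff_ts], value_col, unit),
            _unit_observations(df[ts >= cutoff_ts], value_col, unit),
        )

    rows: list[ComparisonRow] = []
    for s in symptoms:
        x, y = split(sdf[sdf["symptom_id"] == s], "share")
        rows.append(_make_row(s, x, y, variant, "pre", "post"))
    x, y = split(cdf, "set_share")
    rows.append(_make_row(OVERALL_ROW, x, y, variant, "pre", "post"))

    rows = _attach_q(rows, fdr_method)
    return ComparisonTable(
        rows=rows,
        name_a="pre",
        name_b="post",
        n_counties_a=len(selected),
        n_counties_b=len(selected),
        unit=unit,
        alpha=alpha,
        fdr_method=fdr_method,
    )


def rank_counties(
    set_series: SetShareSeries,
    designations: Mapping[str, CountyDesignation],
    k: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k and bottom-k counties by span-mean composite share.

    All observed counties participate — including partial shortage areas,
    which only two-group contrasts exclude.  Ties break by ascending FIPS.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    means = (
        set_series.data.groupby("county_fips")["set_share"].mean().dropna().reset_index()
    )
    means = means.rename(columns={"set_share": "mean_share"})
    means["shortage_status"] = means["county_fips"].map(
        lambda f: designations[f].shortage_status if f in designations else "unknown"
    )
    if k > len(means):
        logger.warning("k=%d exceeds %d ranked counties; truncating", k, len(means))
        k = len(means)
    top = (
        means.sort_values(["mean_share", "county_fips"], ascending=[False, True])
        .head(k)
        .reset_index(drop=True)
    )
    bottom = (
        means.sort_values(["mean_share", "county_fips"], ascending=[True, True])
        .head(k)
        .reset_index(drop=True)
    )
    return top, bottom


def group_time_series(
    set_series: SetShareSeries,
    groupings: Mapping[str, Predicate],
    designations: Mapping[str, CountyDesignation],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-period group means with normal-approximation confidence bands.

    Returns a tidy frame (period_start, group, n, mean, se, lo, hi).  A
    period where a group has a single county reports a missing SE and band.
    """
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    frames = []
    for name, pred in groupings.items():
        members = {f for f, d in designations.items() if pred(d)}
        sub = set_series.data[set_series.data["county_fips"].isin(members)]
        if sub["set_share"].notna().sum() == 0:
            raise DegeneracyError(f"group {name!r} has no observations")
        g = sub.groupby("period_start")["set_share"]
        agg = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
        agg["group"] = name
        with np.errstate(invalid="ignore", divide="ignore"):
            agg["se"] = np.where(agg["n"] > 1, agg["sd"] / np.sqrt(agg["n"]), np.nan)
        agg["lo"] = agg["mean"] - z * agg["se"]
        agg["hi"] = agg["mean"] + z * agg["se"]
        frames.append(agg[["period_start", "group", "n", "mean", "se", "lo", "hi"]])
    return pd.concat(frames, ignore_index=True)


def choropleth_export(
    set_series: SetShareSeries, designations: Mapping[str, CountyDesignation]
) -> pd.DataFrame:
    """Per-county span-mean composite share (FIPS, share, status) for mapping."""
    means = (
        set_series.data.groupby("county_fips")["set_share"].mean().dropna().reset_index()
    )
    means["shortage_status"] = means["county_fips"].map(
        lambda f: designations[f].shortage_status if f in designations else "unknown"
    )
    return means.rename(columns={"set_share": "mean_share"})
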