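"""The core statistic: each symptom's share of all symptom searching.

Dividing a symptom's weight by the summed weight of all symptoms within the
same county-period cancels the unknown per-region scale factor of the raw
panel, which is what makes inconsistently scaled weights comparable across
counties at all.  Shares are reported on the 0-100 percent scale.

Missing (privacy-suppressed) cells are excluded from the denominator rather
than imputed as zero: suppression reflects a privacy threshold, not absence
of searching, and a zero imputation would bias observed symptoms' shares
upward.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import SetShareSeries, ShareTable, SymptomWeightPanel


def share_of_search(panel: SymptomWeightPanel) -> ShareTable:
    """Compute per (county, period, symptom) share-of-search percentages.

    ``share = 100 * w / total`` with the total summed over the non-missing
    weights of that county-period.  If the total is zero, every share in the
    county-period is missing.  Non-missing shares in a county-period sum to
    100 within 1e-9 by construction.
    """
    df = panel.data
    total = df.groupby(["county_fips", "period_start"], sort=False)["weight"].transform(
        "sum"
    )  # skips NaN; all-missing group -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(
            df["weight"].notna() & (total > 0),
            100.0 * df["weight"] / total,
            np.nan,
        )
    out = df[["county_fips", "period_start", "symptom_id"]].copy()
    out["share"] = share
    return ShareTable(data=out, registry=panel.registry).validate()


def set_share(shares: ShareTable, symptom_set: Iterable[str]) -> SetShareSeries:
    """Composite share of a symptom set per county-period.

    The composite is the sum of the member shares; it is missing only when
    every member share is missing in that county-period.
    """
    members = tuple(dict.fromkeys(symptom_set))
    if len(members) == 0:
        raise ValidationError("symptom set must be nonempty")
    unknown = set(members) - set(shares.registry.symptom_ids)
    if unknown:
        raise ValidationError(f"symptom set ids not in registry: {sorted(unknown)[:5]}")

    df = shares.data
    member_rows = df[df["symptom_id"].isin(members)]
    agg = (
        member_rows.groupby(["county_fips", "period_start"], sort=False)["share"]
        .sum(min_count=1)
        .rename("set_share")
        .reset_index()
    )
    all_cp = df[["county_fips", "period_start"]].drop_duplicates()
    out = all_cp.merge(agg, on=["county_fips", "period_start"], how="left")
    return SetShareSeries(
        data=out.reset_index(drop=True), member_ids=members
    ).validate()


def window_mean(
    table: ShareTable | SetShareSeries, window: tuple[object, object]
) -> pd.DataFrame:
    """Per-county mean over the half-open date window ``[start, end)``.

    For a :class:`ShareTable` the mean is additionally per symptom.  Counties
    (or county-symptom pairs) with no observed periods inside the window are
    omitted.  An empty overlap is an error.
    """
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if isinstance(table, ShareTable):
        df, keys, value = table.data, ["county_fips", "symptom_id"], "share"
    else:
        df, keys, value = table.data, ["county_fips"], "set_share"
    periods = pd.to_datetime(df["period_start"])
    sel = df[(periods >= start) & (periods < end)]
    if sel.empty:
        raise ValidationError("window does not overlap the panel span")
    out = sel.groupby(keys, sort=True)[value].mean().dropna().reset_index()
    return out.rename(columns={value: f"mean_{value}"})
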