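"""Readers, writers and resampling for the three input files.

The panel reader speaks the public search-trends dialect: one wide CSV row
per county x date, one column per symptom topic (header optionally prefixed
``symptom:``), empty cell = privacy-suppressed.  Designation inputs are a
shortage-status CSV (geographic-area designations only) and an urbanization
code CSV.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InputOutputError, ValidationError
from .types import (
    CountyDesignation,
    SymptomRegistry,
    SymptomWeightPanel,
    normalize_fips,
)

_COUNTY_KEYS = ("county_fips", "fips", "sub_region_2_code")
_DATE_KEYS = ("date", "period_start", "week_start")
_SYMPTOM_PREFIX = "symptom:"


def _read_csv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError as exc:
        raise InputOutputError(f"cannot read {path}: {exc}") from exc


def _find_column(columns: Iterable[str], candidates: tuple[str, ...]) -> str | None:
    lower = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    return None


def read_symptom_panel(
    path: str | os.PathLike,
    registry_mode: str = "infer",
    registry: SymptomRegistry | None = None,
) -> SymptomWeightPanel:
    """Read a wide search-trends CSV into a long-form weight panel.

    Parameters
    ----------
    path :
        Wide CSV with a county-code column, a date column and one column per
        symptom topic.  Empty cells become missing weights (never zero).
    registry_mode :
        ``"infer"`` builds the registry from the symptom headers; ``"strict"``
        requires ``registry`` and rejects headers outside it.
    registry :
        Registry to validate against in strict mode.

    Raises
    ------
    FormatError
        Missing key columns or a non-numeric weight cell.
    ValidationError
        Negative weight or duplicate (county, date) row.
    """
    if registry_mode not in ("infer", "strict"):
        raise ValidationError(f"unknown registry_mode {registry_mode!r}")
    if registry_mode == "strict" and registry is None:
        raise ValidationError("strict registry_mode requires a registry")

    raw = _read_csv(path)
    county_col = _find_column(raw.columns, _COUNTY_KEYS)
    date_col = _find_column(raw.columns, _DATE_KEYS)
    if county_col is None or date_col is None:
        raise FormatError(
            f"panel file {path} lacks county/date key columns "
            f"(expected one of {_COUNTY_KEYS} and one of {_DATE_KEYS})"
        )

    dup = raw.duplicated(subset=[county_col, date_col])
    if dup.any():
        bad = raw.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate row for county {bad[county_col]} on {bad[date_col]}"
        )

    symptom_cols = [c for c in raw.columns if c not in (county_col, date_col)]
    if not symptom_cols:
        raise FormatError(f"panel file {path} has no symptom columns")
    ids = [
        c[len(_SYMPTOM_PREFIX):] if c.lower().startswith(_SYMPTOM_PREFIX) else c
        for c in symptom_cols
    ]
    if registry_mode == "strict":
        unknown = set(ids) - set(registry.symptom_ids)  # type: ignore[union-attr]
        if unknown:
            raise ValidationError(
                f"symptom headers not in registry: {sorted(unknown)[:5]}"
            )
    else:
        registry = SymptomRegistry.from_ids(ids)

    long = raw.melt(
        id_vars=[county_col, date_col],
        value_vars=symptom_cols,
        var_name="_column",
        value_name="_raw",
    )
    long["symptom_id"] = long["_column"].map(dict(zip(symptom_cols, ids)))
    stripped = long["_raw"].astype(str).str.strip()
    weight = pd.to_numeric(stripped.replace("", np.nan), errors="coerce")
    bad_cells = weight.isna() & (stripped != "")
    if bad_cells.any():
        bad = long.loc[bad_cells].iloc[0]
        raise FormatError(
            f"non-numeric weight {bad['_raw']!r} for county "
            f"{bad[county_col]} / {bad[date_col]} / {bad['symptom_id']}"
        )

    df = pd.DataFrame(
        {
            "county_fips": long[county_col].map(normalize_fips),
            "period_start": pd.to_datetime(long[date_col]),
            "symptom_id": long["symptom_id"],
            "weight": weight.astype(float),
        }
    )
    return SymptomWeightPanel(data=df, registry=registry).validate()


def write_panel(panel: SymptomWeightPanel, path: str | os.PathLike) -> None:
    """Write a panel back out in the wide dialect (empty cell = missing)."""
    wide = panel.data.pivot(
        index=["county_fips", "period_start"], columns="symptom_id", values="weight"
    )
    ordered = [s for s in panel.registry.symptom_ids if s in wide.columns]
    wide = wide[ordered]
    wide.columns = [f"{_SYMPTOM_PREFIX}{c}" for c in wide.columns]
    out = wide.reset_index().rename(columns={"period_start": "date"})
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def resample_to_biweekly(
    panel: SymptomWeightPanel, anchor: object
) -> SymptomWeightPanel:
    """Aggregate a daily or weekly panel into 14-day half-open windows.

    Weights within each window ``[anchor + 14k, anchor + 14(k+1))`` are summed
    per (county, symptom).  A window cell is missing only if every
    contributing cell is missing.  Windows not fully covered by the input span
    (including partial trailing windows) are dropped.

    Raises
    ------
    ValidationError
        Irregular input periods, or no complete window (e.g. anchor after the
        last observed date).
    """
    df = panel.data
    dates = pd.DatetimeIndex(sorted(pd.to_datetime(df["period_start"]).unique()))
    if len(dates) < 2:
        raise ValidationError("cannot infer input period from fewer than 2 dates")
    diffs = np.unique(np.diff(dates.to_numpy()).astype("timedelta64[D]").astype(int))
    if len(diffs) != 1 or diffs[0] not in (1, 7):
        raise ValidationError(
            f"input periods are irregular (observed day gaps {diffs.tolist()}); "
            "expected a constant 1- or 7-day step"
        )
    step = int(diffs[0])
    anchor_ts = pd.Timestamp(anchor)

    work = df.copy()
    work["period_start"] = pd.to_datetime(work["period_start"])
    offset = (work["period_start"] - anchor_ts).dt.days
    work = work[offset >= 0].copy()
    work["_window"] = (offset[offset >= 0] // 14).astype(int)

    # a window is complete when its end falls inside the observed span
    # (the last input period covers [last_date, last_date + step))
    span_end = dates[-1] + pd.Timedelta(days=step)
    window_end = anchor_ts + pd.to_timedelta(14 * (work["_window"] + 1), unit="D")
    work = work[window_end <= span_end]
    if work.empty:
        raise ValidationError(
            "resampling produced no complete biweekly window "
            "(anchor outside or too close to the end of the observed span)"
        )

    agg = (
        work.groupby(["county_fips", "symptom_id", "_window"], sort=False)["weight"]
        .sum(min_count=1)
        .reset_index()
    )
    agg["period_start"] = anchor_ts + pd.to_timedelta(14 * agg["_window"], unit="D")
    out = agg[["county_fips", "period_start", "symptom_id", "weight"]]
    return SymptomWeightPanel(
        data=out.reset_index(drop=True), registry=panel.registry
    ).validate(require_biweekly=True)


_STATUS_ALIASES = {
    "shortage": "shortage",
    "partial": "partial",
    "partial shortage": "partial",
    "nonshortage": "nonshortage",
    "non-shortage": "nonshortage",
    "none": "nonshortage",
}


def read_designations(
    shortage_path: str | os.PathLike, nchs_path: str | os.PathLike
) -> dict[str, CountyDesignation]:
    """Merge shortage-status and urbanization-code files into one mapping.

    The shortage file needs ``fips`` and ``status`` columns; if a
    ``designation_type`` column is present, only geographic-area rows are
    used (population-group and facility designations are ignored).  The
    urbanization file needs ``fips`` and ``nchs6``.  A county present in only
    one file is retained with the other field flagged unknown.
    """
    sdf = _read_csv(shortage_path)
    ndf = _read_csv(nchs_path)

    s_fips = _find_column(sdf.columns, ("fips", "county_fips"))
    s_status = _find_column(sdf.columns, ("status", "shortage_status"))
    if s_fips is None or s_status is None:
        raise FormatError(f"shortage file {shortage_path} lacks fips/status columns")
    type_col = _find_column(sdf.columns, ("designation_type", "type"))
    if type_col is not None:
        sdf = sdf[sdf[type_col].str.lower().str.contains("geographic")]

    status_by_fips: dict[str, str] = {}
    for _, row in sdf.iterrows():
        fips = normalize_fips(row[s_fips])
        raw_status = str(row[s_status]).strip().lower()
        if raw_status not in _STATUS_ALIASES:
            raise ValidationError(
                f"unparseable shortage status {row[s_status]!r} for county {fips}"
            )
        status_by_fips[fips] = _STATUS_ALIASES[raw_status]

    n_fips = _find_column(ndf.columns, ("fips", "county_fips"))
    n_code = _find_column(ndf.columns, ("nchs6", "nchs_code", "code"))
    if n_fips is None or n_code is None:
        raise FormatError(f"urbanization file {nchs_path} lacks fips/nchs6 columns")
    nchs_by_fips: dict[str, int] = {}
    for _, row in ndf.iterrows():
        fips = normalize_fips(row[n_fips])
        try:
            code = int(float(row[n_code]))
        except ValueError as exc:
            raise ValidationError(
                f"non-integer nchs6 code {row[n_code]!r} for county {fips}"
            ) from exc
        if code not in range(1, 7):
            raise ValidationError(f"nchs6 code {code} outside 1-6 for county {fips}")
        nchs_by_fips[fips] = code

    out: dict[str, CountyDesignation] = {}
    for fips in sorted(set(status_by_fips) | set(nchs_by_fips)):
        out[fips] = CountyDesignation(
            county_fips=fips,
            shortage_status=status_by_fips.get(fips, "unknown"),
            nchs6=nchs_by_fips.get(fips),
        )
    return out


def read_designations_combined(path: str | os.PathLike) -> dict[str, CountyDesignation]:
    """Read a single CSV with columns (fips, status, nchs6); blanks = unknown."""
    df = _read_csv(path)
    fips_col = _find_column(df.columns, ("fips", "county_fips"))
    status_col = _find_column(df.columns, ("status", "shortage_status"))
    code_col = _find_column(df.columns, ("nchs6", "nchs_code"))
    if fips_col is None or status_col is None or code_col is None:
        raise FormatError(f"designation file {path} lacks fips/status/nchs6 columns")
    out: dict[str, CountyDesignation] = {}
    for _, row in df.iterrows():
        fips = normalize_fips(row[fips_col])
        raw_status = str(row[status_col]).strip().lower()
        if raw_status == "":
            status = "unknown"
        elif raw_status in _STATUS_ALIASES or raw_status == "unknown":
            status = _STATUS_ALIASES.get(raw_status, "unknown")
        else:
            raise ValidationError(
                f"unparseable shortage status {row[status_col]!r} for county {fips}"
            )
        raw_code = str(row[code_col]).strip()
        code = int(float(raw_code)) if raw_code else None
        if code is not None and code not in range(1, 7):
            raise ValidationError(f"nchs6 code {code} outside 1-6 for county {fips}")
        out[fips] = CountyDesignation(fips, status, code)
    return out


def write_designations(
    designations: Mapping[str, CountyDesignation], path: str | os.PathLike
) -> None:
    rows = [
        {
            "fips": d.county_fips,
            "status": d.shortage_status,
            "nchs6": "" if d.nchs6 is None else d.nchs6,
        }
        for _, d in sorted(designations.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_symptom_list(path: str | os.PathLike) -> tuple[str, ...]:
    """Read a symptom-id list: one id per line, or a CSV with a symptom_id column."""
    df = _read_csv(path)
    col = _find_column(df.columns, ("symptom_id", "symptom", "topic", "id"))
    if col is not None:
        ids = [s.strip() for s in df[col].tolist() if s.strip()]
    else:
        # headerless plain list: the "header" is the first id
        ids = [df.columns[0].strip()] + [
            s.strip() for s in df.iloc[:, 0].tolist() if s.strip()
        ]
    if not ids:
        raise FormatError(f"symptom list {path} is empty")
    return tuple(ids)


def write_symptom_list(ids: Iterable[str], path: str | os.PathLike) -> None:
    pd.DataFrame({"symptom_id": list(ids)}).to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any tidy table; format chosen by suffix (.parquet or CSV)."""
    path = os.fspath(path)
    if path.endswith(".parquet"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
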