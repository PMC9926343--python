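"""Core domain types shared across the pipeline.

All tabular types are thin wrappers around long-form :class:`pandas.DataFrame`
objects with a fixed column contract, plus a ``validate`` method that enforces
the documented invariants.  County identifiers are always 5-character
zero-padded FIPS strings: New England codes start with ``0`` and would be
silently corrupted by a numeric representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: column contract for long-form weight panels
PANEL_COLUMNS = ("county_fips", "period_start", "symptom_id", "weight")
#: column contract for share tables
SHARE_COLUMNS = ("county_fips", "period_start", "symptom_id", "share")
#: column contract for composite (symptom-set) share series
SET_SHARE_COLUMNS = ("county_fips", "period_start", "set_share")

#: collapse of the 6-tier urbanization code to the 3-tier scheme
NCHS6_TO_URBAN3 = {1: "metro", 2: "metro", 3: "metro", 4: "metro",
                   5: "micropolitan", 6: "rural"}

SHORTAGE_STATUSES = ("shortage", "partial", "nonshortage")


def normalize_fips(value: object) -> str:
    """Return ``value`` as a 5-character zero-padded FIPS string."""
    s = str(value).strip()
    if s.endswith(".0"):  # tolerate float-round-tripped codes
        s = s[:-2]
    return s.zfill(5)


@dataclass(frozen=True)
class SymptomRegistry:
    """Ordered catalogue of symptom topics present in a panel.

    Parameters
    ----------
    symptom_ids :
        Unique, nonempty ordered ids.
    display_names :
        Optional id -> human-readable name mapping; defaults to identity.
    """

    symptom_ids: tuple[str, ...]
    display_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.symptom_ids) == 0:
            raise ValidationError("symptom registry must be nonempty")
        if len(set(self.symptom_ids)) != len(self.symptom_ids):
            raise ValidationError("symptom ids must be unique")

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "SymptomRegistry":
        return cls(symptom_ids=tuple(str(i) for i in ids))

    def __contains__(self, symptom_id: str) -> bool:
        return symptom_id in set(self.symptom_ids)

    def __len__(self) -> int:
        return len(self.symptom_ids)

    def display_name(self, symptom_id: str) -> str:
        return dict(self.display_names).get(symptom_id, symptom_id)


@dataclass
class SymptomWeightPanel:
    """Long-form search-weight panel.

    ``data`` has columns ``(county_fips, period_start, symptom_id, weight)``;
    ``weight`` is a nonnegative float with ``NaN`` meaning privacy-suppressed
    (missing), never observed-zero.
    """

    data: pd.DataFrame
    registry: SymptomRegistry

    def validate(self, require_biweekly: bool = False) -> "SymptomWeightPanel":
        df = self.data
        missing_cols = set(PANEL_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValidationError(f"panel is missing columns {sorted(missing_cols)}")
        w = df["weight"]
        if (w.dropna() < 0).any():
            bad = df.loc[w < 0].iloc[0]
            raise ValidationError(
                "negative weight for county "
                f"{bad['county_fips']} / {bad['period_start']} / {bad['symptom_id']}"
            )
        dup = df.duplicated(subset=["county_fips", "period_start", "symptom_id"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValidationError(
                "duplicate record for county "
                f"{bad['county_fips']} / {bad['period_start']} / {bad['symptom_id']}"
            )
        unknown = set(df["symptom_id"].unique()) - set(self.registry.symptom_ids)
        if unknown:
            raise ValidationError(f"symptom ids not in registry: {sorted(unknown)[:5]}")
        if require_biweekly:
            starts = pd.to_datetime(df["period_start"]).drop_duplicates().sort_values()
            if len(starts) > 1:
                offs = (starts - starts.iloc[0]).dt.days.to_numpy()
                if (offs % 14 != 0).any():
                    raise ValidationError("period starts are not 14-day aligned")
        return self

    @property
    def counties(self) -> list[str]:
        return sorted(self.data["county_fips"].unique())

    @property
    def periods(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(
            sorted(pd.to_datetime(self.data["period_start"]).unique())
        )


@dataclass(frozen=True)
class CountyDesignation:
    """Per-county stratification record: shortage status + urbanization tier.

    ``shortage_status`` is one of ``shortage | partial | nonshortage |
    unknown``; ``nchs6`` is the 6-tier urbanization code (1 = large central
    metro ... 6 = noncore/rural), or ``None`` when unknown.
    """

    county_fips: str
    shortage_status: str
    nchs6: int | None

    def __post_init__(self) -> None:
        if self.shortage_status not in SHORTAGE_STATUSES + ("unknown",):
            raise ValidationError(
                f"unparseable shortage status {self.shortage_status!r} "
                f"for county {self.county_fips}"
            )
        if self.nchs6 is not None and self.nchs6 not in range(1, 7):
            raise ValidationError(
                f"nchs6 code {self.nchs6!r} outside 1-6 for county {self.county_fips}"
            )

    @property
    def urban3(self) -> str:
        """Collapse nchs6 to metro (1-4) / micropolitan (5) / rural (6)."""
        if self.nchs6 is None:
            return "unknown"
        return NCHS6_TO_URBAN3[self.nchs6]

    @property
    def is_large_central_metro(self) -> bool:
        return self.nchs6 == 1


def designations_frame(
    designations: Mapping[str, CountyDesignation]
) -> pd.DataFrame:
    """Tabulate a designation mapping as a tidy frame (one row per county)."""
    rows = [
        {
            "county_fips": d.county_fips,
            "shortage_status": d.shortage_status,
            "nchs6": d.nchs6,
            "urban3": d.urban3,
            "is_large_central_metro": d.is_large_central_metro,
        }
        for d in designations.values()
    ]
    return pd.DataFrame(rows).sort_values("county_fips").reset_index(drop=True)


@dataclass(frozen=True)
class PanelProvenance:
    """Accounting of counties expected vs observed in a panel."""

    n_counties_expected: int
    n_counties_present: int
    suppressed_counties: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_counties_present + len(self.suppressed_counties) != self.n_counties_expected:
            raise ValidationError(
                "present + suppressed county counts do not add up to expected"
            )


def panel_provenance(
    panel: SymptomWeightPanel, county_list: Iterable[str]
) -> PanelProvenance:
    """Compare the counties observed in ``panel`` against a full county list."""
    expected = [normalize_fips(c) for c in county_list]
    present = set(panel.data["county_fips"].unique())
    suppressed = tuple(sorted(c for c in expected if c not in present))
    return PanelProvenance(
        n_counties_expected=len(expected),
        n_counties_present=len(set(expected) & present),
        suppressed_counties=suppressed,
    )


@dataclass
class ShareTable:
    """Per (county, period, symptom) share-of-search percentages in [0, 100].

    ``share`` is ``NaN`` iff the underlying weight was missing or the
    county-period total weight was zero.
    """

    data: pd.DataFrame
    registry: SymptomRegistry

    def validate(self, tol: float = 1e-9) -> "ShareTable":
        df = self.data
        missing_cols = set(SHARE_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValidationError(f"share table missing columns {sorted(missing_cols)}")
        sums = df.groupby(["county_fips", "period_start"], sort=False)["share"].sum(
            min_count=1
        )
        observed = sums.dropna()
        if len(observed) and (np.abs(observed.to_numpy() - 100.0) > tol).any():
            worst = observed.iloc[np.argmax(np.abs(observed.to_numpy() - 100.0))]
            raise ValidationError(
                f"shares do not sum to 100 within {tol} (worst sum {worst})"
            )
        return self


@dataclass
class SetShareSeries:
    """Composite share of a symptom set per (county, period)."""

    data: pd.DataFrame
    member_ids: tuple[str, ...]

    def validate(self) -> "SetShareSeries":
        missing_cols = set(SET_SHARE_COLUMNS) - set(self.data.columns)
        if missing_cols:
            raise ValidationError(f"set-share series missing columns {sorted(missing_cols)}")
        vals = self.data["set_share"].dropna().to_numpy()
        if len(vals) and ((vals < -1e-9) | (vals > 100 + 1e-9)).any():
            raise ValidationError("set shares outside [0, 100]")
        return self


def make_panel(
    records: Sequence[tuple[str, object, str, float | None]],
    registry: SymptomRegistry | None = None,
) -> SymptomWeightPanel:
    """Convenience constructor from (fips, date, symptom, weight) tuples."""
    df = pd.DataFrame(records, columns=list(PANEL_COLUMNS))
    df["county_fips"] = df["county_fips"].map(normalize_fips)
    df["period_start"] = pd.to_datetime(df["period_start"])
    df["weight"] = df["weight"].astype(float)
    if registry is None:
        registry = SymptomRegistry.from_ids(pd.unique(df["symptom_id"]))
    return SymptomWeightPanel(data=df, registry=registry).validate()
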