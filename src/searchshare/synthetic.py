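"""Synthetic panel generator with analytically known ground truth.

The generator emulates the structure of anonymized search-weight panels:
latent per-symptom search propensities, an arbitrary per-county scale factor
(weights are *not* comparable across counties), multiplicative group effects
by shortage status / urbanization tier / symptom class, an optional temporal
step and per-period trend, multiplicative log-normal plus additive Laplace
noise, per-cell suppression below a threshold, and whole-county suppression.

Because every planted effect is multiplicative, the implied true
share-of-search differences have a closed form (see :class:`GroundTruth`),
which downstream statistics are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .taxonomy import AffiliationTable
from .types import CountyDesignation, SymptomRegistry, SymptomWeightPanel

SYMPTOM_CLASSES = ("broad", "specific", "non_mh")
_STRATUM_ATOMS = (
    "shortage",
    "partial",
    "nonshortage",
    "rural",
    "micropolitan",
    "metro",
    "large_central_metro",
    "all",
)


def _parse_stratum(token: str) -> tuple[str, ...]:
    """Split a stratum key like ``rural_shortage`` into its atoms."""
    if token in _STRATUM_ATOMS:
        return (token,)
    placeholder = token.replace("large_central_metro", "LCM")
    parts = tuple(
        "large_central_metro" if p == "LCM" else p for p in placeholder.split("_")
    )
    bad = [p for p in parts if p not in _STRATUM_ATOMS]
    if bad:
        raise ValidationError(f"unknown stratum atoms {bad} in key {token!r}")
    return parts


def _atom_matches(atom: str, status: str, urban3: str, nchs6: int | None) -> bool:
    if atom == "all":
        return True
    if atom in ("shortage", "partial", "nonshortage"):
        return status == atom
    if atom in ("rural", "micropolitan", "metro"):
        return urban3 == atom
    if atom == "large_central_metro":
        return nchs6 == 1
    raise ValidationError(f"unknown stratum atom {atom!r}")


def _stratum_matches(
    token: str, status: str, urban3: str, nchs6: int | None
) -> bool:
    return all(_atom_matches(a, status, urban3, nchs6) for a in _parse_stratum(token))


def _target_matches(target: str, symptom_id: str, symptom_class: str) -> bool:
    if target == "all":
        return True
    if target == "mh":
        return symptom_class in ("broad", "specific")
    if target in SYMPTOM_CLASSES:
        return symptom_class == target
    return target == symptom_id


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic panel.

    ``effect_multipliers`` maps ``(stratum_key, target)`` to a positive factor,
    where the stratum key is an atom or underscore-joined conjunction over
    ``shortage | partial | nonshortage | rural | micropolitan | metro |
    large_central_metro | all`` and the target is a symptom id, a symptom
    class (``broad | specific | non_mh``), ``mh`` (both MH classes) or
    ``all``.  All matching factors multiply.
    """

    n_counties: int
    n_periods: int
    symptom_classes: Mapping[str, str]
    base_propensity: Mapping[str, float]
    fraction_shortage: float = 0.5
    fraction_partial: float = 0.0
    fraction_rural: float = 0.25
    fraction_micropolitan: float = 0.25
    effect_multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)
    step_cutoff_index: int | None = None
    step_multipliers: Mapping[str, float] = field(default_factory=dict)
    period_trend: Mapping[str, float] = field(default_factory=dict)
    region_scale_range: tuple[float, float] = (1.0, 1.0)
    lognormal_sd: float = 0.0
    laplace_b: float = 0.0
    n_suppressed_counties: int = 0
    cell_threshold: float = 0.0
    start_date: str = "2019-01-07"
    seed: int = 0

    @property
    def symptom_ids(self) -> tuple[str, ...]:
        return tuple(self.base_propensity)

    def validate(self) -> "SimulationConfig":
        if self.n_counties < 1 or self.n_periods < 1:
            raise ValidationError("n_counties and n_periods must be >= 1")
        if set(self.symptom_classes) != set(self.base_propensity):
            raise ValidationError("symptom_classes and base_propensity keys differ")
        for s, cls in self.symptom_classes.items():
            if cls not in SYMPTOM_CLASSES:
                raise ValidationError(f"unknown symptom class {cls!r} for {s}")
        for s, lam in self.base_propensity.items():
            if not lam > 0:
                raise ValidationError(f"base propensity for {s} must be > 0")
        for (stratum, _target), mult in self.effect_multipliers.items():
            _parse_stratum(stratum)
            if not mult > 0:
                raise ValidationError(f"effect multiplier for {stratum} must be > 0")
        for mult in self.step_multipliers.values():
            if not mult > 0:
                raise ValidationError("step multipliers must be > 0")
        for g in self.period_trend.values():
            if not g > 0:
                raise ValidationError("trend factors must be > 0")
        for frac in (
            self.fraction_shortage,
            self.fraction_partial,
            self.fraction_rural,
            self.fraction_micropolitan,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must lie in [0, 1]")
        if self.fraction_shortage + self.fraction_partial > 1.0 + 1e-12:
            raise ValidationError("shortage + partial fractions exceed 1")
        if self.fraction_rural + self.fraction_micropolitan > 1.0 + 1e-12:
            raise ValidationError("rural + micropolitan fractions exceed 1")
        if not 0 <= self.n_suppressed_counties < self.n_counties:
            raise ValidationError("n_suppressed_counties must be < n_counties")
        lo, hi = self.region_scale_range
        if not (0 < lo <= hi):
            raise ValidationError("region_scale_range must satisfy 0 < lo <= hi")
        if self.lognormal_sd < 0 or self.laplace_b < 0 or self.cell_threshold < 0:
            raise ValidationError("noise/threshold parameters must be >= 0")
        if self.step_cutoff_index is not None and not (
            0 <= self.step_cutoff_index <= self.n_periods
        ):
            raise ValidationError("step_cutoff_index outside 0..n_periods")
        return self

    # -- deterministic effect algebra -------------------------------------

    def effect(
        self, status: str, urban3: str, nchs6: int | None, symptom_id: str
    ) -> float:
        cls = self.symptom_classes[symptom_id]
        out = 1.0
        for (stratum, target), mult in self.effect_multipliers.items():
            if _stratum_matches(stratum, status, urban3, nchs6) and _target_matches(
                target, symptom_id, cls
            ):
                out *= mult
        return out

    def time_factor(self, period_index: int, symptom_id: str) -> float:
        cls = self.symptom_classes[symptom_id]
        out = 1.0
        if (
            self.step_cutoff_index is not None
            and period_index >= self.step_cutoff_index
        ):
            for target, mult in self.step_multipliers.items():
                if _target_matches(target, symptom_id, cls):
                    out *= mult
        for target, g in self.period_trend.items():
            if _target_matches(target, symptom_id, cls):
                out *= g ** period_index
        return out


@dataclass
class GroundTruth:
    """Closed-form expected shares implied by a :class:`SimulationConfig`.

    With weights ``w = sigma(c) * lam(s) * effect * time * noise``, the
    noise-free share of symptom ``s`` for a county profile is
    ``100 * lam(s) e(s) / sum_s' lam(s') e(s')`` — independent of the county
    scale ``sigma``, which is the entire point of the share statistic.
    """

    config: SimulationConfig
    assignments: pd.DataFrame  # fips, status, nchs6, urban3, suppressed
    suppressed_counties: tuple[str, ...]

    def expected_shares(
        self,
        status: str = "nonshortage",
        urban3: str = "metro",
        nchs6: int | None = None,
        period_index: int = 0,
    ) -> pd.Series:
        """Noise-free share (percent) of every symptom for one county profile."""
        cfg = self.config
        weights = {
            s: cfg.base_propensity[s]
            * cfg.effect(status, urban3, nchs6, s)
            * cfg.time_factor(period_index, s)
            for s in cfg.symptom_ids
        }
        total = sum(weights.values())
        return pd.Series({s: 100.0 * w / total for s, w in weights.items()})

    def expected_set_share(
        self,
        member_ids: Sequence[str],
        status: str = "nonshortage",
        urban3: str = "metro",
        nchs6: int | None = None,
        period_index: int = 0,
    ) -> float:
        shares = self.expected_shares(status, urban3, nchs6, period_index)
        return float(shares[list(member_ids)].sum())

    def share_difference(
        self, symptom_id: str, profile_a: Mapping, profile_b: Mapping
    ) -> float:
        """Expected share(a) - share(b) in percentage points."""
        return float(
            self.expected_shares(**profile_a)[symptom_id]
            - self.expected_shares(**profile_b)[symptom_id]
        )


def multiplier_for_set_share(
    base_propensity: Mapping[str, float],
    member_ids: Sequence[str],
    target_share_pct: float,
    symptom_multipliers: Mapping[str, float] | None = None,
) -> float:
    """Solve for the class multiplier that yields a target composite share.

    Given member mass ``M`` (after any fixed per-symptom multipliers) and
    non-member mass ``R``, a uniform factor ``m`` on members gives composite
    share ``t = mM / (mM + R)``; this inverts to ``m = tR / ((1 - t) M)``.
    """
    if not 0 < target_share_pct < 100:
        raise ValidationError("target composite share must be inside (0, 100)")
    mults = dict(symptom_multipliers or {})
    members = set(member_ids)
    m_mass = sum(
        lam * mults.get(s, 1.0) for s, lam in base_propensity.items() if s in members
    )
    r_mass = sum(
        lam * mults.get(s, 1.0)
        for s, lam in base_propensity.items()
        if s not in members
    )
    if m_mass <= 0 or r_mass <= 0:
        raise ValidationError("both member and non-member mass must be positive")
    t = target_share_pct / 100.0
    return t * r_mass / ((1.0 - t) * m_mass)


def _county_assignment(cfg: SimulationConfig, index: int) -> tuple[str, int]:
    """Status and nchs6 for county ``index`` from its own seed substream."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0, index)))
    u_status, u_urban, u_code = rng.random(3)
    if u_status < cfg.fraction_shortage:
        status = "shortage"
    elif u_status < cfg.fraction_shortage + cfg.fraction_partial:
        status = "partial"
    else:
        status = "nonshortage"
    if u_urban < cfg.fraction_rural:
        nchs6 = 6
    elif u_urban < cfg.fraction_rural + cfg.fraction_micropolitan:
        nchs6 = 5
    else:
        nchs6 = 1 + int(u_code * 4)  # large central metro through small metro
    return status, nchs6


def generate_panel(
    config: SimulationConfig,
) -> tuple[SymptomWeightPanel, dict[str, CountyDesignation], GroundTruth]:
    """Simulate one panel plus designations and its analytic ground truth.

    Each county draws from its own seed substream (``SeedSequence(seed,
    spawn_key=(1, i))``), so enlarging ``n_counties`` never perturbs the
    weights of existing counties.  Cells whose pre-truncation value falls
    below ``cell_threshold`` are suppressed (missing); negatives surviving
    suppression are truncated to zero to keep weights nonnegative.
    """
    cfg = config.validate()
    symptoms = list(cfg.symptom_ids)
    n_s = len(symptoms)
    n_t = cfg.n_periods
    lam = np.array([cfg.base_propensity[s] for s in symptoms])
    time_mat = np.array(
        [[cfg.time_factor(t, s) for s in symptoms] for t in range(n_t)]
    )  # (T, S)
    periods = pd.Timestamp(cfg.start_date) + pd.to_timedelta(
        14 * np.arange(n_t), unit="D"
    )

    fips_list = [f"{i + 1:05d}" for i in range(cfg.n_counties)]
    designations: dict[str, CountyDesignation] = {}
    assign_rows = []
    county_blocks = []
    for i, fips in enumerate(fips_list):
        status, nchs6 = _county_assignment(cfg, i)
        d = CountyDesignation(fips, status, nchs6)
        designations[fips] = d
        assign_rows.append(
            {"county_fips": fips, "status": status, "nchs6": nchs6, "urban3": d.urban3}
        )

        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, i)))
        sigma = rng.uniform(*cfg.region_scale_range)
        effect = np.array([cfg.effect(status, d.urban3, nchs6, s) for s in symptoms])
        base = sigma * lam[None, :] * effect[None, :] * time_mat  # (T, S)
        value = base.copy()
        if cfg.lognormal_sd > 0:
            value = value * np.exp(rng.normal(0.0, cfg.lognormal_sd, size=(n_t, n_s)))
        if cfg.laplace_b > 0:
            value = value + rng.laplace(0.0, cfg.laplace_b, size=(n_t, n_s))
        missing = value < cfg.cell_threshold
        weights = np.where(missing, np.nan, np.maximum(value, 0.0))
        county_blocks.append(weights.ravel())

    sup_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2, 0)))
    sup_idx = set(
        sup_rng.choice(
            cfg.n_counties, size=cfg.n_suppressed_counties, replace=False
        ).tolist()
    )
    suppressed = tuple(fips_list[i] for i in sorted(sup_idx))

    kept = [i for i in range(cfg.n_counties) if i not in sup_idx]
    data = pd.DataFrame(
        {
            "county_fips": np.repeat([fips_list[i] for i in kept], n_t * n_s),
            "period_start": np.tile(np.repeat(periods.to_numpy(), n_s), len(kept)),
            "symptom_id": np.tile(symptoms, len(kept) * n_t),
            "weight": np.concatenate([county_blocks[i] for i in kept])
            if kept
            else np.array([], dtype=float),
        }
    )
    registry = SymptomRegistry.from_ids(symptoms)
    panel = SymptomWeightPanel(data=data, registry=registry).validate()

    assignments = pd.DataFrame(assign_rows)
    assignments["suppressed"] = assignments["county_fips"].isin(suppressed)
    truth = GroundTruth(
        config=cfg, assignments=assignments, suppressed_counties=suppressed
    )
    return panel, designations, truth


def generate_coder_labels(
    n_items: int, p_positive: float, p_disagree: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two binary label sequences: rater B flips each of A's labels w.p. ``p_disagree``."""
    if n_items < 1:
        raise ValidationError("n_items must be >= 1")
    for p in (p_positive, p_disagree):
        if not 0.0 <= p <= 1.0:
            raise ValidationError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a = (rng.random(n_items) < p_positive).astype(int)
    flip = rng.random(n_items) < p_disagree
    b = np.where(flip, 1 - a, a)
    return a, b


def generate_affiliation_table(
    symptom_ids: Sequence[str],
    seed_set: Sequence[str],
    p_link: float,
    relevance_range: tuple[float, float],
    seed: int,
) -> AffiliationTable:
    """Random co-search affiliation table over (seed, other-symptom) pairs."""
    if len(symptom_ids) == 0:
        raise ValidationError("symptom list must be nonempty")
    if not set(seed_set) <= set(symptom_ids):
        raise ValidationError("seed_set must be a subset of symptom_ids")
    if not 0.0 <= p_link <= 1.0:
        raise ValidationError("p_link must lie in [0, 1]")
    lo, hi = relevance_range
    if not 0 <= lo <= hi:
        raise ValidationError("relevance_range must satisfy 0 <= lo <= hi")
    rng = np.random.default_rng(seed)
    rows = []
    for src in seed_set:
        for other in symptom_ids:
            if other == src:
                continue
            if rng.random() < p_link:
                rows.append(
                    {
                        "source_symptom": src,
                        "related_symptom": other,
                        "relevance": rng.uniform(lo, hi),
                    }
                )
    df = pd.DataFrame(rows, columns=["source_symptom", "related_symptom", "relevance"])
    return AffiliationTable(data=df).validate()
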