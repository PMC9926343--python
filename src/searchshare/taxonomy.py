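"""Construction of the mental-health symptom set.

Three operators: chance-corrected dual-coder agreement (Cohen's kappa) over
binary include/exclude labels, expansion of a manually coded seed set through
a co-search affiliation table with a relevance threshold (associations below
the threshold are discarded; the boundary value is kept), and rule-based
exclusions with an auditable ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementResult:
    """Dual-coder agreement summary.

    ``confusion_counts`` is ``(a, b, c, d)``: both-positive, A-only-positive,
    B-only-positive, both-negative.
    """

    kappa: float
    percent_agreement: float
    confusion_counts: tuple[int, int, int, int]

    @property
    def n(self) -> int:
        return sum(self.confusion_counts)


def kappa_from_counts(a: int, b: int, c: int, d: int) -> AgreementResult:
    """Cohen's kappa from 2x2 confusion counts.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = (a + d)/n`` and chance agreement
    ``p_e = p_A(1) p_B(1) + p_A(0) p_B(0)``.  When both raters are constant
    and identical (``p_e = 1``, forcing ``p_o = 1``), kappa is defined as 1.
    """
    for count in (a, b, c, d):
        if count < 0:
            raise ValidationError("confusion counts must be nonnegative")
    n = a + b + c + d
    if n == 0:
        raise ValidationError("empty label sequences")
    p_o = (a + d) / n
    p_a1 = (a + b) / n
    p_b1 = (a + c) / n
    p_e = p_a1 * p_b1 + (1 - p_a1) * (1 - p_b1)
    if p_e >= 1.0:
        kappa = 1.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(
        kappa=kappa, percent_agreement=100.0 * p_o, confusion_counts=(a, b, c, d)
    )


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Cohen's kappa over two equal-length binary label sequences."""
    a_arr = np.asarray(labels_a)
    b_arr = np.asarray(labels_b)
    if a_arr.shape != b_arr.shape or a_arr.ndim != 1:
        raise ValidationError("label sequences must be 1-d and of equal length")
    if a_arr.size == 0:
        raise ValidationError("empty label sequences")
    a_bool = a_arr.astype(bool)
    b_bool = b_arr.astype(bool)
    both = int(np.sum(a_bool & b_bool))
    a_only = int(np.sum(a_bool & ~b_bool))
    b_only = int(np.sum(~a_bool & b_bool))
    neither = int(np.sum(~a_bool & ~b_bool))
    return kappa_from_counts(both, a_only, b_only, neither)


@dataclass
class AffiliationTable:
    """Records of (source_symptom, related_symptom, relevance >= 0)."""

    data: pd.DataFrame

    def validate(self) -> "AffiliationTable":
        required = {"source_symptom", "related_symptom", "relevance"}
        if not required <= set(self.data.columns):
            raise ValidationError(
                f"affiliation table missing columns {sorted(required - set(self.data.columns))}"
            )
        if len(self.data) and (self.data["relevance"] < 0).any():
            raise ValidationError("relevance values must be >= 0")
        if self.data.duplicated(subset=["source_symptom", "related_symptom"]).any():
            raise ValidationError("duplicate (source, related) affiliation pair")
        return self

    def __len__(self) -> int:
        return len(self.data)


def expand_by_affiliation(
    seed_set: Iterable[str],
    table: AffiliationTable,
    threshold: float = 2.0,
    transitive: bool = False,
    known_ids: Iterable[str] | None = None,
) -> set[str]:
    """Symptoms co-searched with the seed set at relevance >= ``threshold``.

    Returns related symptoms of table rows whose source is in ``seed_set``
    and whose relevance clears the threshold, minus the seeds themselves.
    With ``transitive=True`` the expansion is iterated to a fixed point
    (newly added symptoms act as sources in turn).  Unknown ids merely log a
    warning — the affiliation source is external and noisy by nature.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    seeds = set(seed_set)
    df = table.validate().data
    if known_ids is not None:
        known = set(known_ids)
        strangers = (set(df["source_symptom"]) | set(df["related_symptom"])) - known
        if strangers:
            logger.warning(
                "affiliation table references %d ids outside the registry: %s",
                len(strangers),
                sorted(strangers)[:5],
            )
    kept = df[df["relevance"] >= threshold]

    frontier = set(seeds)
    expanded: set[str] = set()
    while frontier:
        hits = set(kept.loc[kept["source_symptom"].isin(frontier), "related_symptom"])
        new = hits - seeds - expanded
        expanded |= new
        frontier = new if transitive else set()
    return expanded


def threshold_sweep(
    seed_set: Iterable[str],
    table: AffiliationTable,
    thresholds: Sequence[float],
    transitive: bool = False,
) -> pd.DataFrame:
    """Report expansion size as a function of the relevance threshold."""
    seeds = set(seed_set)
    rows = []
    for tau in thresholds:
        exp = expand_by_affiliation(seeds, table, threshold=tau, transitive=transitive)
        rows.append(
            {"threshold": tau, "n_expanded": len(exp), "n_total": len(seeds | exp)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MHSymptomSet:
    """Curated symptom set with full construction provenance."""

    seed_ids: frozenset[str]
    expanded_ids: frozenset[str]
    excluded: Mapping[str, str] = field(default_factory=dict)  # id -> reason
    final_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        expected = (self.seed_ids | self.expanded_ids) - set(self.excluded)
        if self.final_ids != expected:
            raise ValidationError(
                "final_ids must equal (seeds | expanded) minus exclusions"
            )

    def summary(self) -> dict[str, int]:
        return {
            "n_seed": len(self.seed_ids),
            "n_expanded": len(self.expanded_ids),
            "n_excluded": len(self.excluded),
            "n_final": len(self.final_ids),
        }


def build_symptom_set(
    seed_ids: Iterable[str],
    expanded_ids: Iterable[str],
    exclusion_rules: Sequence[Mapping[str, str]] = (),
) -> MHSymptomSet:
    """Assemble the final set: (seeds | expansion) minus excluded ids.

    ``exclusion_rules`` are mappings with ``symptom_id`` and ``reason``; a
    rule naming an id absent from the candidates logs a warning rather than
    failing.
    """
    seeds = frozenset(seed_ids)
    expanded = frozenset(expanded_ids) - seeds
    candidates = seeds | expanded
    ledger: dict[str, str] = {}
    for rule in exclusion_rules:
        sid = rule["symptom_id"]
        reason = rule.get("reason", "unspecified")
        if sid not in candidates:
            logger.warning("exclusion rule names absent symptom %r; ignored", sid)
            continue
        ledger[sid] = reason
    return MHSymptomSet(
        seed_ids=seeds,
        expanded_ids=expanded,
        excluded=ledger,
        final_ids=candidates - set(ledger),
    )


def apply_exclusions(
    candidates: Iterable[str],
    rules: Sequence[Mapping[str, str]],
    seed_ids: Iterable[str] | None = None,
) -> MHSymptomSet:
    """Apply exclusion rules to a candidate set (seeds optional metadata)."""
    cand = frozenset(candidates)
    seeds = frozenset(seed_ids) if seed_ids is not None else cand
    return build_symptom_set(seeds & cand, cand - seeds, rules)


def read_exclusion_rules(path) -> list[dict[str, str]]:
    """CSV with columns (symptom_id, reason) -> rule list."""
    df = pd.read_csv(path, dtype=str)
    if "symptom_id" not in df.columns:
        raise ValidationError(f"exclusion file {path} lacks a symptom_id column")
    if "reason" not in df.columns:
        df["reason"] = "unspecified"
    return df[["symptom_id", "reason"]].to_dict("records")


def read_affiliation_table(path) -> AffiliationTable:
    df = pd.read_csv(path)
    return AffiliationTable(data=df).validate()
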