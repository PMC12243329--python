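"""Feedstock screening by composition thresholds and mass-pool aggregation.

A bioprocess targets one biochemical fraction (lignin, NFC, oil/glycerol).
Residues qualify in two tiers: *favorable* (high share of the relevant
fraction) and *possible* (meets a relaxed threshold only).  Pools aggregate
the raw-material mass (technical potential × usable share) and the
contained fraction mass over a selection of residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .resource_matrix import FRACTIONS, ResourceMatrix

logger = logging.getLogger(__name__)

COMPARISONS = ("geq", "gt")


@dataclass(frozen=True)
class ScreeningRule:
    """Tiered inclusion thresholds on the mean of one fraction (g g⁻¹ DM).

    ``comparison`` applies to both tiers: ``geq`` keeps residues at the
    threshold (lignin, NFC rules), ``gt`` requires strictly more (oil rule).
    Setting ``possible_threshold == favorable_threshold`` collapses the
    possible tier to empty.
    """

    fraction_name: str
    favorable_threshold: float
    possible_threshold: float
    comparison: str = "geq"

    def __post_init__(self) -> None:
        if self.fraction_name not in FRACTIONS:
            raise ValueError(f"unknown fraction name {self.fraction_name!r}")
        if not (0.0 <= self.possible_threshold <= self.favorable_threshold <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0 ≤ possible ≤ favorable ≤ 1, got "
                f"possible={self.possible_threshold}, "
                f"favorable={self.favorable_threshold}"
            )
        if self.comparison not in COMPARISONS:
            raise ValueError(
                f"comparison must be one of {COMPARISONS}, got {self.comparison!r}"
            )

    def meets(self, value: float, threshold: float) -> bool:
        return value >= threshold if self.comparison == "geq" else value > threshold


@dataclass(frozen=True)
class TieredSelection:
    """Residue ids meeting the favorable or (only) the possible threshold."""

    favorable: tuple[str, ...]
    possible: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.favorable) & set(self.possible):
            raise ValueError("favorable and possible tiers must be disjoint")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.favorable + self.possible


@dataclass(frozen=True)
class MassPools:
    """Raw-material and contained-fraction mass of a selection, Mg DM a⁻¹."""

    raw_pool: float
    fraction_pool: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_pool <= self.raw_pool or self.raw_pool == 0.0):
            raise ValueError(
                f"fraction_pool ({self.fraction_pool}) must lie in "
                f"[0, raw_pool={self.raw_pool}]"
            )

    def __add__(self, other: "MassPools") -> "MassPools":
        return MassPools(
            self.raw_pool + other.raw_pool, self.fraction_pool + other.fraction_pool
        )


def screen_feedstocks(matrix: ResourceMatrix, rule: ScreeningRule) -> TieredSelection:
    """Assign residues to favorable/possible tiers by their mean fraction.

    Deterministic and order-preserving.  Residues without a mean value for
    the rule's fraction are silently ineligible (logged).
    """
    favorable: list[str] = []
    possible: list[str] = []
    for residue in matrix:
        value = residue.composition.mean(rule.fraction_name)
        if value is None:
            logger.info(
                "residue %s has no mean %s value; ineligible for screening",
                residue.id,
                rule.fraction_name,
            )
            continue
        if rule.meets(value, rule.favorable_threshold):
            favorable.append(residue.id)
        elif rule.meets(value, rule.possible_threshold):
            possible.append(residue.id)
    return TieredSelection(tuple(favorable), tuple(possible))


def pool_masses(
    matrix: ResourceMatrix, ids: Sequence[str], fraction_name: str
) -> MassPools:
    """Sum raw-material and fraction masses over the given residues.

    raw_pool = Σ potential × usable_share;
    fraction_pool = Σ potential × usable_share × mean fraction.
    Additive over disjoint id sets; summation follows matrix order.
    """
    if fraction_name not in FRACTIONS:
        raise ValueError(f"unknown fraction name {fraction_name!r}")
    wanted = set(ids)
    unknown = wanted - set(matrix.ids)
    if unknown:
        raise ValueError(f"unknown residue ids: {sorted(unknown)}")
    raw = 0.0
    frac = 0.0
    for residue in matrix:
        if residue.id not in wanted:
            continue
        mean = residue.composition.mean(fraction_name)
        if mean is None:
            raise ValueError(
                f"residue {residue.id} has no mean {fraction_name} value"
            )
        usable = residue.usable_potential
        raw += usable
        frac += usable * mean
    return MassPools(raw_pool=raw, fraction_pool=frac)
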