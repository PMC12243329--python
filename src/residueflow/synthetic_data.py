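"""Synthetic resource matrices with known ground truth, plus the bundled fixture.

The generator emulates the statistical structure of a national residue
inventory: residues drawn from five origin sectors, log-uniform technical
potentials, and per-sector composition archetypes sampled on the simplex
(seven fractions plus an "unassigned" remainder) with a concentration
parameter controlling dispersion.  *Planted truth* constraints force an
exact number of residues above a screening threshold — optionally with an
exact fraction-pool mass — so screening and pooling can be verified against
a recorded ground truth.

:func:`reference_fixture` loads the bundled 20-residue reference matrix
(relevant-fraction means from a published cross-sector survey of German
biogenic residues) together with the published pool tonnages and product
potentials.  The per-residue technical potentials in that file are
synthetic: they were reconstructed so the tier pool sums close on the
published tonnages wherever those are internally consistent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .resource_matrix import (
    ANALYSIS_GRADES,
    FRACTIONS,
    SECTORS,
    CompositionProfile,
    FractionStat,
    QualityMeta,
    Residue,
    ResourceMatrix,
    load_matrix,
)
from .screening import MassPools

_SIMPLEX_PARTS = FRACTIONS + ("unassigned",)

#: Per-sector mean composition archetypes over the seven fractions plus an
#: unassigned remainder (woody sectors lignin-heavy, food-industry NFC-heavy).
DEFAULT_ARCHETYPES: dict[str, tuple[float, ...]] = {
    "agriculture": (0.30, 0.20, 0.10, 0.15, 0.08, 0.02, 0.07, 0.08),
    "forestry": (0.40, 0.22, 0.25, 0.03, 0.01, 0.02, 0.02, 0.05),
    "industry": (0.15, 0.10, 0.10, 0.35, 0.10, 0.05, 0.05, 0.10),
    "municipal_waste_sewage": (0.20, 0.10, 0.12, 0.25, 0.10, 0.05, 0.10, 0.08),
    "other": (0.25, 0.15, 0.15, 0.15, 0.08, 0.04, 0.08, 0.10),
}

DEFAULT_SECTOR_WEIGHTS: dict[str, float] = {
    "agriculture": 0.30,
    "forestry": 0.15,
    "industry": 0.25,
    "municipal_waste_sewage": 0.20,
    "other": 0.10,
}


class GenerationError(ValueError):
    """Raised when a generator configuration cannot be satisfied."""


@dataclass(frozen=True)
class PlantedTier:
    """Constraint: exactly ``count`` residues meet ``threshold`` on one fraction.

    If ``fraction_pool`` is given, the members' usable fraction mass sums to
    it exactly (member potentials are rescaled accordingly).
    """

    fraction_name: str
    threshold: float
    count: int
    fraction_pool: float | None = None
    comparison: str = "geq"

    def __post_init__(self) -> None:
        if self.fraction_name not in FRACTIONS:
            raise GenerationError(f"unknown fraction name {self.fraction_name!r}")
        if not (0.0 < self.threshold < 1.0):
            raise GenerationError(
                f"planted threshold must lie in (0, 1), got {self.threshold}"
            )
        if self.count < 0:
            raise GenerationError(f"count must be ≥ 0, got {self.count}")
        if self.fraction_pool is not None and self.fraction_pool <= 0:
            raise GenerationError(
                f"fraction_pool must be > 0, got {self.fraction_pool}"
            )
        if self.fraction_pool is not None and self.count == 0:
            raise GenerationError("cannot plant a fraction pool with count = 0")
        if self.comparison not in ("geq", "gt"):
            raise GenerationError(f"comparison must be geq or gt, got {self.comparison}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a synthetic matrix, given a seed."""

    n_residues: int
    seed: int
    sector_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTOR_WEIGHTS)
    )
    potential_range: tuple[float, float] = (2.5e5, 2.0e7)
    composition_archetypes: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    concentration: float = 60.0
    reference_year: int = 2025
    mean_extra_sources: float = 1.5
    grade_probabilities: tuple[float, float, float, float] = (0.15, 0.35, 0.30, 0.20)
    max_source_age: int = 35
    planted_truth: tuple[PlantedTier, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_truth", tuple(self.planted_truth))
        if self.n_residues < 0:
            raise GenerationError(f"n_residues must be ≥ 0, got {self.n_residues}")
        if set(self.sector_weights) != set(SECTORS):
            raise GenerationError(f"sector_weights must cover exactly {SECTORS}")
        total = sum(self.sector_weights.values())
        if abs(total - 1.0) > 1e-9 or min(self.sector_weights.values()) < 0:
            raise GenerationError("sector_weights must be non-negative and sum to 1")
        low, high = self.potential_range
        if not (0 < low < high):
            raise GenerationError(
                f"potential_range must satisfy 0 < low < high, got {self.potential_range}"
            )
        if self.concentration <= 0:
            raise GenerationError("concentration must be > 0")
        for sector, archetype in self.composition_archetypes.items():
            if sector not in SECTORS:
                raise GenerationError(f"archetype for unknown sector {sector!r}")
            if len(archetype) != len(_SIMPLEX_PARTS) or min(archetype) <= 0:
                raise GenerationError(
                    f"archetype for {sector!r} must be {len(_SIMPLEX_PARTS)} "
                    "positive values"
                )
        if abs(sum(self.grade_probabilities) - 1.0) > 1e-9:
            raise GenerationError("grade_probabilities must sum to 1")
        # planted constraints must be mutually satisfiable before sampling
        names = [p.fraction_name for p in self.planted_truth]
        if len(names) != len(set(names)):
            raise GenerationError(
                "planted constraints must target distinct fractions"
            )
        if sum(p.count for p in self.planted_truth) > self.n_residues:
            raise GenerationError(
                "planted member counts exceed the number of residues"
            )


@dataclass(frozen=True)
class PlantedRecord:
    """Ground truth implied by one planted constraint in a generated matrix."""

    fraction_name: str
    threshold: float
    comparison: str
    member_ids: tuple[str, ...]
    raw_pool: float
    fraction_pool: float


@dataclass(frozen=True)
class GroundTruth:
    """Sidecar record of everything the generator planted."""

    seed: int
    n_residues: int
    sector_counts: Mapping[str, int]
    planted: tuple[PlantedRecord, ...]

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["sector_counts"] = dict(self.sector_counts)
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
        )


def generate_matrix(config: GeneratorConfig) -> tuple[ResourceMatrix, GroundTruth]:
    """Sample a matrix reproducibly; planted constraints hold exactly.

    Member potentials rescaled to hit a planted fraction pool may leave the
    configured potential range; everything else stays stochastic.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    sectors = rng.choice(len(SECTORS), size=n, p=[config.sector_weights[s] for s in SECTORS])
    low, high = config.potential_range
    potentials = np.exp(rng.uniform(np.log(low), np.log(high), size=n))
    means = np.empty((n, len(FRACTIONS)))
    for i in range(n):
        alpha = config.concentration * np.asarray(
            config.composition_archetypes[SECTORS[sectors[i]]]
        )
        means[i] = rng.dirichlet(alpha)[: len(FRACTIONS)]
    spreads = rng.uniform(0.05, 0.30, size=(n, len(FRACTIONS)))
    n_sources = 1 + rng.poisson(config.mean_extra_sources, size=n)
    grades = rng.choice(len(ANALYSIS_GRADES), size=n, p=config.grade_probabilities)
    ages = rng.integers(0, config.max_source_age, size=n)

    # --- plant constraints by exact post-hoc adjustment --------------------
    records: list[dict] = []
    block_start = 0
    for planted in config.planted_truth:
        members = list(range(block_start, block_start + planted.count))
        block_start += planted.count
        col = FRACTIONS.index(planted.fraction_name)
        for i in members:
            value = planted.threshold + (1.0 - planted.threshold) * rng.uniform(
                0.05, 0.40
            )
            others = np.delete(np.arange(len(FRACTIONS)), col)
            others_sum = means[i, others].sum()
            if others_sum > 1.0 - value and others_sum > 0:
                means[i, others] *= (1.0 - value) / others_sum
            means[i, col] = value
        member_set = set(members)
        for i in range(n):
            if i in member_set:
                continue
            meets = (
                means[i, col] >= planted.threshold
                if planted.comparison == "geq"
                else means[i, col] > planted.threshold
            )
            if meets:
                means[i, col] = planted.threshold * rng.uniform(0.3, 0.9)
        if planted.fraction_pool is not None:
            current = sum(potentials[i] * means[i, col] for i in members)
            if current <= 0:
                raise GenerationError(
                    f"cannot scale to fraction pool for {planted.fraction_name}"
                )
            scale = planted.fraction_pool / current
            for i in members:
                potentials[i] *= scale
        records.append(
            {"planted": planted, "members": members, "col": col}
        )

    residues: list[Residue] = []
    for i in range(n):
        stats = {}
        for j, frac in enumerate(FRACTIONS):
            mean = float(means[i, j])
            stats[frac] = FractionStat(
                min=float(max(0.0, mean * (1.0 - spreads[i, j]))),
                mean=mean,
                max=float(min(1.0, mean * (1.0 + spreads[i, j]))),
            )
        sector = SECTORS[sectors[i]]
        residues.append(
            Residue(
                id=f"syn{i:04d}",
                name=f"synthetic residue {i}",
                sector=sector,
                technical_potential=float(potentials[i]),
                composition=CompositionProfile(stats),
                quality=QualityMeta(
                    n_sources=int(n_sources[i]),
                    analysis_quality=ANALYSIS_GRADES[grades[i]],
                    newest_source_year=config.reference_year - int(ages[i]),
                    reference_year=config.reference_year,
                ),
            )
        )
    matrix = ResourceMatrix(
        tuple(residues),
        reference_year=config.reference_year,
        provenance=f"synthetic matrix (seed={config.seed})",
    )

    # ground truth pools: plain left-to-right loop in matrix order, mirroring
    # how pooling is defined (usable share is 1.0 for generated residues)
    planted_records: list[PlantedRecord] = []
    for rec in records:
        members = set(rec["members"])
        raw = 0.0
        frac_mass = 0.0
        member_ids = []
        for i, residue in enumerate(matrix):
            if i not in members:
                continue
            member_ids.append(residue.id)
            usable = residue.usable_potential
            raw += usable
            frac_mass += usable * residue.composition.mean(rec["planted"].fraction_name)
        planted_records.append(
            PlantedRecord(
                fraction_name=rec["planted"].fraction_name,
                threshold=rec["planted"].threshold,
                comparison=rec["planted"].comparison,
                member_ids=tuple(member_ids),
                raw_pool=raw,
                fraction_pool=frac_mass,
            )
        )
    sector_counts = {s: 0 for s in SECTORS}
    for residue in matrix:
        sector_counts[residue.sector] += 1
    truth = GroundTruth(
        seed=config.seed,
        n_residues=n,
        sector_counts=sector_counts,
        planted=tuple(planted_records),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Bundled reference fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceFixture:
    """The bundled 20-residue matrix plus published pool and product tonnages.

    ``pools`` holds the published raw/fraction tonnages per process feedstock
    group and tier; ``products`` the published biogenic product potentials.
    These published values serve as report inputs where per-residue data
    cannot reconstruct them (the NFC possible-tier fraction pool is not
    internally consistent in the source tonnage table).
    """

    matrix: ResourceMatrix
    pools: Mapping[str, Mapping[str, MassPools]]
    products: Mapping[str, float]


#: Published pool tonnages (Mg DM a⁻¹) per feedstock group and tier.
REFERENCE_POOLS: dict[str, dict[str, MassPools]] = {
    "lignin": {
        "favorable": MassPools(31.2e6, 7.8e6),
        "with_possible": MassPools(42.7e6, 10.1e6),
    },
    "nfc": {
        "favorable": MassPools(6.9e6, 2.7e6),
        "with_possible": MassPools(16.6e6, 4.0e6),
    },
    "oil_waste": {"favorable": MassPools(156_000.0, 142_000.0)},
    "glycerol": {"favorable": MassPools(277_000.0, 263_000.0)},
}

#: Published biogenic product potentials (Mg a⁻¹).
REFERENCE_PRODUCTS: dict[str, float] = {
    "adipic_acid_baseline_favorable": 665_000.0,
    "adipic_acid_idealized_with_possible": 2.5e6,
    "c6_c8_acids_favorable": 210_000.0,
    "c6_c8_acids_with_possible": 368_000.0,
    "citric_acid": 188_000.0,
    "citric_acid_wastewater": 147_000.0,
    "kga": 116_000.0,
}


def reference_fixture() -> ReferenceFixture:
    """Load the bundled reference matrix and published tonnage constants."""
    with resources.as_file(
        resources.files("residueflow.data") / "reference_matrix.csv"
    ) as path:
        matrix = load_matrix(path)
    return ReferenceFixture(
        matrix=matrix, pools=REFERENCE_POOLS, products=REFERENCE_PRODUCTS
    )
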