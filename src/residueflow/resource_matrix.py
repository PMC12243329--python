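"""Cross-sector resource matrix: data model, I/O, validation and quality scoring.

The resource matrix interlinks biogenic residues (straw, manure, logging
residues, industrial by-products, municipal wastes, ...) with their
biochemical composition, expressed as mass fractions of dry matter (DM) for
the seven fractions cellulose, hemicellulose, lignin, non-fibrous
carbohydrates (NFC), protein, fats/oils and ash.  Published compositions
vary strongly with source, storage and treatment, so every fraction carries
MIN/MEAN/MAX statistics, any of which may be unknown.

All masses are dry matter; the reference unit for annual technical
potentials is Mg DM a⁻¹.  Heterogeneous literature data is graded with a
five-level quality score (1 = good, 5 = not reliable) combining the number
of independent sources, the quality of the analytical method, and recency.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The fixed set of biochemical fractions, in canonical column order.
FRACTIONS: tuple[str, ...] = (
    "cellulose",
    "hemicellulose",
    "lignin",
    "nfc",
    "protein",
    "fats_oils",
    "ash",
)

#: Origin sectors of biogenic residues.
SECTORS: tuple[str, ...] = (
    "agriculture",
    "forestry",
    "industry",
    "municipal_waste_sewage",
    "other",
)

#: Analytical-quality grades, worst to best.
ANALYSIS_GRADES: tuple[str, ...] = (
    "unclear",
    "method_stated",
    "detailed",
    "detailed_with_series",
)

#: Suitability classes used when summarising exploitability of the portfolio.
SUITABILITY_CLASSES: tuple[str, ...] = (
    "model_process",
    "principal_feasibility",
    "not_exploitable",
    "below_cutoff",
)

# Mean fractions need not close to 1 exactly (heterogeneous assays), but
# gross violations indicate data errors.
COMPOSITION_SUM_WARN = 1.05
COMPOSITION_SUM_ERROR = 1.20


class MatrixFormatError(ValueError):
    """Raised when a matrix file is structurally unreadable (columns, parsing)."""


class MatrixValidationError(ValueError):
    """Raised when matrix content violates domain invariants."""


def _check_unit_interval(value: float | None, what: str) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise MatrixValidationError(f"{what} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class FractionStat:
    """MIN/MEAN/MAX of one biochemical fraction, g g⁻¹ DM; ``None`` = unknown."""

    min: float | None = None
    mean: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        for name in ("min", "mean", "max"):
            _check_unit_interval(getattr(self, name), f"fraction {name}")
        if self.min is not None and self.mean is not None and self.min > self.mean:
            raise MatrixValidationError(f"min {self.min} > mean {self.mean}")
        if self.mean is not None and self.max is not None and self.mean > self.max:
            raise MatrixValidationError(f"mean {self.mean} > max {self.max}")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise MatrixValidationError(f"min {self.min} > max {self.max}")

    @property
    def is_empty(self) -> bool:
        return self.min is None and self.mean is None and self.max is None


@dataclass(frozen=True)
class CompositionProfile:
    """One :class:`FractionStat` per fraction in :data:`FRACTIONS`."""

    fractions: Mapping[str, FractionStat]

    def __post_init__(self) -> None:
        keys = set(self.fractions)
        if keys != set(FRACTIONS):
            missing = set(FRACTIONS) - keys
            extra = keys - set(FRACTIONS)
            raise MatrixValidationError(
                f"composition must cover exactly {FRACTIONS}; "
                f"missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        # normalize to a plain dict in canonical order (stable equality/repr)
        object.__setattr__(
            self, "fractions", {name: self.fractions[name] for name in FRACTIONS}
        )
        total = sum(
            stat.mean for stat in self.fractions.values() if stat.mean is not None
        )
        if total > COMPOSITION_SUM_ERROR:
            raise MatrixValidationError(
                f"mean fractions sum to {total:.3f} > {COMPOSITION_SUM_ERROR}"
            )
        if total > COMPOSITION_SUM_WARN:
            warnings.warn(
                f"mean fractions sum to {total:.3f} > {COMPOSITION_SUM_WARN}",
                stacklevel=2,
            )

    @classmethod
    def from_means(cls, **means: float) -> "CompositionProfile":
        """Build a profile from mean values only, e.g. ``from_means(lignin=0.34)``."""
        stats = {
            name: FractionStat(mean=means.get(name)) for name in FRACTIONS
        }
        unknown = set(means) - set(FRACTIONS)
        if unknown:
            raise MatrixValidationError(f"unknown fraction names: {sorted(unknown)}")
        return cls(stats)

    def mean(self, fraction_name: str) -> float | None:
        if fraction_name not in FRACTIONS:
            raise MatrixValidationError(f"unknown fraction name {fraction_name!r}")
        return self.fractions[fraction_name].mean


@dataclass(frozen=True)
class QualityMeta:
    """Provenance metadata feeding the five-level data-quality score."""

    n_sources: int
    analysis_quality: str
    newest_source_year: int
    reference_year: int

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise MatrixValidationError(f"n_sources must be ≥ 1, got {self.n_sources}")
        if self.analysis_quality not in ANALYSIS_GRADES:
            raise MatrixValidationError(
                f"analysis_quality must be one of {ANALYSIS_GRADES}, "
                f"got {self.analysis_quality!r}"
            )
        if self.newest_source_year > self.reference_year:
            raise MatrixValidationError(
                f"newest_source_year {self.newest_source_year} is after "
                f"reference_year {self.reference_year}"
            )

    @property
    def age_years(self) -> int:
        return self.reference_year - self.newest_source_year


@dataclass(frozen=True)
class Residue:
    """One biogenic residue with its annual technical potential and composition.

    ``usable_share`` discounts the technical potential where only part of a
    residue stream is a suitable feedstock (e.g. 0.8 for residues from starch
    production, representing the potato-pulp share).
    """

    id: str
    name: str
    sector: str
    technical_potential: float  # Mg DM a⁻¹
    composition: CompositionProfile
    quality: QualityMeta
    usable_share: float = 1.0

    def __post_init__(self) -> None:
        if not self.id:
            raise MatrixValidationError("residue id must be non-empty")
        if self.sector not in SECTORS:
            raise MatrixValidationError(
                f"sector must be one of {SECTORS}, got {self.sector!r}"
            )
        if self.technical_potential < 0:
            raise MatrixValidationError(
                f"technical_potential must be ≥ 0, got {self.technical_potential}"
            )
        if not (0.0 < self.usable_share <= 1.0):
            raise MatrixValidationError(
                f"usable_share must lie in (0, 1], got {self.usable_share}"
            )

    @property
    def usable_potential(self) -> float:
        """Technical potential discounted by the usable share, Mg DM a⁻¹."""
        return self.technical_potential * self.usable_share


@dataclass(frozen=True)
class ResourceMatrix:
    """Ordered collection of residues plus assessment metadata."""

    residues: tuple[Residue, ...] = ()
    reference_year: int = 2025
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        ids = [r.id for r in self.residues]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MatrixValidationError(f"duplicate residue ids: {dupes}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.residues)

    def get(self, residue_id: str) -> Residue:
        for r in self.residues:
            if r.id == residue_id:
                return r
        raise KeyError(residue_id)

    def subset(self, ids: Sequence[str]) -> "ResourceMatrix":
        """Order-preserving restriction to the given ids (all must resolve)."""
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise MatrixValidationError(f"unknown residue ids: {sorted(unknown)}")
        return ResourceMatrix(
            tuple(r for r in self.residues if r.id in wanted),
            reference_year=self.reference_year,
            provenance=self.provenance,
        )

    @property
    def total_technical_potential(self) -> float:
        return sum(r.technical_potential for r in self.residues)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ("id", "name", "sector", "technical_potential_Mg_DM_a", "usable_share")
_QUALITY_COLUMNS = ("n_sources", "analysis_quality", "newest_source_year")


def matrix_columns() -> list[str]:
    """Canonical column order of the matrix file format."""
    cols = list(_BASE_COLUMNS)
    for frac in FRACTIONS:
        cols += [f"{frac}_min", f"{frac}_mean", f"{frac}_max"]
    cols += list(_QUALITY_COLUMNS)
    return cols


def _parse_float(raw: str, row: int, col: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise MatrixFormatError(
            f"row {row}, column {col!r}: not numeric: {raw!r}"
        ) from exc


def _parse_int(raw: str, row: int, col: str) -> int:
    raw = raw.strip()
    try:
        return int(raw)
    except ValueError as exc:
        raise MatrixFormatError(
            f"row {row}, column {col!r}: not an integer: {raw!r}"
        ) from exc


def load_matrix(path: str | Path, dialect: str | None = None) -> ResourceMatrix:
    """Read and validate a resource matrix from a delimited UTF-8 text file.

    Leading ``#`` comment lines may carry ``reference_year`` and ``provenance``
    metadata.  The delimiter is taken from ``dialect`` if given, otherwise
    auto-detected from the header line (tab beats comma).  Rows violating
    domain invariants are rejected with row-indexed diagnostics.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line.lstrip("#").strip()
        if ":" in stripped:
            key, _, value = stripped.partition(":")
            meta[key.strip()] = value.strip()
    if body_start >= len(lines) or not lines[body_start].strip():
        raise MatrixFormatError(f"{path}: no header row found")
    header = lines[body_start]
    sep = dialect if dialect is not None else ("\t" if "\t" in header else ",")
    frame = pd.read_csv(
        io.StringIO("\n".join(lines[body_start:])),
        sep=sep,
        dtype=str,
        keep_default_na=False,
    )
    missing = [c for c in matrix_columns() if c not in frame.columns]
    if missing:
        raise MatrixFormatError(f"{path}: missing required columns {missing}")

    reference_year = int(meta.get("reference_year", "2025"))
    provenance = meta.get("provenance", "")

    residues: list[Residue] = []
    errors: list[str] = []
    for i, row in frame.iterrows():
        try:
            stats = {}
            for frac in FRACTIONS:
                stats[frac] = FractionStat(
                    min=_parse_float(row[f"{frac}_min"], i, f"{frac}_min"),
                    mean=_parse_float(row[f"{frac}_mean"], i, f"{frac}_mean"),
                    max=_parse_float(row[f"{frac}_max"], i, f"{frac}_max"),
                )
            potential = _parse_float(
                row["technical_potential_Mg_DM_a"], i, "technical_potential_Mg_DM_a"
            )
            if potential is None:
                raise MatrixFormatError(
                    f"row {i}: technical_potential_Mg_DM_a is required"
                )
            usable = _parse_float(row["usable_share"], i, "usable_share")
            quality = QualityMeta(
                n_sources=_parse_int(row["n_sources"], i, "n_sources"),
                analysis_quality=row["analysis_quality"].strip(),
                newest_source_year=_parse_int(
                    row["newest_source_year"], i, "newest_source_year"
                ),
                reference_year=reference_year,
            )
            residues.append(
                Residue(
                    id=row["id"].strip(),
                    name=row["name"].strip(),
                    sector=row["sector"].strip(),
                    technical_potential=potential,
                    composition=CompositionProfile(stats),
                    quality=quality,
                    usable_share=1.0 if usable is None else usable,
                )
            )
        except (MatrixFormatError, MatrixValidationError) as exc:
            errors.append(f"row {i} (id={row.get('id', '?')}): {exc}")
    if errors:
        raise MatrixValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return ResourceMatrix(
        tuple(residues), reference_year=reference_year, provenance=provenance
    )


def save_matrix(matrix: ResourceMatrix, path: str | Path) -> None:
    """Write a matrix to comma-delimited text; round-trips with :func:`load_matrix`.

    Unknown fraction values are written as empty cells, never coerced to 0.
    """
    path = Path(path)

    def fmt(value: float | int | None) -> str:
        if value is None:
            return ""
        # repr of a Python float round-trips exactly (casts numpy scalars)
        return repr(float(value)) if isinstance(value, float) else str(value)

    rows = []
    for r in matrix:
        row: dict[str, str] = {
            "id": r.id,
            "name": r.name,
            "sector": r.sector,
            "technical_potential_Mg_DM_a": fmt(r.technical_potential),
            "usable_share": fmt(r.usable_share),
        }
        for frac in FRACTIONS:
            stat = r.composition.fractions[frac]
            row[f"{frac}_min"] = fmt(stat.min)
            row[f"{frac}_mean"] = fmt(stat.mean)
            row[f"{frac}_max"] = fmt(stat.max)
        row["n_sources"] = str(r.quality.n_sources)
        row["analysis_quality"] = r.quality.analysis_quality
        row["newest_source_year"] = str(r.quality.newest_source_year)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=matrix_columns())
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# reference_year: {matrix.reference_year}\n")
        if matrix.provenance:
            fh.write(f"# provenance: {matrix.provenance}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def apply_potential_cutoff(matrix: ResourceMatrix, cutoff: float) -> ResourceMatrix:
    """Retain residues with technical potential ≥ ``cutoff`` (Mg DM a⁻¹).

    Order-preserving and idempotent; the retained mass is non-increasing in
    the cutoff.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be ≥ 0, got {cutoff}")
    kept = tuple(r for r in matrix if r.technical_potential >= cutoff)
    return ResourceMatrix(
        kept, reference_year=matrix.reference_year, provenance=matrix.provenance
    )


# ---------------------------------------------------------------------------
# Data-quality scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RubricLevel:
    """Requirements that must ALL be met to earn a given quality level."""

    min_sources: int
    min_grade: str  # member of ANALYSIS_GRADES
    max_age_years: int  # recency: age strictly below this

    def met_by(self, q: QualityMeta) -> bool:
        grade_rank = ANALYSIS_GRADES.index(q.analysis_quality)
        need_rank = ANALYSIS_GRADES.index(self.min_grade)
        return (
            q.n_sources >= self.min_sources
            and grade_rank >= need_rank
            and q.age_years < self.max_age_years
        )


#: Default five-level rubric.  Levels 1–4 carry explicit requirements;
#: level 5 ("not reliable") is the fallback.  Requirements weaken
#: monotonically with the level, which makes the score monotone in each
#: criterion independently.
DEFAULT_RUBRIC: dict[int, RubricLevel] = {
    1: RubricLevel(min_sources=3, min_grade="detailed_with_series", max_age_years=5),
    2: RubricLevel(min_sources=2, min_grade="detailed", max_age_years=10),
    3: RubricLevel(min_sources=2, min_grade="method_stated", max_age_years=20),
    4: RubricLevel(min_sources=1, min_grade="method_stated", max_age_years=30),
}


def _validate_rubric(rubric: Mapping[int, RubricLevel]) -> None:
    levels = sorted(rubric)
    if levels != list(range(1, len(levels) + 1)):
        raise ValueError(f"rubric levels must be 1..{len(levels)}, got {levels}")
    for lo, hi in zip(levels, levels[1:]):
        a, b = rubric[lo], rubric[hi]
        if b.min_grade not in ANALYSIS_GRADES or a.min_grade not in ANALYSIS_GRADES:
            raise ValueError("rubric grades must be members of ANALYSIS_GRADES")
        if (
            b.min_sources > a.min_sources
            or ANALYSIS_GRADES.index(b.min_grade) > ANALYSIS_GRADES.index(a.min_grade)
            or b.max_age_years < a.max_age_years
        ):
            raise ValueError(
                f"rubric requirements must weaken monotonically: level {hi} is "
                f"stricter than level {lo} on some criterion"
            )


def score_data_quality(
    q: QualityMeta, rubric: Mapping[int, RubricLevel] | None = None
) -> int:
    """Best (lowest) quality level whose requirements are all met; worst level otherwise.

    With the default rubric: 1 = good ... 5 = not reliable.  The score is
    monotone — improving any single criterion never worsens (increases) it.
    """
    if rubric is None:
        rubric = DEFAULT_RUBRIC
    else:
        _validate_rubric(rubric)
    worst = len(rubric) + 1
    for level in sorted(rubric):
        if rubric[level].met_by(q):
            return level
    return worst


# ---------------------------------------------------------------------------
# Suitability summary
# ---------------------------------------------------------------------------


def suitability_summary(
    matrix: ResourceMatrix, assignments: Mapping[str, str]
) -> pd.DataFrame:
    """Per-class technical-potential mass and share of the portfolio total.

    ``assignments`` maps every residue id to exactly one class in
    :data:`SUITABILITY_CLASSES`.  Shares sum to 1 and are invariant to
    residue ordering.
    """
    ids = set(matrix.ids)
    unassigned = ids - set(assignments)
    if unassigned:
        raise ValueError(f"unassigned residues: {sorted(unassigned)}")
    unknown = set(assignments) - ids
    if unknown:
        raise ValueError(f"assignments for unknown residues: {sorted(unknown)}")
    bad = {c for c in assignments.values() if c not in SUITABILITY_CLASSES}
    if bad:
        raise ValueError(
            f"unknown suitability classes {sorted(bad)}; "
            f"expected one of {SUITABILITY_CLASSES}"
        )
    total = matrix.total_technical_potential
    if total <= 0:
        raise ValueError("total technical potential must be > 0")
    masses = dict.fromkeys(SUITABILITY_CLASSES, 0.0)
    for r in matrix:
        masses[assignments[r.id]] += r.technical_potential
    frame = pd.DataFrame(
        {
            "mass_Mg_DM_a": [masses[c] for c in SUITABILITY_CLASSES],
            "share": [masses[c] / total for c in SUITABILITY_CLASSES],
        },
        index=pd.Index(SUITABILITY_CLASSES, name="suitability_class"),
    )
    return frame
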