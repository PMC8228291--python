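"""Cohort data model for tiered diagnostic-pathway studies.

The unit of analysis is the proband: each patient carries the tier of the
stepwise genetic workup at which a molecular diagnosis was first achieved
(``diagnostic_level`` 1..k) or 0 if no tier was diagnostic.  Variant-level
detail (gene, genotype class) is carried as annotation only; the package
never touches sequencing data.

The monotone-diagnosis assumption — a patient diagnosed at an earlier,
narrower tier would also have been diagnosed by any later, more inclusive
tier — is encoded by the cumulative indicator matrix derived from
:class:`OutcomeMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "Cohort",
    "OutcomeMatrix",
    "SimulationSpec",
    "CohortFormatError",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "outcome_matrix",
    "simulate_cohort",
]

SEXES = frozenset({"M", "F"})
GENOTYPE_CLASSES = frozenset({"Het", "Hom", "Hemi"})

#: Canonical TSV column order; ``phenotype_label`` is optional on read.
TSV_COLUMNS = (
    "patient_id",
    "diagnostic_level",
    "sex",
    "age_years",
    "age_at_diagnosis_years",
    "gene",
    "genotype_class",
    "phenotype_label",
)


class CohortFormatError(ValueError):
    """A cohort file does not have the expected tabular structure."""


class CohortValidationError(ValueError):
    """A record or cohort violates a domain invariant."""


@dataclass(frozen=True)
class PatientRecord:
    """One proband.

    Parameters
    ----------
    patient_id
        Unique identifier within the cohort.
    diagnostic_level
        Tier (1-based) at which a molecular diagnosis was first achieved,
        or 0 for an undiagnosed patient.
    sex, age_years, age_at_diagnosis_years, gene, genotype_class,
    phenotype_label
        Optional annotations; diagnosis-related annotations must be absent
        for undiagnosed patients.
    """

    patient_id: str
    diagnostic_level: int
    sex: str | None = None
    age_years: float | None = None
    age_at_diagnosis_years: float | None = None
    gene: str | None = None
    genotype_class: str | None = None
    phenotype_label: str | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be non-empty")
        lvl = self.diagnostic_level
        if not isinstance(lvl, (int, np.integer)) or isinstance(lvl, bool) or lvl < 0:
            raise CohortValidationError(
                f"record {self.patient_id!r}: diagnostic_level must be a "
                f"non-negative integer, got {lvl!r}"
            )
        object.__setattr__(self, "diagnostic_level", int(lvl))
        if self.sex is not None and self.sex not in SEXES:
            raise CohortValidationError(
                f"record {self.patient_id!r}: sex must be one of {sorted(SEXES)}"
            )
        if self.genotype_class is not None and self.genotype_class not in GENOTYPE_CLASSES:
            raise CohortValidationError(
                f"record {self.patient_id!r}: genotype_class must be one of "
                f"{sorted(GENOTYPE_CLASSES)}, got {self.genotype_class!r}"
            )
        for name in ("age_years", "age_at_diagnosis_years"):
            value = getattr(self, name)
            if value is not None and not value >= 0:
                raise CohortValidationError(
                    f"record {self.patient_id!r}: {name} must be non-negative"
                )
        if self.gene is not None and not self.gene:
            raise CohortValidationError(
                f"record {self.patient_id!r}: gene, when present, must be non-empty"
            )
        if self.diagnostic_level == 0:
            for name in ("gene", "genotype_class", "age_at_diagnosis_years"):
                if getattr(self, name) is not None:
                    raise CohortValidationError(
                        f"record {self.patient_id!r}: undiagnosed patient must not "
                        f"carry {name}"
                    )


class Cohort:
    """An ordered collection of :class:`PatientRecord` with unique ids."""

    def __init__(self, records: Sequence[PatientRecord]):
        records = tuple(records)
        if len(records) == 0:
            raise CohortValidationError("a cohort must contain at least one record")
        ids = [r.patient_id for r in records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise CohortValidationError(f"duplicate patient_id {dup!r}")
        self._records = records

    @property
    def records(self) -> tuple[PatientRecord, ...]:
        return self._records

    @property
    def n(self) -> int:
        return len(self._records)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"Cohort(n={self.n}, diagnosed={int(np.sum(self.levels() > 0))})"

    def levels(self) -> np.ndarray:
        """Diagnostic level of every patient, in record order."""
        return np.array([r.diagnostic_level for r in self._records], dtype=np.int64)

    def max_level(self) -> int:
        return int(self.levels().max())

    def tier_counts(self, k: int = 3) -> np.ndarray:
        """Number of patients first diagnosed at each tier 1..k."""
        lv = self.levels()
        if lv.max() > k:
            raise CohortValidationError(
                f"cohort contains diagnostic_level {lv.max()} > k={k}"
            )
        return np.array([int(np.sum(lv == j)) for j in range(1, k + 1)])

    @property
    def n_undiagnosed(self) -> int:
        return int(np.sum(self.levels() == 0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(r, c) for c in TSV_COLUMNS} for r in self._records],
            columns=list(TSV_COLUMNS),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, max_level: int | None = None) -> "Cohort":
        """Build a cohort from a data frame with the canonical columns.

        Unknown columns are ignored with a warning; ``patient_id`` and
        ``diagnostic_level`` are required.
        """
        required = {"patient_id", "diagnostic_level"}
        missing = required - set(df.columns)
        if missing:
            raise CohortFormatError(f"missing required column(s): {sorted(missing)}")
        unknown = [c for c in df.columns if c not in TSV_COLUMNS]
        if unknown:
            logger.warning("ignoring unknown column(s): %s", unknown)
        records = []
        for idx, row in df.iterrows():
            lvl_raw = row["diagnostic_level"]
            try:
                lvl_float = float(lvl_raw)
            except (TypeError, ValueError):
                raise CohortValidationError(
                    f"row {idx}: diagnostic_level {lvl_raw!r} is not an integer"
                ) from None
            if not float(lvl_float).is_integer():
                raise CohortValidationError(
                    f"row {idx}: diagnostic_level {lvl_raw!r} is not an integer"
                )
            lvl = int(lvl_float)
            if lvl < 0 or (max_level is not None and lvl > max_level):
                raise CohortValidationError(
                    f"row {idx} (patient_id={row['patient_id']!r}): diagnostic_level "
                    f"{lvl} outside 0..{max_level}"
                )
            kwargs: dict[str, object] = {}
            for name in ("sex", "gene", "genotype_class", "phenotype_label"):
                if name in df.columns:
                    v = row[name]
                    kwargs[name] = None if _is_blank(v) else str(v)
            for name in ("age_years", "age_at_diagnosis_years"):
                if name in df.columns:
                    v = row[name]
                    kwargs[name] = None if _is_blank(v) else float(v)
            records.append(
                PatientRecord(patient_id=str(row["patient_id"]), diagnostic_level=lvl, **kwargs)
            )
        return cls(records)


def _is_blank(v: object) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""


def load_cohort(path: str | Path, max_level: int = 3) -> Cohort:
    """Read a cohort from a UTF-8 tab-separated file.

    The file must have a header row containing at least ``patient_id`` and
    ``diagnostic_level``; empty strings stand for absent optional values.
    ``diagnostic_level`` outside ``0..max_level`` is a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise CohortFormatError(f"{path}: {exc}") from exc
    return Cohort.from_dataframe(df, max_level=max_level)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as UTF-8 TSV with the canonical column order.

    ``write_cohort`` followed by :func:`load_cohort` reproduces an identical
    cohort (empty string encodes an absent optional value; level 0 is an
    explicit value, never a sentinel).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in cohort:
            cells = []
            for c in TSV_COLUMNS:
                v = getattr(r, c)
                if v is None:
                    cells.append("")
                elif isinstance(v, float):
                    cells.append(format(v, "g"))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


@dataclass(frozen=True)
class OutcomeMatrix:
    """n x k binary matrix of marginal (tier-specific) diagnosis indicators.

    Entry ``(i, j)`` is 1 iff patient ``i`` was first diagnosed at tier
    ``j+1``; rows of undiagnosed patients are all-zero, so every row sums to
    at most 1.  The running row-wise maximum (:attr:`cumulative`) gives the
    "diagnosed by tier j" indicators implied by the monotone-diagnosis
    assumption.
    """

    marginal: np.ndarray
    tier_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.marginal, dtype=np.int64)
        if m.ndim != 2:
            raise CohortValidationError("marginal matrix must be 2-D")
        if not np.isin(m, (0, 1)).all():
            raise CohortValidationError("marginal matrix must be binary")
        if (m.sum(axis=1) > 1).any():
            raise CohortValidationError("a patient can be first-diagnosed at most once")
        object.__setattr__(self, "marginal", m)
        labels = self.tier_labels or tuple(f"tier{j}" for j in range(1, m.shape[1] + 1))
        if len(labels) != m.shape[1]:
            raise CohortValidationError("tier_labels length must equal k")
        object.__setattr__(self, "tier_labels", tuple(labels))

    @property
    def n(self) -> int:
        return self.marginal.shape[0]

    @property
    def k(self) -> int:
        return self.marginal.shape[1]

    @property
    def column_sums(self) -> np.ndarray:
        """Marginal diagnosis counts (d_1, ..., d_k)."""
        return self.marginal.sum(axis=0)

    @property
    def cumulative(self) -> np.ndarray:
        """Indicators "diagnosed at or before tier j"; monotone along tiers."""
        return np.maximum.accumulate(self.marginal, axis=1)


def outcome_matrix(cohort: Cohort, k: int = 3) -> OutcomeMatrix:
    """Marginal diagnosis-indicator matrix of a cohort over ``k`` tiers."""
    lv = cohort.levels()
    if lv.max() > k:
        raise CohortValidationError(
            f"cohort contains diagnostic_level {lv.max()} > k={k}"
        )
    m = np.zeros((cohort.n, k), dtype=np.int64)
    diagnosed = lv > 0
    m[np.flatnonzero(diagnosed), lv[diagnosed] - 1] = 1
    return OutcomeMatrix(m)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic multinomial cohort.

    ``probs`` holds ``(p_1, ..., p_k, p_none)``: the probability of a
    proband being first diagnosed at each tier, and of remaining
    undiagnosed; the entries must be non-negative and sum to one.
    """

    n: int
    probs: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortValidationError("n must be >= 1")
        probs = tuple(float(p) for p in self.probs)
        if len(probs) < 2:
            raise CohortValidationError("probs needs at least one tier plus p_none")
        if any(p < 0 for p in probs):
            raise CohortValidationError("probabilities must be non-negative")
        if abs(sum(probs) - 1.0) >= 1e-12:
            raise CohortValidationError(
                f"probabilities must sum to 1, got {sum(probs)!r}"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def k(self) -> int:
        return len(self.probs) - 1


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    """Draw a cohort of independent probands from a multinomial outcome model.

    Each record's diagnostic level is drawn independently from
    ``(tier 1, ..., tier k, none)`` with the probabilities of ``spec``.
    The generator is owned by the call and seeded from ``spec.seed``, so an
    identical spec reproduces the identical cohort bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    categories = np.array(list(range(1, spec.k + 1)) + [0], dtype=np.int64)
    levels = rng.choice(categories, size=spec.n, p=np.array(spec.probs))
    width = max(4, len(str(spec.n)))
    records = [
        PatientRecord(patient_id=f"S{i + 1:0{width}d}", diagnostic_level=int(lv))
        for i, lv in enumerate(levels)
    ]
    return Cohort(records)
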