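"""Reimbursement cost engine for tiered diagnostic pathways.

A pathway is an ordered list of costed tiers; every patient enters at tier
1 and undergoes tiers in order, leaving after the first tier whose
cumulative detection set contains the patient's diagnostic level.  Patients
whose level is never covered (including the undiagnosed, level 0) undergo
every tier.  Each tier performed is reimbursed at the tier's unit cost; by
default every NGS analysis carries the same tariff regardless of technique.

Three standard strategies are provided for a k=3 workup:

* ``two-step-panels`` (the reference): first-step panel, then the broader
  reanalysis panel; tier-3-only diagnoses are missed.
* ``panels-then-exome``: the two panels followed by exome sequencing as a
  separately reimbursed third-step test.
* ``exome-first``: exome sequencing as the single costed act; the tiered
  virtual panels are applied in silico to the stored data, so reanalysis
  incurs no new reimbursement and all levels are detected for one tariff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .cohort import Cohort, CohortValidationError

__all__ = [
    "UNIT_COST_EUR",
    "TierDefinition",
    "PathwayModel",
    "CostResult",
    "IncrementalResult",
    "standard_pathways",
    "StandardPathways",
    "apply_pathway",
    "incremental",
    "round_eur",
]

#: Regional public-health reimbursement per NGS analysis, in euros.
UNIT_COST_EUR = 2072.74


def round_eur(x: float, decimals: int = 2) -> float:
    """Round half-up to euro cents (display convention for money)."""
    q = 10.0**decimals
    return math.floor(x * q + 0.5) / q


@dataclass(frozen=True)
class TierDefinition:
    """One costed testing step and the diagnostic levels it resolves."""

    label: str
    unit_cost: float
    detects: frozenset[int]

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise CohortValidationError(f"tier {self.label!r}: unit_cost must be >= 0")
        detects = frozenset(int(d) for d in self.detects)
        if not detects:
            raise CohortValidationError(f"tier {self.label!r}: detects must be non-empty")
        if any(d < 1 for d in detects):
            raise CohortValidationError(
                f"tier {self.label!r}: detection set must contain positive levels"
            )
        object.__setattr__(self, "detects", detects)


@dataclass(frozen=True)
class PathwayModel:
    """An ordered diagnostic strategy of costed tiers with disjoint detection sets."""

    name: str
    tiers: tuple[TierDefinition, ...]

    def __post_init__(self) -> None:
        tiers = tuple(self.tiers)
        if not tiers:
            raise CohortValidationError(f"pathway {self.name!r} needs at least one tier")
        seen: set[int] = set()
        for t in tiers:
            if seen & t.detects:
                raise CohortValidationError(
                    f"pathway {self.name!r}: detection sets must be disjoint"
                )
            seen |= t.detects
        object.__setattr__(self, "tiers", tiers)

    @property
    def n_tiers(self) -> int:
        return len(self.tiers)

    def cumulative_detects(self, t: int) -> frozenset[int]:
        """Union of detection sets of tiers 1..t (1-based)."""
        out: frozenset[int] = frozenset()
        for tier in self.tiers[:t]:
            out |= tier.detects
        return out

    @property
    def detects_all(self) -> frozenset[int]:
        return self.cumulative_detects(self.n_tiers)


class StandardPathways(NamedTuple):
    reference: PathwayModel
    panels_then_exome: PathwayModel
    exome_first: PathwayModel


def standard_pathways(unit_cost: float = UNIT_COST_EUR, k: int = 3) -> StandardPathways:
    """The three standard strategies for a k-tier workup, sharing one tariff.

    The reference runs the k-1 panel steps; ``panels-then-exome`` adds the
    exome as a costed tier resolving level k; ``exome-first`` is a single
    costed exome whose in-silico reanalysis resolves every level.
    """
    if unit_cost < 0:
        raise CohortValidationError("unit_cost must be >= 0")
    if k < 2:
        raise CohortValidationError("standard pathways require k >= 2")
    panels = tuple(
        TierDefinition(label=f"panel{j}", unit_cost=unit_cost, detects=frozenset({j}))
        for j in range(1, k)
    )
    exome_tail = TierDefinition(
        label="exome", unit_cost=unit_cost, detects=frozenset({k})
    )
    exome_only = TierDefinition(
        label="exome-dynamic", unit_cost=unit_cost, detects=frozenset(range(1, k + 1))
    )
    return StandardPathways(
        reference=PathwayModel(name="two-step-panels", tiers=panels),
        panels_then_exome=PathwayModel(
            name="panels-then-exome", tiers=panels + (exome_tail,)
        ),
        exome_first=PathwayModel(name="exome-first", tiers=(exome_only,)),
    )


@dataclass(frozen=True)
class CostResult:
    """Tests performed, spend and yield of one pathway on one cohort.

    ``cost_per_diagnosis`` is None when the pathway diagnoses nobody; money
    fields are exact (unrounded) euros — use :func:`round_eur` for display.
    """

    pathway_name: str
    n: int
    tests_per_tier: tuple[int, ...]
    total_tests: int
    total_cost: float
    n_diagnosed: int
    cost_per_diagnosis: float | None

    def to_dict(self) -> dict[str, object]:
        return {
            "pathway": self.pathway_name,
            "n": self.n,
            "tests_per_tier": list(self.tests_per_tier),
            "total_tests": self.total_tests,
            "total_cost_eur": self.total_cost,
            "total_cost_eur_rounded": round_eur(self.total_cost),
            "n_diagnosed": self.n_diagnosed,
            "cost_per_diagnosis_eur": self.cost_per_diagnosis,
            "cost_per_diagnosis_eur_rounded": (
                None if self.cost_per_diagnosis is None else round_eur(self.cost_per_diagnosis)
            ),
        }


def _as_levels(cohort: "Cohort | np.ndarray | Sequence[int]") -> np.ndarray:
    if isinstance(cohort, Cohort):
        return cohort.levels()
    return np.asarray(cohort, dtype=np.int64)


def apply_pathway(cohort: "Cohort | np.ndarray | Sequence[int]", pathway: PathwayModel) -> CostResult:
    """Run a cohort through a pathway and account tests, cost and diagnoses.

    Accepts a :class:`~tierdx.cohort.Cohort` or a plain array of diagnostic
    levels (the fast path used by the bootstrap).
    """
    levels = _as_levels(cohort)
    n = levels.size
    if n == 0:
        raise CohortValidationError("cannot cost an empty cohort")
    # exit_tier[i] = 1-based tier at which patient i leaves, or n_tiers+1 if never
    max_lv = int(levels.max(initial=0))
    exit_of_level = np.full(max_lv + 1, pathway.n_tiers + 1, dtype=np.int64)
    for t, tier in enumerate(pathway.tiers, start=1):
        for lv in tier.detects:
            if lv <= max_lv:
                exit_of_level[lv] = t
    exit_tier = exit_of_level[levels]
    tests_per_tier = tuple(
        int(np.sum(exit_tier >= t)) for t in range(1, pathway.n_tiers + 1)
    )
    total_cost = float(
        sum(cnt * tier.unit_cost for cnt, tier in zip(tests_per_tier, pathway.tiers))
    )
    n_diagnosed = int(np.sum(exit_tier <= pathway.n_tiers))
    cpd = total_cost / n_diagnosed if n_diagnosed > 0 else None
    return CostResult(
        pathway_name=pathway.name,
        n=n,
        tests_per_tier=tests_per_tier,
        total_tests=int(sum(tests_per_tier)),
        total_cost=total_cost,
        n_diagnosed=n_diagnosed,
        cost_per_diagnosis=cpd,
    )


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost and effect of a strategy over a reference.

    ``icer`` (incremental cost per additional diagnosis) is defined when
    both deltas are positive; ``dominant`` flags a strategy that is at least
    as effective at no greater cost (and not identical to the reference).
    """

    model_name: str
    reference_name: str
    n: int
    delta_cost: float
    delta_diagnoses: int
    icer: float | None
    dominant: bool

    def to_dict(self) -> dict[str, object]:
        return {
            "model": self.model_name,
            "reference": self.reference_name,
            "n": self.n,
            "delta_cost_eur": self.delta_cost,
            "delta_cost_eur_rounded": round_eur(self.delta_cost),
            "delta_diagnoses": self.delta_diagnoses,
            "icer_eur_per_diagnosis": self.icer,
            "icer_eur_per_diagnosis_rounded": (
                None if self.icer is None else round_eur(self.icer)
            ),
            "dominant": self.dominant,
        }


def incremental(model: CostResult, reference: CostResult) -> IncrementalResult:
    """Incremental comparison of two cost results on the same cohort."""
    if model.n != reference.n:
        raise CohortValidationError(
            f"cohort sizes differ: {model.n} vs {reference.n}"
        )
    delta_cost = model.total_cost - reference.total_cost
    delta_diag = model.n_diagnosed - reference.n_diagnosed
    dominant = delta_diag >= 0 and delta_cost <= 0 and not (delta_diag == 0 and delta_cost == 0)
    icer = delta_cost / delta_diag if (delta_diag > 0 and not dominant) else None
    return IncrementalResult(
        model_name=model.pathway_name,
        reference_name=reference.pathway_name,
        n=model.n,
        delta_cost=delta_cost,
        delta_diagnoses=delta_diag,
        icer=icer,
        dominant=dominant,
    )
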