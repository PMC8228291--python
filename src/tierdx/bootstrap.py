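"""Patient-level bootstrap and the cost-effectiveness (CE) plane.

Uncertainty in the incremental cost and incremental number of diagnoses is
assessed by resampling whole patients (their full outcome vector) with
replacement; the reference and every comparator strategy are costed on the
SAME resampled cohort in each replicate, so the plotted quantities are
properly paired.  Each replicate yields one point per strategy on the CE
plane: additional diagnoses on the x-axis, additional cost on the y-axis.
The lower-right (SE) quadrant — more diagnoses at lower cost — is the
dominant, "leading" region; the half-plane below the x-axis is cost saving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortValidationError
from .costs import PathwayModel, apply_pathway, incremental

__all__ = [
    "BootstrapSpec",
    "CESummary",
    "bootstrap_ce",
    "classify_quadrant",
    "summarize_ce",
    "nearest_rank_percentile",
    "plot_ce_plane",
]

#: Default number of bootstrap replicates.
DEFAULT_REPLICATES = 500
#: Default, documented seed used when none is supplied.
DEFAULT_SEED = 2021


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap settings; the resampling unit is always the patient."""

    n_replicates: int = DEFAULT_REPLICATES
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise CohortValidationError("n_replicates must be >= 1")


def classify_quadrant(delta_diagnoses: float, delta_cost: float) -> str:
    """CE-plane quadrant of one incremental point.

    Sign-based: NE (more effect, more cost), SE (more effect, cost saving —
    dominant), NW, SW; any point with a zero coordinate is labelled
    ``axis``.
    """
    if delta_diagnoses == 0 or delta_cost == 0:
        return "axis"
    if delta_diagnoses > 0:
        return "NE" if delta_cost > 0 else "SE"
    return "NW" if delta_cost > 0 else "SW"


def bootstrap_ce(
    cohort: Cohort,
    models: Sequence[PathwayModel],
    reference: PathwayModel,
    spec: BootstrapSpec | None = None,
) -> pd.DataFrame:
    """Bootstrap the CE plane for one or more strategies against a reference.

    Returns a tidy frame with one row per (replicate, model): columns
    ``replicate``, ``model``, ``delta_diagnoses``, ``delta_cost``,
    ``quadrant``.  Fully reproducible from ``spec.seed``.
    """
    spec = spec or BootstrapSpec()
    if not models:
        raise CohortValidationError("at least one comparator model is required")
    rng = np.random.default_rng(spec.seed)
    levels = cohort.levels()
    n = levels.size
    rows = []
    for b in range(spec.n_replicates):
        resampled = levels[rng.integers(0, n, size=n)]
        ref_res = apply_pathway(resampled, reference)
        for model in models:
            inc = incremental(apply_pathway(resampled, model), ref_res)
            rows.append(
                (
                    b,
                    model.name,
                    inc.delta_diagnoses,
                    inc.delta_cost,
                    classify_quadrant(inc.delta_diagnoses, inc.delta_cost),
                )
            )
    return pd.DataFrame(
        rows, columns=["replicate", "model", "delta_diagnoses", "delta_cost", "quadrant"]
    )


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (no interpolation): smallest value whose
    rank is at least ceil(q/100 * n)."""
    if not 0 < q <= 100:
        raise CohortValidationError("percentile must lie in (0, 100]")
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size == 0:
        raise CohortValidationError("cannot take a percentile of no values")
    rank = max(1, math.ceil(q / 100.0 * v.size))
    return float(v[rank - 1])


@dataclass(frozen=True)
class CESummary:
    """Per-strategy aggregation of a bootstrap point cloud."""

    model_name: str
    n_replicates: int
    quadrant_proportions: dict[str, float]
    mean_delta_cost: float
    delta_cost_ci: tuple[float, float]
    mean_delta_diagnoses: float
    delta_diagnoses_ci: tuple[float, float]
    dominance_proportion: float

    def to_dict(self) -> dict[str, object]:
        return {
            "model": self.model_name,
            "n_replicates": self.n_replicates,
            "quadrant_proportions": dict(self.quadrant_proportions),
            "mean_delta_cost_eur": self.mean_delta_cost,
            "delta_cost_ci_eur": list(self.delta_cost_ci),
            "mean_delta_diagnoses": self.mean_delta_diagnoses,
            "delta_diagnoses_ci": list(self.delta_diagnoses_ci),
            "dominance_proportion": self.dominance_proportion,
        }


def summarize_ce(points: pd.DataFrame) -> dict[str, CESummary]:
    """Summarise a CE point cloud per strategy.

    Intervals are nearest-rank 2.5/97.5 percentiles; the dominance
    proportion is the fraction of replicates with at least as many
    diagnoses at no greater cost (excluding exact ties on both axes).
    """
    if points.empty:
        raise CohortValidationError("no points to summarise")
    out: dict[str, CESummary] = {}
    for name, grp in points.groupby("model", sort=False):
        B = len(grp)
        quadrants = {
            q: float((grp["quadrant"] == q).sum()) / B
            for q in ("NE", "SE", "NW", "SW", "axis")
        }
        dd = grp["delta_diagnoses"].to_numpy(dtype=np.float64)
        dc = grp["delta_cost"].to_numpy(dtype=np.float64)
        dominant = (dd >= 0) & (dc <= 0) & ~((dd == 0) & (dc == 0))
        out[name] = CESummary(
            model_name=name,
            n_replicates=B,
            quadrant_proportions=quadrants,
            mean_delta_cost=float(dc.mean()),
            delta_cost_ci=(
                nearest_rank_percentile(dc, 2.5),
                nearest_rank_percentile(dc, 97.5),
            ),
            mean_delta_diagnoses=float(dd.mean()),
            delta_diagnoses_ci=(
                nearest_rank_percentile(dd, 2.5),
                nearest_rank_percentile(dd, 97.5),
            ),
            dominance_proportion=float(dominant.mean()),
        )
    return out


def plot_ce_plane(points: pd.DataFrame, ax=None, jitter: float = 0.12, seed: int = 0):
    """Scatter the bootstrap CE plane, one colour per strategy.

    Shades the cost-saving half-plane (below the x-axis) and draws the
    quadrant axes.  ``delta_diagnoses`` is integer-valued, so a small
    horizontal jitter (visual only) keeps overlapping points readable.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    rng = np.random.default_rng(seed)
    for name, grp in points.groupby("model", sort=False):
        x = grp["delta_diagnoses"].to_numpy(dtype=np.float64)
        if jitter:
            x = x + rng.uniform(-jitter, jitter, size=x.size)
        ax.scatter(x, grp["delta_cost"], s=14, alpha=0.55, label=name)
    ax.axhline(0.0, color="0.3", lw=1)
    ax.axvline(0.0, color="0.3", lw=1)
    ylim = ax.get_ylim()
    ax.axhspan(min(ylim[0], 0.0), 0.0, color="tab:green", alpha=0.08)
    ax.set_ylim(ylim)
    ax.set_xlabel("additional diagnoses (effect)")
    ax.set_ylabel("additional cost (EUR)")
    ax.set_title("Cost-effectiveness plane (bootstrap replicates)")
    ax.legend()
    return ax
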