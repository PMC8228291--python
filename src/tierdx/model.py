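"""Model/Results layer tying the pipeline together.

:class:`DiagnosticPathwayAnalysis` is built from a cohort plus the analysis
settings (number of tiers, unit reimbursement, significance level);
``fit()`` runs the full evaluation — yields, paired-proportion tests, the
three pathway cost models, incremental comparisons and (optionally) the
bootstrap CE plane — and returns a :class:`DiagnosticPathwayResults` whose
``summary()`` renders the headline numbers as a text report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bs
from .cohort import (
    Cohort,
    CohortValidationError,
    OutcomeMatrix,
    SimulationSpec,
    load_cohort,
    outcome_matrix,
    simulate_cohort,
)
from .costs import (
    UNIT_COST_EUR,
    CostResult,
    IncrementalResult,
    StandardPathways,
    apply_pathway,
    incremental,
    round_eur,
    standard_pathways,
)
from .stats import (
    CochranQResult,
    PairedTestResult,
    YieldTable,
    cochran_q,
    format_percent,
    pairwise_mcnemar,
    yield_table,
)

logger = logging.getLogger(__name__)

__all__ = ["DiagnosticPathwayAnalysis", "DiagnosticPathwayResults", "format_p"]


def format_p(p: float, decimals: int = 3) -> str:
    """p-value display: rounded to 3 decimals, "<0.001" when that rounds to 0."""
    rounded = round(p, decimals)
    if rounded < 10.0**-decimals:
        return f"<{10.0 ** -decimals:.{decimals}f}"
    return f"{rounded:.{decimals}f}"


class DiagnosticPathwayAnalysis:
    """Evaluation of a tiered diagnostic workup on one cohort.

    Parameters
    ----------
    cohort
        The proband cohort (each record carries its tier of diagnosis).
    k
        Number of tiers in the stepwise workup (default 3: first panel,
        reanalysis panel, full exome).
    unit_cost
        Reimbursement per NGS analysis in euros (default the regional
        tariff of 2072.74 EUR).
    alpha
        Significance level for the paired tests (default 0.05).
    """

    def __init__(
        self,
        cohort: Cohort,
        k: int = 3,
        unit_cost: float = UNIT_COST_EUR,
        alpha: float = 0.05,
    ):
        if not 0 < alpha < 1:
            raise CohortValidationError("alpha must lie strictly between 0 and 1")
        if cohort.max_level() > k:
            raise CohortValidationError(
                f"cohort has diagnostic levels above k={k}"
            )
        self.cohort = cohort
        self.k = int(k)
        self.unit_cost = float(unit_cost)
        self.alpha = float(alpha)
        self.pathways: StandardPathways = standard_pathways(unit_cost=unit_cost, k=k)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "DiagnosticPathwayAnalysis":
        k = kwargs.get("k", 3)
        return cls(load_cohort(path, max_level=k), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DiagnosticPathwayAnalysis":
        k = kwargs.get("k", 3)
        return cls(Cohort.from_dataframe(df, max_level=k), **kwargs)

    @classmethod
    def from_simulation(cls, spec: SimulationSpec, **kwargs) -> "DiagnosticPathwayAnalysis":
        kwargs.setdefault("k", spec.k)
        return cls(simulate_cohort(spec), **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        bootstrap: bool = True,
        n_replicates: int = bs.DEFAULT_REPLICATES,
        seed: int = bs.DEFAULT_SEED,
    ) -> "DiagnosticPathwayResults":
        """Run the full evaluation and return a results object."""
        matrix = outcome_matrix(self.cohort, k=self.k)
        logger.info("yields: n=%d, tier counts %s", matrix.n, matrix.column_sums.tolist())
        yields = yield_table(matrix)
        q = cochran_q(matrix)
        pairwise = pairwise_mcnemar(matrix, alpha=self.alpha)
        logger.info("Cochran's Q=%.4f (df=%d, p=%.3g)", q.statistic, q.df, q.p_value)

        costs = {
            p.name: apply_pathway(self.cohort, p) for p in self.pathways
        }
        reference = costs[self.pathways.reference.name]
        incrementals = {
            p.name: incremental(costs[p.name], reference)
            for p in (self.pathways.panels_then_exome, self.pathways.exome_first)
        }

        ce_points = None
        ce_summary = None
        if bootstrap:
            spec = bs.BootstrapSpec(n_replicates=n_replicates, seed=seed)
            logger.info("bootstrap: B=%d, seed=%d", spec.n_replicates, spec.seed)
            ce_points = bs.bootstrap_ce(
                self.cohort,
                models=[self.pathways.panels_then_exome, self.pathways.exome_first],
                reference=self.pathways.reference,
                spec=spec,
            )
            ce_summary = bs.summarize_ce(ce_points)

        return DiagnosticPathwayResults(
            model=self,
            yields=yields,
            cochran_q=q,
            pairwise=pairwise,
            costs=costs,
            incrementals=incrementals,
            ce_points=ce_points,
            ce_summary=ce_summary,
        )


@dataclass
class DiagnosticPathwayResults:
    """Fitted results of a :class:`DiagnosticPathwayAnalysis`."""

    model: DiagnosticPathwayAnalysis
    yields: YieldTable
    cochran_q: CochranQResult
    pairwise: list[PairedTestResult]
    costs: dict[str, CostResult]
    incrementals: dict[str, IncrementalResult]
    ce_points: pd.DataFrame | None = None
    ce_summary: dict[str, bs.CESummary] | None = None

    # -- tabular/structured views ----------------------------------------
    def yields_frame(self) -> pd.DataFrame:
        return self.yields.to_dataframe()

    def tests_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test": "cochran_q",
                "tiers": "all",
                "b": None,
                "c": None,
                "statistic": self.cochran_q.statistic,
                "df": self.cochran_q.df,
                "p_value": self.cochran_q.p_value,
                "significant": self.cochran_q.p_value <= self.model.alpha,
            }
        ]
        for r in self.pairwise:
            rows.append(
                {
                    "test": r.method,
                    "tiers": f"{r.tier_pair[0]}v{r.tier_pair[1]}",
                    "b": r.b,
                    "c": r.c,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
            )
        return pd.DataFrame(rows)

    def costs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.costs.values()]).drop(
            columns=["tests_per_tier"]
        )

    def incrementals_frame(self) -> pd.DataFrame:
        return pd.DataFrame([i.to_dict() for i in self.incrementals.values()])

    def to_dict(self) -> dict[str, object]:
        """Flat JSON-serialisable document of every computed statistic."""
        doc: dict[str, object] = {
            "n": self.yields.n,
            "k": self.yields.k,
            "alpha": self.model.alpha,
            "unit_cost_eur": self.model.unit_cost,
            "yields": {
                "marginal_counts": list(self.yields.marginal_counts),
                "marginal_yields": list(self.yields.marginal_yields),
                "cumulative_counts": list(self.yields.cumulative_counts),
                "cumulative_yields": list(self.yields.cumulative_yields),
                "overall_count": self.yields.overall_count,
                "overall_yield": self.yields.overall_yield,
            },
            "cochran_q": {
                "statistic": self.cochran_q.statistic,
                "df": self.cochran_q.df,
                "p_value": self.cochran_q.p_value,
                "degenerate": self.cochran_q.degenerate,
            },
            "pairwise_mcnemar": [
                {
                    "tiers": list(r.tier_pair),
                    "b": r.b,
                    "c": r.c,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
                for r in self.pairwise
            ],
            "costs": {name: c.to_dict() for name, c in self.costs.items()},
            "incrementals": {name: i.to_dict() for name, i in self.incrementals.items()},
        }
        if self.ce_summary is not None:
            doc["bootstrap"] = {name: s.to_dict() for name, s in self.ce_summary.items()}
        return doc

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        """Human-readable report of the headline numbers."""
        y = self.yields
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append("Tiered diagnostic pathway evaluation".center(w))
        lines.append("=" * w)
        lines.append(f"Probands: {y.n}    tiers: {y.k}    "
                     f"unit reimbursement: {round_eur(self.model.unit_cost):,.2f} EUR")
        lines.append("-" * w)
        lines.append("Diagnostic yield")
        lines.append(f"  overall: {y.overall_count}/{y.n} "
                     f"({format_percent(y.overall_yield)}%)")
        for j in range(y.k):
            lines.append(
                f"  {y.tier_labels[j]}: {y.marginal_counts[j]}/{y.n} "
                f"({format_percent(y.marginal_yields[j])}%)   "
                f"cumulative {y.cumulative_counts[j]}/{y.n} "
                f"({format_percent(y.cumulative_yields[j])}%)"
            )
        lines.append("-" * w)
        lines.append("Paired-proportion tests (marginal tier indicators)")
        lines.append(
            f"  Cochran's Q = {self.cochran_q.statistic:.3f} "
            f"(df={self.cochran_q.df}), p = {format_p(self.cochran_q.p_value)}"
        )
        for r in self.pairwise:
            star = " *" if r.significant else ""
            lines.append(
                f"  McNemar tiers {r.tier_pair[0]} vs {r.tier_pair[1]}: "
                f"b={r.b}, c={r.c}, chi2 = {r.statistic:.3f}, "
                f"p = {format_p(r.p_value)}{star}"
            )
        lines.append(f"  (* significant at alpha = {self.model.alpha})")
        lines.append("-" * w)
        lines.append("Pathway costs")
        for c in self.costs.values():
            cpd = ("undefined" if c.cost_per_diagnosis is None
                   else f"{round_eur(c.cost_per_diagnosis):,.2f} EUR")
            lines.append(
                f"  {c.pathway_name}: {c.total_tests} tests, "
                f"total {round_eur(c.total_cost):,.2f} EUR, "
                f"{c.n_diagnosed} diagnoses, {cpd} per diagnosis"
            )
        lines.append("-" * w)
        lines.append(f"Incremental vs {self.model.pathways.reference.name}")
        for i in self.incrementals.values():
            if i.dominant:
                tail = "dominant (no fewer diagnoses at no greater cost)"
            elif i.icer is not None:
                tail = f"ICER {round_eur(i.icer):,.2f} EUR per additional diagnosis"
            else:
                tail = "ICER undefined"
            lines.append(
                f"  {i.model_name}: delta cost {round_eur(i.delta_cost):+,.2f} EUR, "
                f"delta diagnoses {i.delta_diagnoses:+d}; {tail}"
            )
        if self.ce_summary is not None:
            lines.append("-" * w)
            B = next(iter(self.ce_summary.values())).n_replicates
            lines.append(f"Bootstrap CE plane ({B} patient-level replicates)")
            for s in self.ce_summary.values():
                qp = s.quadrant_proportions
                lines.append(
                    f"  {s.model_name}: mean delta cost "
                    f"{round_eur(s.mean_delta_cost):+,.2f} EUR "
                    f"[{round_eur(s.delta_cost_ci[0]):,.2f}, "
                    f"{round_eur(s.delta_cost_ci[1]):,.2f}], "
                    f"mean delta diagnoses {s.mean_delta_diagnoses:+.2f} "
                    f"[{s.delta_diagnoses_ci[0]:g}, {s.delta_diagnoses_ci[1]:g}]"
                )
                lines.append(
                    f"    quadrants NE {qp['NE']:.1%}  SE {qp['SE']:.1%}  "
                    f"NW {qp['NW']:.1%}  SW {qp['SW']:.1%}  axis {qp['axis']:.1%}; "
                    f"dominance {s.dominance_proportion:.1%}"
                )
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_ce_plane(self, ax=None, **kwargs):
        if self.ce_points is None:
            raise CohortValidationError("results were fitted without a bootstrap")
        return bs.plot_ce_plane(self.ce_points, ax=ax, **kwargs)
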