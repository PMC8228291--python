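"""Report bundle writer.

Serialises a fitted :class:`~tierdx.model.DiagnosticPathwayResults` into a
directory of machine-readable tables (CSV/JSON), a plain-text summary and,
optionally, the CE-plane figure.  All files are deterministic given the
fitted results: no timestamps, sorted JSON keys, fixed column orders — two
runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .model import DiagnosticPathwayResults

logger = logging.getLogger(__name__)

__all__ = ["write_bundle"]


def write_bundle(
    results: DiagnosticPathwayResults,
    outdir: str | Path,
    figure: bool = False,
) -> list[Path]:
    """Write the full report bundle; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(name: str, frame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)
        logger.info("wrote %s", path)

    def _text(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text, encoding="utf-8")
        written.append(path)
        logger.info("wrote %s", path)

    _csv("yields.csv", results.yields_frame())
    _csv("tests.csv", results.tests_frame())
    _csv("costs.csv", results.costs_frame())
    _csv("incrementals.csv", results.incrementals_frame())
    _text("analysis.json", json.dumps(results.to_dict(), indent=2, sort_keys=True) + "\n")
    if results.ce_points is not None:
        _csv("bootstrap_points.csv", results.ce_points)
        assert results.ce_summary is not None
        _text(
            "bootstrap_summary.json",
            json.dumps(
                {k: v.to_dict() for k, v in results.ce_summary.items()},
                indent=2,
                sort_keys=True,
            )
            + "\n",
        )
    _text("summary.txt", results.summary() + "\n")
    if figure and results.ce_points is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ax = results.plot_ce_plane()
        path = outdir / "ce_plane.png"
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(path)
        logger.info("wrote %s", path)
    return written
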