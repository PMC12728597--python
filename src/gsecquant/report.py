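"""Reproducible JSON report serialization.

Reports contain no timestamps or machine metadata in the body, and every
floating-point value is rounded to 12 significant digits before writing,
so running the same inputs twice produces byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Sequence

from .metrics import PurityReport, ReplicateSummary, resolution as _resolution
from .mixture import LogNormalComponent, MixtureFit

__all__ = ["SCHEMA_VERSION", "report_document", "write_report", "round_sig"]

SCHEMA_VERSION = "1"


def round_sig(x: float, sig: int = 12) -> float:
    """Round to ``sig`` significant digits; passes through non-finite values."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _num(x) -> float | None:
    if x is None:
        return None
    x = float(x)
    return None if math.isnan(x) else round_sig(x)


def _component_dict(c: LogNormalComponent, fwhm: float) -> dict[str, Any]:
    return {
        "mu": _num(c.mu),
        "sigma": _num(c.sigma),
        "alpha": _num(c.alpha),
        "mode": _num(c.mode_uL),
        "fwhm": _num(fwhm),
    }


def _fit_dict(fit: MixtureFit, res) -> dict[str, Any]:
    return {
        "target": _component_dict(fit.component_target, res.w_half_1),
        "contaminant": _component_dict(fit.component_contaminant, res.w_half_2),
        "rss": _num(fit.rss),
        "r_squared": _num(fit.r_squared),
        "converged": fit.converged,
        "n_points": fit.n_points,
        "poorly_identified": fit.poorly_identified,
    }


def _replicate_dict(report: PurityReport) -> dict[str, Any]:
    res = report.resolution
    return {
        "replicate_id": report.replicate_id,
        "fit": _fit_dict(report.fit, res),
        "fractions": [
            {
                "index": fm.index,
                "volume_uL": _num(fm.volume_uL),
                "mass_ng": _num(fm.mass_ng),
                "measured_yield": _num(fm.measured_yield),
                "model_purity": _num(fm.model_purity),
                "model_yield": _num(fm.model_yield),
            }
            for fm in report.fractions
        ],
        "pooled": {
            "fractions": list(report.pooled.fractions),
            "mass_ng": _num(report.pooled.mass_ng),
            "measured_yield": _num(report.pooled.measured_yield),
            "model_purity": _num(report.pooled.model_purity),
            "model_yield": _num(report.pooled.model_yield),
            "yield_exceeds_one": report.pooled.yield_exceeds_one,
        },
        "resolution": {
            "t_r1": _num(res.t_r1),
            "t_r2": _num(res.t_r2),
            "w_half_1": _num(res.w_half_1),
            "w_half_2": _num(res.w_half_2),
            "rs": _num(res.rs),
        },
    }


def _summary_dict(summary: ReplicateSummary) -> dict[str, Any]:
    def pair(ms: tuple[float, float]) -> dict[str, float | None]:
        return {"mean": _num(ms[0]), "sd": _num(ms[1])}

    return {
        "n_replicates": summary.n_replicates,
        "per_fraction": {
            str(idx): {m: pair(ms) for m, ms in entry.items()}
            for idx, entry in summary.per_fraction.items()
        },
        "pooled": {m: pair(ms) for m, ms in summary.pooled.items()},
        "resolution": {m: pair(ms) for m, ms in summary.resolution.items()},
    }


def report_document(
    reports: Sequence[PurityReport],
    summary: ReplicateSummary,
    pool_recommendation: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Assemble the full JSON-serializable report document."""
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "replicates": [_replicate_dict(r) for r in reports],
        "summary": _summary_dict(summary),
    }
    if pool_recommendation is not None:
        doc["pool_recommendation"] = {
            "fractions": list(pool_recommendation["fractions"]),
            "purity": _num(pool_recommendation.get("purity")),
            "yield": _num(pool_recommendation.get("yield")),
        }
    return doc


def write_report(doc: dict[str, Any], path: str | Path) -> None:
    """Write the report with a stable key order and trailing newline."""
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
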