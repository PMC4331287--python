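"""Report rendering for chain and intake results (JSON, CSV, text)."""

from __future__ import annotations

import csv
import io as _stdio
import json
from typing import Any

from . import __version__
from .chain import ChainResult
from .feeding import IntakeEstimate

__all__ = ["build_report", "render_report"]


def build_report(
    result: ChainResult,
    intake: IntakeEstimate | None = None,
    config: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Assemble the full machine-readable report dictionary.

    Every report embeds the tool version, seed and configuration used, so a
    run can be reproduced from its own output.
    """
    report: dict[str, Any] = {
        "tool": "crocallometry",
        "version": __version__,
        "config": config or {},
        "chain": result.to_dict(),
    }
    if intake is not None:
        report["intake"] = {
            "bm_kg": intake.bm,
            "intake_growing_kg_per_day": intake.intake_growing,
            "intake_nongrowing_kg_per_day": intake.intake_nongrowing,
            "intake_mean_kg_per_day": intake.intake_mean,
            "reported_growing_kg_per_day": intake.reported_growing,
            "reported_nongrowing_kg_per_day": intake.reported_nongrowing,
            "reported_mean_kg_per_day": intake.reported_mean,
            "days_to_consume_body_mass": [intake.days_fast, intake.days_slow],
        }
    return report


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:,.1f}"


def render_report(
    result: ChainResult,
    intake: IntakeEstimate | None = None,
    format: str = "text",
    config: dict[str, Any] | None = None,
) -> str:
    """Serialize a report as ``json`` (lossless), ``csv`` or ``text``.

    Text and CSV round to 1 decimal on the natural scale; total length is
    additionally shown in metres in the text rendering.
    """
    report = build_report(result, intake, config)
    if format == "json":
        return json.dumps(report, indent=2, sort_keys=True)
    if format == "csv":
        buf = _stdio.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["quantity", "unit", "point", "lower", "upper"])
        writer.writerow(["dcl", "mm", f"{result.dcl:.1f}", "", ""])
        for s in result.stages:
            writer.writerow(
                [
                    s.role,
                    s.unit,
                    f"{s.point:.1f}",
                    "" if s.lower is None else f"{s.lower:.1f}",
                    "" if s.upper is None else f"{s.upper:.1f}",
                ]
            )
        if intake is not None:
            writer.writerow(
                ["intake_growing", "kg/day", f"{intake.reported_growing:.1f}", "", ""]
            )
            writer.writerow(
                [
                    "intake_nongrowing",
                    "kg/day",
                    f"{intake.reported_nongrowing:.1f}",
                    "",
                    "",
                ]
            )
            writer.writerow(
                ["intake_mean", "kg/day", f"{intake.reported_mean:.1f}", "", ""]
            )
            writer.writerow(
                ["days_fast", "day", str(intake.days_fast), "", ""]
            )
            writer.writerow(
                ["days_slow", "day", str(intake.days_slow), "", ""]
            )
        return buf.getvalue()
    if format == "text":
        lines = [
            f"crocallometry v{__version__} — chained allometric estimates",
            f"input skull length (DCL): {result.dcl:,.1f} mm "
            f"[coefficients: {result.provenance}]",
            "",
        ]
        names = {
            "svl": "snout-vent length (SVL)",
            "ttl": "total length (TTL)",
            "bm": "body mass (BM)",
            "bf": "bite force (BF)",
        }
        for s in result.stages:
            line = f"  {names[s.role]:<26s} {_fmt(s.point):>12s} {s.unit}"
            if s.lower is not None:
                line += f"  (95% PL {_fmt(s.lower)}–{_fmt(s.upper)} {s.unit})"
            lines.append(line)
            if s.role == "ttl":
                lines.append(
                    f"  {'':<26s} {s.point / 100:>12.1f} m"
                )
        if result.provenance == "published":
            lines.append(
                "  (published-coefficient chain: per-stage prediction limits "
                "unavailable)"
            )
        if intake is not None:
            lines += [
                "",
                f"  daily food intake, growing season:     "
                f"{intake.reported_growing:,.1f} kg/day",
                f"  daily food intake, non-growing season: "
                f"{intake.reported_nongrowing:,.1f} kg/day",
                f"  mean daily food intake:                "
                f"{intake.reported_mean:,.1f} kg/day",
                f"  days to consume own body mass:         "
                f"{intake.days_fast} to {intake.days_slow} days",
            ]
        lines.append("")
        lines.append(f"  note: {result.interval_note}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
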