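"""Assembly of summary reports across the two pipelines.

Combines per-zone synaptic density reports, per-animal pulse summaries,
surge calls and group comparisons into a single JSON-serialisable document,
including the distal:proximal density ratio.  The ratio is computed from
the 1-decimal displayed densities (the form in which densities are
reported), with the raw-value ratio alongside.
"""

from __future__ import annotations

import json
from pathlib import Path

from .pulses import PulseSummary, SurgeCall
from .stats import GroupComparison
from .synapses import DensityReport

__all__ = ["build_report", "render_markdown", "write_report", "read_report"]


def _density_rows(density_reports: list[DensityReport]) -> list[dict]:
    return [r.to_dict() for r in density_reports]


def build_report(density_reports: list[DensityReport] | None = None,
                 pulse_summaries: dict[str, PulseSummary] | None = None,
                 surge_calls: dict[str, SurgeCall] | None = None,
                 comparisons: dict[str, GroupComparison] | None = None
                 ) -> dict:
    """Build the combined report document.

    ``pulse_summaries`` and ``surge_calls`` map group/animal labels to
    their results.  Raises when density reports carry different expansion
    factors (lengths would not be commensurable).
    """
    density_reports = density_reports or []
    pulse_summaries = pulse_summaries or {}
    surge_calls = surge_calls or {}
    comparisons = comparisons or {}

    factors = {r.expansion_factor for r in density_reports
               if r.expansion_factor is not None}
    if len(factors) > 1:
        raise ValueError(f"mixed expansion factors in density inputs: {factors}")

    report: dict = {
        "synaptic_density": {
            "rows": _density_rows(density_reports),
            "units": "synapses per 10 um membrane, pre-expansion lengths",
        },
        "pulses": {label: s.to_dict() for label, s in pulse_summaries.items()},
        "surges": {
            "calls": {label: c.to_dict() for label, c in surge_calls.items()},
            "incidence": {},
        },
        "comparisons": {label: c.to_dict() for label, c in comparisons.items()},
    }

    zones = {r.zone: r for r in density_reports}
    if "proximal" in zones and "distal" in zones:
        prox, dist = zones["proximal"], zones["distal"]
        if prox.density_display > 0:
            report["synaptic_density"]["distal_to_proximal_ratio"] = (
                dist.density_display / prox.density_display)
        if prox.density_per_10um > 0:
            report["synaptic_density"]["distal_to_proximal_ratio_raw"] = (
                dist.density_per_10um / prox.density_per_10um)

    if surge_calls:
        n_surge = sum(1 for c in surge_calls.values() if c.is_surge)
        report["surges"]["incidence"] = {
            "n_animals": len(surge_calls),
            "n_with_surge": n_surge,
            "percent_with_surge": 100.0 * n_surge / len(surge_calls),
        }
    return report


def render_markdown(report: dict) -> str:
    """Render a report document as a small Markdown summary."""
    lines = ["# Summary report", ""]
    rows = report.get("synaptic_density", {}).get("rows", [])
    if rows:
        lines += ["## Synaptic density", "",
                  "| zone | segments | % contacted | contacts | per 10 um |",
                  "|---|---|---|---|---|"]
        for r in rows:
            lines.append(
                f"| {r['zone']} | {r['n_segments']} "
                f"| {r['percent_contacted']:.0f}% | {r['n_contacts_total']} "
                f"| {r['density_display']:.1f} ({r['denominator_mode']}) |")
        ratio = report["synaptic_density"].get("distal_to_proximal_ratio")
        if ratio is not None:
            lines.append("")
            lines.append(f"Distal:proximal density ratio = {ratio:.1f}")
    pulses = report.get("pulses", {})
    if pulses:
        lines += ["", "## LH pulses", "",
                  "| group | pulses | per hour | mean amplitude (ng/ml) | mean LH |",
                  "|---|---|---|---|---|"]
        for label, s in pulses.items():
            amp = s["mean_amplitude_ng_per_ml"]
            amp_s = f"{amp:.2f}" if amp is not None else "-"
            lines.append(f"| {label} | {s['n_pulses']} "
                         f"| {s['frequency_per_hour']:.1f} | {amp_s} "
                         f"| {s['mean_lh_ng_per_ml']:.2f} |")
    inc = report.get("surges", {}).get("incidence", {})
    if inc:
        lines += ["", "## LH surge incidence", "",
                  f"{inc['n_with_surge']}/{inc['n_animals']} animals "
                  f"({inc['percent_with_surge']:.0f}%) met the surge criterion"]
    comps = report.get("comparisons", {})
    if comps:
        lines += ["", "## Group comparisons (Mann-Whitney)", "",
                  "| comparison | U | p (two-sided) | method |", "|---|---|---|---|"]
        for label, c in comps.items():
            lines.append(f"| {label} | {c['U']:.1f} | {c['p_two_sided']:.4g} "
                         f"| {c['method']} |")
    return "\n".join(lines) + "\n"


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
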