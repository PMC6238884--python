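"""Textual interpretation: findings, event summaries and rendered reports.

Maps hypothesis results through the knowledge base's explanation templates
into hedged findings ("this event may have been due to ..."), aggregates a
summary of noticeable events with their main potential causes and their
distribution per hour and per weekday, and renders the whole as JSON,
Markdown or HTML.  The numeric trust grade is deliberately omitted from the
rendered (human-facing) formats and kept only in the JSON output: an alert
stating the concrete problems is what readers act on, not a number.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .engine import RunResult
from .kb import CAUSE_BRANCHES, KnowledgeBase
from .model import State

#: Human-readable event kind labels.
KIND_LABELS = {
    "hyperglycemia": "hyperglycemic event",
    "hypoglycemia": "hypoglycemic event",
    "high_bp": "high blood pressure reading",
    "short_sleep": "short sleep period",
}


@dataclass
class Finding:
    """One interpreted statement tied to an event or to the whole dataset."""

    scope: str
    headline: str
    justifications: List[str] = field(default_factory=list)
    severity: str = "info"  # info | warning | gap


@dataclass
class Summary:
    """Event counts, main-cause counts and time-of-day / weekday histograms."""

    event_counts: Dict[str, int] = field(default_factory=dict)
    cause_counts: Dict[str, int] = field(default_factory=dict)
    per_hour: Dict[str, List[int]] = field(default_factory=dict)
    per_weekday: Dict[str, List[int]] = field(default_factory=dict)


def _fill(template: str, evidence: Dict[str, float]) -> str:
    return template.format(**evidence)


def interpret(result: RunResult, kb: KnowledgeBase) -> List[Finding]:
    """One finding per TRUE cause branch per event, per information gap, and
    per TRUE reliability sub-hypothesis (with its recommendation).

    Cause headlines use hedged phrasing: the module proposes, the clinician
    and patient decide.
    """
    from .reliability import RECOMMENDATIONS

    findings: List[Finding] = []
    # reliability warnings, in knowledge-base order
    for r in result.results:
        if r.scope != "dataset" or r.state != State.TRUE:
            continue
        h = kb.hypotheses.get(r.hypothesis_id)
        if h is None or h.scope != "dataset":
            continue
        justs = [r.justification] if r.justification else []
        if h.template:
            try:
                justs.insert(0, _fill(h.template, r.numeric_evidence))
            except (KeyError, IndexError):
                pass
        reco = RECOMMENDATIONS.get(r.hypothesis_id)
        if reco:
            justs.append(reco)
        findings.append(Finding(scope="dataset",
                                headline=f"Data reliability: {h.description}.",
                                justifications=justs, severity="warning"))
    # per-event causes and gaps
    for event in result.events:
        label = KIND_LABELS.get(event.kind, event.kind)
        attached = {r.hypothesis_id: r for r in result.event_causes(event)}
        branches = CAUSE_BRANCHES.get(event.kind, ())
        for branch_id in branches:
            r = attached.get(branch_id)
            if r is None or r.state != State.TRUE:
                continue
            h = kb.hypotheses[branch_id]
            if branch_id.endswith("lack_of_evidence"):
                findings.append(Finding(
                    scope=event.scope,
                    headline=f"This {label} could not be explained by the available "
                             "data: a potential information gap.",
                    justifications=["Please investigate the registrations around "
                                    f"{event.reference_time.strftime('%Y-%m-%d %H:%M')}."],
                    severity="gap"))
                continue
            justs = []
            for child_id in h.children or (branch_id,):
                cr = attached.get(child_id)
                if cr is None or cr.state != State.TRUE:
                    continue
                ch = kb.hypotheses[child_id]
                if ch.template:
                    try:
                        justs.append(_fill(ch.template, cr.numeric_evidence))
                        continue
                    except (KeyError, IndexError):
                        pass
                if cr.justification:
                    justs.append(cr.justification)
            findings.append(Finding(
                scope=event.scope,
                headline=f"This {label} may have been due to the fact that "
                         f"{h.description}.",
                justifications=justs, severity="info"))
        if event.kind == "short_sleep":
            r = next(iter(attached.values()), None)
            if r is not None and r.state == State.TRUE:
                findings.append(Finding(
                    scope=event.scope,
                    headline="The patient may have slept less than the recommended "
                             "7 hours.",
                    justifications=[r.justification] if r.justification else [],
                    severity="info"))
    return findings


def summarize(result: RunResult) -> Summary:
    """Histograms are keyed by each event's reference time."""
    summary = Summary()
    for event in result.events:
        k = event.kind
        summary.event_counts[k] = summary.event_counts.get(k, 0) + 1
        summary.per_hour.setdefault(k, [0] * 24)[event.reference_time.hour] += 1
        summary.per_weekday.setdefault(k, [0] * 7)[event.reference_time.weekday()] += 1
        attached = {r.hypothesis_id: r for r in result.event_causes(event)}
        for branch_id in CAUSE_BRANCHES.get(k, ()):
            if branch_id.endswith("lack_of_evidence"):
                continue
            r = attached.get(branch_id)
            if r is not None and r.state == State.TRUE:
                summary.cause_counts[branch_id] = summary.cause_counts.get(branch_id, 0) + 1
    return summary


# ---------------------------------------------------------------------------
# rendering


def _render_markdown(findings: List[Finding], summary: Summary) -> str:
    lines = ["# Consultation report", ""]
    warnings = [f for f in findings if f.severity == "warning"]
    lines.append("## Data reliability")
    lines.append("")
    if warnings:
        for f in warnings:
            lines.append(f"- **{f.headline}**")
            for j in f.justifications:
                lines.append(f"  - {j}")
    else:
        lines.append("No data reliability issues were found.")
    lines.append("")
    lines.append("## Noticeable events")
    lines.append("")
    event_findings = [f for f in findings if f.scope != "dataset"]
    if event_findings:
        by_scope: Dict[str, List[Finding]] = {}
        for f in event_findings:
            by_scope.setdefault(f.scope, []).append(f)
        for scope in sorted(by_scope):
            lines.append(f"### {scope}")
            lines.append("")
            for f in by_scope[scope]:
                marker = "⚠ " if f.severity == "gap" else ""
                lines.append(f"- {marker}{f.headline}")
                for j in f.justifications:
                    lines.append(f"  - *{j}*")
            lines.append("")
    else:
        lines.append("No noticeable events were detected.")
        lines.append("")
    lines.append("## Summary")
    lines.append("")
    if summary.event_counts:
        for kind in sorted(summary.event_counts):
            lines.append(f"- {KIND_LABELS.get(kind, kind)}s: {summary.event_counts[kind]}")
        for cause in sorted(summary.cause_counts):
            lines.append(f"- events possibly caused by `{cause}`: "
                         f"{summary.cause_counts[cause]}")
        for kind in sorted(summary.per_hour):
            hours = ", ".join(f"{h:02d}h×{n}" for h, n in
                              enumerate(summary.per_hour[kind]) if n)
            days = ", ".join(f"{d}×{n}" for d, n in zip(
                ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"],
                summary.per_weekday[kind]) if n)
            lines.append(f"- {kind} distribution: per hour [{hours}]; "
                         f"per weekday [{days}]")
    else:
        lines.append("Nothing to summarize.")
    lines.append("")
    return "\n".join(lines)


def render(findings: List[Finding], summary: Summary, format: str = "markdown",
           run: Optional[RunResult] = None) -> str:
    """Render findings and summary; deterministic for fixed inputs.

    ``json`` includes the numeric trust level (API consumers need it) when a
    run result is supplied; ``markdown`` and ``html`` never show it.
    """
    if format == "json":
        doc = {
            "findings": [
                {"scope": f.scope, "headline": f.headline,
                 "justifications": f.justifications, "severity": f.severity}
                for f in findings
            ],
            "summary": {
                "event_counts": summary.event_counts,
                "cause_counts": summary.cause_counts,
                "per_hour": summary.per_hour,
                "per_weekday": summary.per_weekday,
            },
        }
        if run is not None:
            doc["run"] = run.to_dict()
        return json.dumps(doc, indent=2, sort_keys=True)
    if format == "markdown":
        return _render_markdown(findings, summary)
    if format == "html":
        body = _render_markdown(findings, summary)
        paragraphs = body.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        return ("<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
                "<title>Consultation report</title></head>\n"
                f"<body><pre>\n{paragraphs}\n</pre></body></html>\n")
    raise ValueError(f"unknown report format: {format!r}")
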