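"""Traffic-light assessment reports and the longitudinal dashboard.

Signal mapping follows the 0-2 severity semantics: green means routine
monitoring only (no trigger), yellow means an early warning requiring
corrective intervention within 24-48 h (a population tier fired but no
adverse welfare event), red means an AWE requiring immediate intervention.
The report also unions the management-domain (DOM) categories of every
triggered indicator — pointing mitigation at the most likely root causes —
and carries the registry's corrective-action text verbatim, in catalog
order.

Dashboard rows are one flat record per (pond, date, indicator), appended to
a CSV store; identical rows (same pond, date, indicator and registry
version) are detected and not duplicated, so re-running an assessment is
idempotent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .registry import Registry
from .scoring import CohortAssessment

__all__ = [
    "Signal",
    "AssessmentReport",
    "DashboardRow",
    "render_report",
    "append_dashboard",
    "read_dashboard",
    "render_text",
]

EXIT_CODE_BY_SIGNAL = {"green": 0, "yellow": 2, "red": 3}


class Signal(str, Enum):
    green = "green"
    yellow = "yellow"
    red = "red"


@dataclass(frozen=True)
class IndicatorBlock:
    indicator_id: str
    name: str
    n_scored: int
    proportion_pi_ge1: float
    count_pi2: int
    triggered_tiers: tuple[str, ...]
    sentinel_triggered: bool
    signal: Signal


@dataclass(frozen=True)
class AssessmentReport:
    pond_id: str
    date: Optional[str]
    sample_size: int
    registry_version: str
    signal: Signal
    indicator_blocks: tuple[IndicatorBlock, ...]
    cluster_summary: dict
    awe_list: tuple[dict, ...]
    dom_categories: tuple[str, ...]
    corrective_actions: dict[str, tuple[str, ...]]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signal"] = self.signal.value
        d["indicator_blocks"] = [
            {**asdict(b), "signal": b.signal.value} for b in self.indicator_blocks
        ]
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def _indicator_signal(a, is_awe_indicator: bool) -> Signal:
    if is_awe_indicator:
        return Signal.red
    if any(t.triggered for t in a.tier_outcomes):
        return Signal.yellow
    return Signal.green


def render_report(assessment: CohortAssessment, registry: Registry) -> AssessmentReport:
    """Build the deterministic traffic-light report for one assessment."""
    warnings_: list[str] = []
    if assessment.registry_version != registry.version:
        warnings_.append(
            f"registry version mismatch: assessment used {assessment.registry_version!r}, "
            f"report rendered against {registry.version!r}")

    awe_indicators = {t.indicator_id for t in assessment.triggers
                      if t.indicator_id is not None}
    blocks = []
    dom: list[str] = []
    actions: dict[str, tuple[str, ...]] = {}
    for ind_id in sorted(assessment.indicators):
        a = assessment.indicators[ind_id]
        defn = registry.lookup(ind_id)
        is_awe = ind_id in awe_indicators
        triggered_tiers = tuple(t.label.value for t in a.tier_outcomes if t.triggered)
        blocks.append(IndicatorBlock(
            indicator_id=ind_id,
            name=defn.name,
            n_scored=a.n_scored,
            proportion_pi_ge1=a.proportion_pi_ge1,
            count_pi2=a.count_pi2,
            triggered_tiers=triggered_tiers,
            sentinel_triggered=a.sentinel.triggered,
            signal=_indicator_signal(a, is_awe),
        ))
        if is_awe or triggered_tiers:
            for cat in defn.dom_categories:
                if cat not in dom:
                    dom.append(cat)
            actions[ind_id] = tuple(defn.corrective_actions)

    if assessment.awe:
        signal = Signal.red
    elif any(b.triggered_tiers for b in blocks):
        signal = Signal.yellow
    else:
        signal = Signal.green

    cluster_values = {"EIC": [], "IIC": []}
    consolidated = {"EIC": 0, "IIC": 0}
    for clusters in assessment.fish_clusters.values():
        for name, cr in clusters.items():
            cluster_values[name].append(cr.value)
            if cr.interpretation.value == "consolidated_awe":
                consolidated[name] += 1
    cluster_summary = {
        name: {
            "n_fish": len(vals),
            "mean": sum(vals) / len(vals) if vals else None,
            "max": max(vals) if vals else None,
            "n_consolidated_awe": consolidated[name],
        }
        for name, vals in cluster_values.items()
    }

    awe_list = tuple(
        {"rule": t.rule, "indicator_id": t.indicator_id, "fish_id": t.fish_id, "detail": t.detail}
        for t in assessment.triggers)

    return AssessmentReport(
        pond_id=assessment.pond_id,
        date=assessment.date.isoformat() if assessment.date else None,
        sample_size=assessment.sample_size,
        registry_version=assessment.registry_version,
        signal=signal,
        indicator_blocks=tuple(blocks),
        cluster_summary=cluster_summary,
        awe_list=awe_list,
        dom_categories=tuple(dom),
        corrective_actions=actions,
        warnings=tuple(warnings_),
    )


# ---------------------------------------------------------------------------
# dashboard
# ---------------------------------------------------------------------------

DASHBOARD_COLUMNS = [
    "pond_id", "date", "indicator_id", "n_scored", "proportion_pi_ge1",
    "count_pi2", "triggered_tiers", "sentinel_triggered", "eic_mean",
    "iic_mean", "signal", "registry_version",
]


@dataclass(frozen=True)
class DashboardRow:
    pond_id: str
    date: str
    indicator_id: str
    n_scored: int
    proportion_pi_ge1: float
    count_pi2: int
    triggered_tiers: str
    sentinel_triggered: bool
    eic_mean: Optional[float]
    iic_mean: Optional[float]
    signal: str
    registry_version: str


def _report_rows(report: AssessmentReport) -> list[DashboardRow]:
    eic = report.cluster_summary.get("EIC", {}).get("mean")
    iic = report.cluster_summary.get("IIC", {}).get("mean")
    return [
        DashboardRow(
            pond_id=report.pond_id,
            date=report.date or "",
            indicator_id=b.indicator_id,
            n_scored=b.n_scored,
            proportion_pi_ge1=round(b.proportion_pi_ge1, 6),
            count_pi2=b.count_pi2,
            triggered_tiers="|".join(b.triggered_tiers),
            sentinel_triggered=b.sentinel_triggered,
            eic_mean=round(eic, 6) if eic is not None else None,
            iic_mean=round(iic, 6) if iic is not None else None,
            signal=b.signal.value,
            registry_version=report.registry_version,
        )
        for b in report.indicator_blocks
    ]


def append_dashboard(report: AssessmentReport, store: Union[str, Path]) -> pd.DataFrame:
    """Append one row per indicator to the CSV store; duplicates are skipped.

    A row is a duplicate when its (pond, date, indicator, registry version)
    key already exists, so re-appending an identical report leaves the store
    unchanged.  Returns the updated dashboard frame.
    """
    store = Path(store)
    new = pd.DataFrame([asdict(r) for r in _report_rows(report)], columns=DASHBOARD_COLUMNS)
    if store.exists():
        existing = pd.read_csv(store, dtype={"pond_id": str, "indicator_id": str, "date": str})
        missing = [c for c in DASHBOARD_COLUMNS if c not in existing.columns]
        if missing:
            raise ValueError(
                f"dashboard store schema drift: missing columns {missing}; "
                "migrate the store before appending")
        existing["date"] = existing["date"].fillna("")
        key_cols = ["pond_id", "date", "indicator_id", "registry_version"]
        existing_keys = set(map(tuple, existing[key_cols].astype(str).values))
        mask = [tuple(map(str, row)) not in existing_keys
                for row in new[key_cols].values]
        fresh = new[mask]
        combined = pd.concat([existing, fresh], ignore_index=True) if not fresh.empty else existing
    else:
        combined = new
    combined.to_csv(store, index=False)
    return combined


def read_dashboard(store: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(store, dtype={"pond_id": str, "indicator_id": str, "date": str})


def render_text(report: AssessmentReport) -> str:
    """Plain-text rendering of a report (colors as words, machine-safe)."""
    lines = [
        f"Pond {report.pond_id}  date={report.date or '-'}  n={report.sample_size}  "
        f"signal={report.signal.value.upper()}  (registry {report.registry_version})",
    ]
    for w in report.warnings:
        lines.append(f"  WARNING: {w}")
    for b in report.indicator_blocks:
        tiers = ",".join(b.triggered_tiers) or "-"
        lines.append(
            f"  [{b.signal.value:6s}] {b.indicator_id:24s} n={b.n_scored:3d}  "
            f"Pi>=1: {b.proportion_pi_ge1:6.1%}  Pi=2: {b.count_pi2:3d}  "
            f"tiers={tiers}  sentinel={'yes' if b.sentinel_triggered else 'no'}")
    for name, s in report.cluster_summary.items():
        if s["n_fish"]:
            lines.append(
                f"  {name}: mean={s['mean']:.3f} max={s['max']:.3f} "
                f"consolidated={s['n_consolidated_awe']}/{s['n_fish']}")
    if report.awe_list:
        lines.append("  Adverse welfare events:")
        for t in report.awe_list:
            lines.append(f"    - [{t['rule']}] {t['detail']}")
        lines.append("  Implicated DOM categories: " + "; ".join(report.dom_categories))
        for ind, acts in report.corrective_actions.items():
            lines.append(f"  Actions ({ind}):")
            for a in acts:
                lines.append(f"    * {a}")
    return "\n".join(lines)
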