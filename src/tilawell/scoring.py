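"""Severity scoring and adverse-welfare-event (AWE) detection.

Converts raw fish-level measurements into 0-2 severity scores (Pi),
aggregates per-fish scores into the external and internal indicator
clusters (EIC/IIC), applies each indicator's population-based and sentinel
criteria, and flags adverse welfare events with full trigger provenance.

Decision rules implemented here:

* per-indicator Pi from the registry's scoring bands (benign-first boundary
  convention, see :mod:`tilawell.registry`);
* cluster value = mean (optionally weighted) of the Pi scores assessed in
  that dimension; interpretation bands <0.5 stable, 0.5-<1.2 mild/moderate
  risk, >=1.2 consolidated AWE;
* population criterion: proportion of sampled fish at or above a Pi tier
  compared against the stored threshold with the stored strict/non-strict
  comparator;
* sentinel criterion: a minimum number of fish at Pi=2 (usually 2, one for
  the tissue-damage/redox panel) declares an AWE regardless of sample
  proportion; where stricter raw-value sentinel cut-offs are printed
  (glucose, cortisol) they gate which fish qualify as sentinel-grade;
* cohort AWE flag: any sentinel rule fired, or any fish with any Pi=2, or
  any fish whose cluster reaches 1.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .registry import (
    Category,
    Comparator,
    IndicatorDefinition,
    Pi,
    Registry,
    RuleKind,
    SeverityBand,
    TierLabel,
    classify_value,
)

__all__ = [
    "CONSOLIDATED_AWE_THRESHOLD",
    "MILD_RISK_THRESHOLD",
    "ClusterInterpretation",
    "Measurement",
    "FishRecord",
    "ClusterResult",
    "TierOutcome",
    "SentinelOutcome",
    "IndicatorAssessment",
    "AweTrigger",
    "CohortAssessment",
    "ScoringError",
    "score_measurement",
    "score_value",
    "score_fold_change",
    "score_electrolyte_panel",
    "fulton_k",
    "score_condition_factor",
    "score_baseline_relative",
    "compute_cluster",
    "population_criterion",
    "sentinel_awe",
    "evaluate_cohort",
    "evaluate_measurements",
    "longitudinal_flags",
    "read_measurements_csv",
]

#: Cluster value at or above which an aggregated (consolidated) AWE exists.
CONSOLIDATED_AWE_THRESHOLD = 1.2
#: Cluster value at or above which welfare is at mild-to-moderate risk.
MILD_RISK_THRESHOLD = 0.5


class ScoringError(ValueError):
    pass


class ClusterInterpretation(str, Enum):
    stable = "stable"
    mild_moderate_risk = "mild_moderate_risk"
    consolidated_awe = "consolidated_awe"


@dataclass(frozen=True)
class Measurement:
    """One raw observation for one fish.

    ``value`` is a numeric reading for lab/physiology indicators or a
    pre-assigned ordinal Pi for observational external indicators (field
    scoring).  ``analyte`` distinguishes panel members (e.g. ``na``,
    ``osmolality``) for multi-analyte indicators.
    """

    pond_id: str
    fish_id: str
    indicator_id: str
    value: Optional[float] = None
    pi: Optional[int] = None
    units: str = ""
    life_stage: str = "adult"
    date: Optional[Date] = None
    analyte: Optional[str] = None
    weight_g: Optional[float] = None
    length_cm: Optional[float] = None

    def __post_init__(self):
        if self.pi is not None and self.pi not in (0, 1, 2):
            raise ScoringError(f"ordinal score must be 0, 1 or 2 (got {self.pi})")


@dataclass
class FishRecord:
    fish_id: str
    pis: dict[str, Pi] = field(default_factory=dict)
    raw_values: dict[str, float] = field(default_factory=dict)
    weight_g: Optional[float] = None
    length_cm: Optional[float] = None


@dataclass(frozen=True)
class ClusterResult:
    cluster: str  # "EIC" or "IIC"
    value: float
    n_indicators: int
    interpretation: ClusterInterpretation
    weights: Optional[tuple[float, ...]] = None


@dataclass(frozen=True)
class TierOutcome:
    label: TierLabel
    min_pi: int
    proportion_threshold: float
    comparator: Comparator
    observed_proportion: float
    n_meeting: int
    n_sample: int
    triggered: bool


@dataclass(frozen=True)
class SentinelOutcome:
    triggered: bool
    count_pi2: int
    min_fish_at_pi2: int
    qualifying_fish: tuple[str, ...]
    #: fish at Pi=2 below the sentinel count, flagged for individual follow-up
    followup_fish: tuple[str, ...] = ()


@dataclass(frozen=True)
class AweTrigger:
    rule: str  # "sentinel" | "indicator_pi2" | "cluster"
    indicator_id: Optional[str] = None
    fish_id: Optional[str] = None
    detail: str = ""


@dataclass
class IndicatorAssessment:
    indicator_id: str
    n_scored: int
    pis: dict[str, Pi]
    proportion_pi_ge1: float
    count_pi2: int
    tier_outcomes: list[TierOutcome]
    sentinel: SentinelOutcome
    mean_raw: Optional[float] = None


@dataclass
class CohortAssessment:
    pond_id: str
    date: Optional[Date]
    sample_size: int
    indicators: dict[str, IndicatorAssessment]
    fish_clusters: dict[str, dict[str, ClusterResult]]
    awe: bool
    triggers: list[AweTrigger]
    registry_version: str


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------

def fulton_k(weight_g: float, length_cm: float) -> float:
    """Fulton's condition factor K = 100 * W / L^3 (W in g, L in cm)."""
    if weight_g <= 0 or length_cm <= 0:
        raise ScoringError("weight and length must be positive")
    return 100.0 * weight_g / length_cm**3


def score_condition_factor(k: float, k_mu: float, pi1_dev: float = 0.10, pi2_dev: float = 0.20) -> Pi:
    """Score body condition from K's relative deviation from the batch mean.

    Within +/-10% of the batch mean scores 0; a 10-20% deviation scores 1;
    a deviation of 20% or more scores 2 (severe emaciation / visceral fat
    excess).  The 10% boundary is benign (scores 0); the 20% boundary is
    severe as printed ("K >=20% below/above").
    """
    if k_mu <= 0:
        raise ScoringError("batch mean condition factor must be positive")
    dev = abs(k - k_mu) / k_mu
    eps = 1e-9  # absorb float round-off exactly at a printed boundary
    if dev <= pi1_dev + eps:
        return 0
    if dev < pi2_dev - eps:
        return 1
    return 2


def score_fold_change(defn: IndicatorDefinition, observed: float, reference: float) -> Pi:
    """Pure fold-change scoring: ratio <=1 scores 0, <2 scores 1, >=2 scores 2.

    For symmetric rules (antioxidant enzymes, where both marked induction and
    exhaustion are severe) the fold deviation ``max(r, 1/r)`` is used.
    """
    if reference <= 0:
        raise ScoringError("fold-change reference must be positive")
    rule = defn.scoring_rule
    if rule.kind is not RuleKind.fold_change:
        raise ScoringError(f"indicator {defn.id!r} is not fold-change scored")
    ratio = observed / reference
    if rule.symmetric:
        if ratio <= 0:
            return 2
        dev = max(ratio, 1.0 / ratio)
        if dev <= 1.0:
            return 0
        if dev < 2.0:
            return 1
        return 2
    if ratio <= 1.0:
        return 0
    if ratio < 2.0:
        return 1
    return 2


def score_baseline_relative(defn: IndicatorDefinition, observed: float, baseline: float) -> Pi:
    """Score a baseline-relative indicator (respiratory or heart rate).

    The deviation thresholds are configurable defaults (+/-20% mild,
    +/-50% severe), not literature constants; qualitative severe findings
    (gasping, asynchrony, marked arrhythmia) should be entered as ordinal
    Pi=2 directly.
    """
    if baseline <= 0:
        raise ScoringError("baseline must be positive")
    rule = defn.scoring_rule
    dev = abs(observed - baseline) / baseline
    eps = 1e-9
    if dev <= rule.pi1_deviation + eps:
        return 0
    if dev <= rule.pi2_deviation + eps:
        return 1
    return 2


def score_electrolyte_panel(defn: IndicatorDefinition, values: Mapping[str, float]) -> Pi:
    """Score the electrolyte/osmolality panel.

    Per printed rule: all analytes inside their reference ranges scores 0; a
    10-20% deviation from the reference range in exactly one analyte scores
    1; a deviation >20%, or two or more analytes out of range, scores 2.
    Deviations are measured relative to the nearest range bound.
    """
    rule = defn.scoring_rule
    ranges = rule.reference_ranges or {}
    if not values:
        raise ScoringError("electrolyte panel requires at least one analyte value")
    deviations: list[float] = []
    for analyte, value in values.items():
        key = analyte.lower()
        if key not in ranges:
            raise ScoringError(f"unknown analyte {analyte!r} for {defn.id!r}")
        lo, hi = ranges[key]
        if value < lo:
            deviations.append((lo - value) / lo)
        elif value > hi:
            deviations.append((value - hi) / hi)
        else:
            deviations.append(0.0)
    out_of_range = [d for d in deviations if d > 0]
    if len(out_of_range) >= 2:
        return 2
    if not out_of_range:
        return 0
    d = out_of_range[0]
    if d > rule.pi2_deviation:
        return 2
    if d >= rule.pi1_deviation:
        return 1
    return 0  # <10% beyond the range: gap closed toward the benign band


@dataclass(frozen=True)
class ScoreContext:
    """Caller-supplied references for relative rule kinds."""

    baseline: Optional[float] = None  # baseline_relative
    reference: Optional[float] = None  # fold_change
    k_mu: Optional[float] = None  # condition_factor


def score_value(
    defn: IndicatorDefinition,
    value: float,
    life_stage: str = "adult",
    context: Optional[ScoreContext] = None,
) -> Pi:
    """Score a single numeric value against an indicator definition."""
    rule = defn.scoring_rule
    if rule.kind is RuleKind.numeric_bands:
        bands: list[SeverityBand] = rule.bands_for(life_stage)
        return classify_value(bands, value)
    if rule.kind is RuleKind.fold_change:
        reference = context.reference if context and context.reference else rule.default_reference()
        if reference is None:
            raise ScoringError(f"indicator {defn.id!r} needs a fold-change reference")
        # a value inside the printed operational range is normal even when it
        # exceeds the (midpoint) reference
        if rule.reference_ranges and not (context and context.reference):
            lo, hi = next(iter(rule.reference_ranges.values()))
            if lo <= value <= hi:
                return 0
        return score_fold_change(defn, value, reference)
    if rule.kind is RuleKind.baseline_relative:
        if rule.reference_ranges:  # electrolyte-style: score single analyte vs range
            first = next(iter(rule.reference_ranges))
            return score_electrolyte_panel(defn, {first: value})
        if context is None or context.baseline is None:
            raise ScoringError(f"indicator {defn.id!r} requires a baseline context")
        return score_baseline_relative(defn, value, context.baseline)
    if rule.kind is RuleKind.condition_factor:
        if context is None or context.k_mu is None:
            raise ScoringError(f"indicator {defn.id!r} requires the batch mean K (k_mu)")
        return score_condition_factor(value, context.k_mu, rule.pi1_deviation, rule.pi2_deviation)
    raise ScoringError(f"indicator {defn.id!r} is observational; supply an ordinal Pi")


def score_measurement(
    defn: IndicatorDefinition,
    m: Measurement,
    context: Optional[ScoreContext] = None,
) -> Pi:
    """Score one measurement; ordinal Pi passes through after validation."""
    if m.indicator_id.lower() != defn.id.lower():
        raise ScoringError(f"measurement for {m.indicator_id!r} scored against {defn.id!r}")
    if m.pi is not None:
        return m.pi
    rule = defn.scoring_rule
    if rule.kind is RuleKind.condition_factor and m.value is None:
        if m.weight_g is None or m.length_cm is None:
            raise ScoringError("condition factor needs K, or weight and length")
        return score_value(defn, fulton_k(m.weight_g, m.length_cm), m.life_stage, context)
    if m.value is None:
        raise ScoringError(f"measurement for {defn.id!r} carries neither a value nor a Pi")
    if m.units and defn.units and rule.kind is RuleKind.numeric_bands:
        if m.units.strip().lower() != defn.units.strip().lower():
            raise ScoringError(
                f"unit mismatch for {defn.id!r}: measurement in {m.units!r}, "
                f"registry expects {defn.units!r} (no silent conversion)"
            )
    return score_value(defn, m.value, m.life_stage, context)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def compute_cluster(
    pis: Sequence[Pi],
    cluster: str,
    weights: Optional[Sequence[float]] = None,
) -> ClusterResult:
    """Mean (optionally weighted) of the Pi scores assessed in one dimension.

    Only scored indicators enter ``n``; weights are normalized internally.
    """
    if len(pis) == 0:
        raise ScoringError("cannot compute a cluster over zero indicators")
    for p in pis:
        if p not in (0, 1, 2):
            raise ScoringError(f"invalid Pi {p!r}")
    if weights is not None:
        if len(weights) != len(pis):
            raise ScoringError("weights must match the number of scores")
        if any(w < 0 for w in weights):
            raise ScoringError("weights must be non-negative")
        total = float(sum(weights))
        if total == 0:
            raise ScoringError("weights must not all be zero")
        value = sum(w * p for w, p in zip(weights, pis)) / total
        norm = tuple(w / total for w in weights)
    else:
        value = sum(pis) / len(pis)
        norm = None
    if value >= CONSOLIDATED_AWE_THRESHOLD:
        interp = ClusterInterpretation.consolidated_awe
    elif value >= MILD_RISK_THRESHOLD:
        interp = ClusterInterpretation.mild_moderate_risk
    else:
        interp = ClusterInterpretation.stable
    return ClusterResult(cluster=cluster, value=value, n_indicators=len(pis),
                         interpretation=interp, weights=norm)


def population_criterion(defn: IndicatorDefinition, pis_across_fish: Sequence[Pi]) -> list[TierOutcome]:
    """Apply each stored population tier to the sampled Pi scores."""
    n = len(pis_across_fish)
    if n == 0:
        raise ScoringError("population criterion needs a non-empty sample")
    outcomes = []
    for tier in defn.population_rule.tiers:
        meeting = sum(1 for p in pis_across_fish if p >= tier.min_pi)
        proportion = meeting / n
        outcomes.append(TierOutcome(
            label=tier.label,
            min_pi=tier.min_pi,
            proportion_threshold=tier.proportion_threshold,
            comparator=tier.comparator,
            observed_proportion=proportion,
            n_meeting=meeting,
            n_sample=n,
            triggered=tier.comparator.apply(proportion, tier.proportion_threshold),
        ))
    return outcomes


def _severe_extreme_qualifies(defn: IndicatorDefinition, raw: float) -> bool:
    se = defn.scoring_rule.severe_extreme or {}
    high = se.get("high")
    low = se.get("low")
    return (high is not None and raw > high) or (low is not None and raw < low)


def sentinel_awe(
    defn: IndicatorDefinition,
    pis_across_fish: Mapping[str, Pi],
    raw_values: Optional[Mapping[str, float]] = None,
) -> SentinelOutcome:
    """Apply the indicator's sentinel early-warning rule.

    ``pis_across_fish`` maps fish id to Pi.  Where the registry stores
    stricter severe-extreme raw cut-offs, a fish only qualifies as
    sentinel-grade if its raw value also exceeds them.
    """
    if not pis_across_fish:
        raise ScoringError("sentinel criterion needs a non-empty sample")
    rule = defn.sentinel_rule
    pi2_fish = [fid for fid, p in pis_across_fish.items() if p == 2]
    if rule.uses_severe_extreme and raw_values:
        qualifying = [f for f in pi2_fish
                      if f in raw_values and _severe_extreme_qualifies(defn, raw_values[f])]
    else:
        qualifying = pi2_fish
    triggered = len(qualifying) >= rule.min_fish_at_pi2
    followup = () if triggered else tuple(sorted(pi2_fish))
    return SentinelOutcome(
        triggered=triggered,
        count_pi2=len(pi2_fish),
        min_fish_at_pi2=rule.min_fish_at_pi2,
        qualifying_fish=tuple(sorted(qualifying)),
        followup_fish=followup,
    )


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------

def _build_fish_records(
    registry: Registry,
    measurements: Sequence[Measurement],
    context: Optional[Mapping[str, ScoreContext]],
) -> tuple[dict[str, FishRecord], dict[str, dict[str, float]]]:
    context = context or {}
    unknown = sorted({m.indicator_id for m in measurements if m.indicator_id not in registry})
    if unknown:
        raise ScoringError(f"unresolvable indicator ids: {', '.join(unknown)}")

    fish: dict[str, FishRecord] = {}
    raw_by_indicator: dict[str, dict[str, float]] = {}

    # electrolyte-style panels: collect analyte rows per fish first
    panels: dict[tuple[str, str], dict[str, float]] = {}
    panel_stage: dict[tuple[str, str], str] = {}

    # batch mean K for condition-factor scoring when no k_mu supplied
    k_values: dict[str, float] = {}
    for m in measurements:
        defn = registry.lookup(m.indicator_id)
        if defn.scoring_rule.kind is RuleKind.condition_factor and m.pi is None:
            k = m.value if m.value is not None else (
                fulton_k(m.weight_g, m.length_cm)
                if m.weight_g is not None and m.length_cm is not None else None)
            if k is not None:
                k_values[m.fish_id] = k
    batch_k_mu = sum(k_values.values()) / len(k_values) if k_values else None

    for m in measurements:
        defn = registry.lookup(m.indicator_id)
        rec = fish.setdefault(m.fish_id, FishRecord(fish_id=m.fish_id))
        if m.weight_g is not None:
            rec.weight_g = m.weight_g
        if m.length_cm is not None:
            rec.length_cm = m.length_cm

        rule = defn.scoring_rule
        if (rule.kind is RuleKind.baseline_relative and rule.reference_ranges
                and m.pi is None):
            key = (m.fish_id, defn.id)
            analyte = (m.analyte or next(iter(rule.reference_ranges))).lower()
            panels.setdefault(key, {})[analyte] = float(m.value)
            panel_stage[key] = m.life_stage
            continue

        ctx = context.get(defn.id)
        if defn.scoring_rule.kind is RuleKind.condition_factor and (ctx is None or ctx.k_mu is None):
            ctx = ScoreContext(k_mu=batch_k_mu)
        pi = score_measurement(defn, m, ctx)
        rec.pis[defn.id] = pi
        if m.value is not None:
            rec.raw_values[defn.id] = float(m.value)
            raw_by_indicator.setdefault(defn.id, {})[m.fish_id] = float(m.value)

    for (fish_id, ind_id), values in panels.items():
        defn = registry.lookup(ind_id)
        pi = score_electrolyte_panel(defn, values)
        fish[fish_id].pis[ind_id] = pi
        primary = next(iter(values.values()))
        fish[fish_id].raw_values[ind_id] = primary
        raw_by_indicator.setdefault(ind_id, {})[fish_id] = primary

    return fish, raw_by_indicator


def evaluate_cohort(
    registry: Registry,
    measurements: Sequence[Measurement],
    context: Optional[Mapping[str, ScoreContext]] = None,
) -> CohortAssessment:
    """Score a single pond/date sample and apply every decision rule.

    Deterministic for a fixed input: fish and indicator ordering never
    affects any output.  Partially scored fish contribute to each cluster
    with a correspondingly reduced ``n``.
    """
    if not measurements:
        raise ScoringError("no measurements supplied")
    ponds = {m.pond_id for m in measurements}
    dates = {m.date for m in measurements}
    if len(ponds) > 1 or len(dates) > 1:
        raise ScoringError(
            "evaluate_cohort expects one pond and date; use evaluate_measurements to group")
    pond_id, mdate = next(iter(ponds)), next(iter(dates))

    fish, raw_by_indicator = _build_fish_records(registry, measurements, context)

    indicator_assessments: dict[str, IndicatorAssessment] = {}
    triggers: list[AweTrigger] = []
    scored_indicator_ids = sorted({ind for rec in fish.values() for ind in rec.pis})
    for ind_id in scored_indicator_ids:
        defn = registry.lookup(ind_id)
        pis = {fid: rec.pis[ind_id] for fid, rec in sorted(fish.items()) if ind_id in rec.pis}
        values = list(pis.values())
        tier_outcomes = population_criterion(defn, values)
        sentinel = sentinel_awe(defn, pis, raw_by_indicator.get(ind_id))
        raws = raw_by_indicator.get(ind_id)
        indicator_assessments[ind_id] = IndicatorAssessment(
            indicator_id=ind_id,
            n_scored=len(values),
            pis=pis,
            proportion_pi_ge1=sum(1 for p in values if p >= 1) / len(values),
            count_pi2=sum(1 for p in values if p == 2),
            tier_outcomes=tier_outcomes,
            sentinel=sentinel,
            mean_raw=(sum(raws.values()) / len(raws)) if raws else None,
        )
        if sentinel.triggered:
            triggers.append(AweTrigger(
                rule="sentinel", indicator_id=ind_id,
                detail=f"{sentinel.count_pi2} fish at Pi=2 "
                       f"(threshold {sentinel.min_fish_at_pi2}): "
                       f"{', '.join(sentinel.qualifying_fish)}"))

    fish_clusters: dict[str, dict[str, ClusterResult]] = {}
    for fid in sorted(fish):
        rec = fish[fid]
        clusters: dict[str, ClusterResult] = {}
        for cluster_name in ("EIC", "IIC"):
            pis = [rec.pis[i] for i in sorted(rec.pis)
                   if registry.lookup(i).cluster == cluster_name]
            if pis:
                clusters[cluster_name] = compute_cluster(pis, cluster_name)
        fish_clusters[fid] = clusters
        for ind_id, p in sorted(rec.pis.items()):
            if p == 2:
                triggers.append(AweTrigger(rule="indicator_pi2", indicator_id=ind_id,
                                           fish_id=fid, detail=f"{ind_id} Pi=2 in fish {fid}"))
        for cluster_name, cr in clusters.items():
            if cr.value >= CONSOLIDATED_AWE_THRESHOLD:
                triggers.append(AweTrigger(
                    rule="cluster", fish_id=fid,
                    detail=f"{cluster_name}={cr.value:.3g} >= {CONSOLIDATED_AWE_THRESHOLD} in fish {fid}"))

    return CohortAssessment(
        pond_id=pond_id,
        date=mdate,
        sample_size=len(fish),
        indicators=indicator_assessments,
        fish_clusters=fish_clusters,
        awe=bool(triggers),
        triggers=triggers,
        registry_version=registry.version,
    )


def evaluate_measurements(
    registry: Registry,
    measurements: Sequence[Measurement],
    context: Optional[Mapping[str, ScoreContext]] = None,
) -> list[CohortAssessment]:
    """Group measurements by (pond, date) and evaluate each cohort."""
    groups: dict[tuple, list[Measurement]] = {}
    for m in measurements:
        groups.setdefault((m.pond_id, m.date), []).append(m)
    key_order = sorted(groups, key=lambda k: (k[0], k[1] or Date.min))
    return [evaluate_cohort(registry, groups[k], context) for k in key_order]


# ---------------------------------------------------------------------------
# longitudinal helpers
# ---------------------------------------------------------------------------

def longitudinal_flags(assessments: Sequence[CohortAssessment]) -> dict[str, dict[str, bool]]:
    """Flags over consecutive assessments of the same pond.

    ``repeated_detection``: the same indicator shows at least one fish at
    Pi=2 in two consecutive assessments.  ``rising_trend``: the indicator's
    mean raw value strictly increases across two consecutive sampling
    events (the escalation clause used by the damage/redox panel).
    """
    ordered = sorted(assessments, key=lambda a: (a.date or Date.min))
    ponds = {a.pond_id for a in ordered}
    if len(ponds) > 1:
        raise ScoringError("longitudinal flags are per pond; filter first")
    flags: dict[str, dict[str, bool]] = {}
    for prev, cur in zip(ordered[:-1], ordered[1:]):
        for ind_id, cur_a in cur.indicators.items():
            prev_a = prev.indicators.get(ind_id)
            if prev_a is None:
                continue
            entry = flags.setdefault(ind_id, {"repeated_detection": False, "rising_trend": False})
            if prev_a.count_pi2 >= 1 and cur_a.count_pi2 >= 1:
                entry["repeated_detection"] = True
            if (prev_a.mean_raw is not None and cur_a.mean_raw is not None
                    and cur_a.mean_raw > prev_a.mean_raw):
                entry["rising_trend"] = True
    return flags


# ---------------------------------------------------------------------------
# measurement IO
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["pond_id", "fish_id", "indicator_id", "value", "pi", "units",
                "life_stage", "date", "analyte", "weight_g", "length_cm"]


def read_measurements_csv(path: Union[str, Path]) -> list[Measurement]:
    """Read the tidy measurement table (UTF-8 CSV, ISO-8601 dates).

    Required columns: ``pond_id, fish_id, indicator_id``; one of ``value``
    or ``pi`` per row; the remaining columns are optional.  Empty strings
    are missing values.
    """
    df = pd.read_csv(path, dtype={"pond_id": str, "fish_id": str, "indicator_id": str})
    for col in ("pond_id", "fish_id", "indicator_id"):
        if col not in df.columns:
            raise ScoringError(f"measurement CSV is missing required column {col!r}")
    out: list[Measurement] = []

    def _get(row, col, cast=float):
        if col not in df.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return cast(v)

    for _, row in df.iterrows():
        raw_date = _get(row, "date", str)
        out.append(Measurement(
            pond_id=row["pond_id"],
            fish_id=row["fish_id"],
            indicator_id=row["indicator_id"],
            value=_get(row, "value"),
            pi=_get(row, "pi", lambda v: int(float(v))),
            units=_get(row, "units", str) or "",
            life_stage=_get(row, "life_stage", str) or "adult",
            date=Date.fromisoformat(raw_date) if raw_date else None,
            analyte=_get(row, "analyte", str),
            weight_g=_get(row, "weight_g"),
            length_cm=_get(row, "length_cm"),
        ))
    return out


def measurements_to_frame(measurements: Iterable[Measurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append({
            "pond_id": m.pond_id, "fish_id": m.fish_id, "indicator_id": m.indicator_id,
            "value": m.value, "pi": m.pi, "units": m.units, "life_stage": m.life_stage,
            "date": m.date.isoformat() if m.date else "", "analyte": m.analyte or "",
            "weight_g": m.weight_g, "length_cm": m.length_cm,
        })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)
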