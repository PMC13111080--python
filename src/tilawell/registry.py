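"""Machine-readable indicator catalog for tilapia welfare assessment.

The registry is the single source of truth for every welfare indicator: its
severity bands (the 0-2 ``Pi`` scale), the population-based and sentinel
criteria that turn individual scores into group-level decisions, and the
management-domain (DOM) and risk-factor (EPI) metadata used to direct
corrective action.  The catalog ships as JSON (YAML is also accepted) so that
threshold revisions are data edits, not code edits.

Boundary convention
-------------------
Printed reference bands in the aquaculture literature overlap at shared
endpoints (e.g. glucose 40-80 normal vs 80-100 mild) and occasionally leave
small gaps (hematocrit 45 vs 46).  Scoring here is *benign-first*: bands are
evaluated in order of increasing severity, so a value sitting on a shared
boundary takes the mildest band that contains it, and a value falling in a
gap between printed bands is assigned the milder of the two adjacent bands.
This guarantees that every admissible value maps to exactly one Pi and that
boundary values never raise false alarms.
"""

from __future__ import annotations

import difflib
import json
import math
import warnings
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Pi",
    "Category",
    "RuleKind",
    "Comparator",
    "TierLabel",
    "Interval",
    "SeverityBand",
    "ScoringRule",
    "PopulationTier",
    "PopulationRule",
    "SentinelRule",
    "IndicatorDefinition",
    "Registry",
    "RegistryError",
    "CoverageError",
    "IndicatorNotFoundError",
    "classify_value",
    "normalized_partition",
    "load_registry",
    "default_registry",
    "default_registry_path",
]

Pi = int  # severity score, always one of {0, 1, 2}

#: Number of external (EIC) indicators the default catalog must carry.
N_EXTERNAL_INDICATORS = 11


class RegistryError(ValueError):
    """Raised for schema violations in a registry document."""


class CoverageError(RegistryError):
    """Raised when a scoring rule does not cover its admissible value domain."""


class IndicatorNotFoundError(KeyError):
    """Raised when an indicator id cannot be resolved in a registry."""

    def __init__(self, indicator_id: str, suggestions: list[str]):
        self.indicator_id = indicator_id
        self.suggestions = suggestions
        hint = f"; nearest matches: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"unknown indicator {indicator_id!r}{hint}")


class Category(str, Enum):
    external = "external"
    physiology = "physiology"
    hematology = "hematology"
    biochemistry = "biochemistry"
    damage_redox = "damage_redox"

    @property
    def cluster(self) -> str:
        """Which cluster (EIC or IIC) this category feeds."""
        return "EIC" if self is Category.external else "IIC"


class RuleKind(str, Enum):
    ordinal_observational = "ordinal_observational"
    numeric_bands = "numeric_bands"
    fold_change = "fold_change"
    baseline_relative = "baseline_relative"
    condition_factor = "condition_factor"


class Comparator(str, Enum):
    gt = "gt"
    ge = "ge"

    def apply(self, proportion: float, threshold: float) -> bool:
        if self is Comparator.gt:
            return proportion > threshold
        return proportion >= threshold


class TierLabel(str, Enum):
    intervention = "intervention"
    alert = "alert"
    critical = "critical"


class Interval(BaseModel):
    """A numeric interval with explicit endpoint inclusivity.

    ``lo``/``hi`` of ``None`` mean unbounded on that side.
    """

    lo: Optional[float] = None
    hi: Optional[float] = None
    lo_incl: bool = True
    hi_incl: bool = True

    @model_validator(mode="after")
    def _check_nonempty(self) -> "Interval":
        if self.lo is not None and self.hi is not None and not self.lo < self.hi:
            raise ValueError(f"empty interval [{self.lo}, {self.hi}]")
        return self

    def contains(self, value: float) -> bool:
        if self.lo is not None:
            if value < self.lo or (value == self.lo and not self.lo_incl):
                return False
        if self.hi is not None:
            if value > self.hi or (value == self.hi and not self.hi_incl):
                return False
        return True

    @classmethod
    def from_spec(cls, spec) -> "Interval":
        """Build from the compact JSON form ``[lo, hi, lo_incl, hi_incl]``."""
        if isinstance(spec, Interval):
            return spec
        if isinstance(spec, dict):
            return cls(**spec)
        lo, hi, lo_incl, hi_incl = spec
        return cls(lo=lo, hi=hi, lo_incl=bool(lo_incl), hi_incl=bool(hi_incl))


class SeverityBand(BaseModel):
    pi: int = Field(ge=0, le=2)
    intervals: list[Interval] = Field(default_factory=list)
    description: str = ""

    @field_validator("intervals", mode="before")
    @classmethod
    def _coerce_intervals(cls, v):
        return [Interval.from_spec(iv) for iv in (v or [])]


class ScoringRule(BaseModel):
    kind: RuleKind
    bands: list[SeverityBand]
    # admissible value domain for numeric_bands (used for coverage checking
    # and to truncate open-ended bands when simulating values)
    domain: Optional[tuple[float, float]] = None
    life_stage_variants: Optional[dict[str, list[SeverityBand]]] = None
    # one-sided raw-value cut-offs used only by the sentinel rule where the
    # printed sentinel threshold is stricter than the Pi=2 band
    severe_extreme: Optional[dict[str, float]] = None
    # baseline_relative / condition_factor parameters
    pi1_deviation: Optional[float] = None
    pi2_deviation: Optional[float] = None
    provisional_defaults: bool = False
    qualitative_pi2: Optional[str] = None
    # fold_change parameters
    symmetric: bool = False
    ratio_cap: float = 5.0
    reference_ranges: Optional[dict[str, tuple[float, float]]] = None
    # value used by the pond simulator as the reference/baseline when
    # emitting raw values for relative rule kinds (not a clinical threshold)
    emission_baseline: Optional[float] = None
    notes: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ScoringRule":
        pis = sorted(b.pi for b in self.bands)
        if pis != [0, 1, 2]:
            raise ValueError(f"rule must define exactly the bands Pi=0,1,2 (got {pis})")
        if self.kind is RuleKind.numeric_bands and self.domain is None:
            raise ValueError("numeric_bands rule requires a value domain")
        if self.kind in (RuleKind.baseline_relative, RuleKind.condition_factor):
            if self.pi1_deviation is None or self.pi2_deviation is None:
                raise ValueError(f"{self.kind.value} rule requires pi1/pi2 deviation thresholds")
            if not 0 < self.pi1_deviation < self.pi2_deviation:
                raise ValueError("deviation thresholds must satisfy 0 < pi1 < pi2")
        return self

    def bands_for(self, life_stage: Optional[str] = None) -> list[SeverityBand]:
        if life_stage and self.life_stage_variants and life_stage in self.life_stage_variants:
            return self.life_stage_variants[life_stage]
        return self.bands

    def default_reference(self) -> Optional[float]:
        """Default fold-change reference from the first printed operational range.

        Two-sided ranges use their midpoint; one-sided ranges printed as an
        upper bound (lower limit zero) use that bound, since the literature
        states them as "below X under optimal conditions".
        """
        if self.reference_ranges:
            lo, hi = next(iter(self.reference_ranges.values()))
            return hi if lo == 0 else (lo + hi) / 2.0
        return None


class PopulationTier(BaseModel):
    min_pi: int = Field(ge=1, le=2)
    proportion_threshold: float = Field(gt=0.0, lt=1.0)
    comparator: Comparator
    label: TierLabel


class PopulationRule(BaseModel):
    tiers: list[PopulationTier]

    @model_validator(mode="after")
    def _ordered(self) -> "PopulationRule":
        order = {TierLabel.intervention: 0, TierLabel.alert: 0, TierLabel.critical: 1}
        severities = [order[t.label] for t in self.tiers]
        if severities != sorted(severities):
            raise ValueError("population tiers must be ordered by increasing severity")
        return self


class SentinelRule(BaseModel):
    min_fish_at_pi2: int = Field(ge=1)
    uses_severe_extreme: bool = False


class IndicatorDefinition(BaseModel):
    id: str
    name: str
    category: Category
    scoring_rule: ScoringRule
    population_rule: PopulationRule
    sentinel_rule: SentinelRule
    dom_categories: list[str] = Field(default_factory=list)
    epi_factors: list[str] = Field(default_factory=list)
    corrective_actions: list[str] = Field(default_factory=list)
    units: str = ""

    @field_validator("id")
    @classmethod
    def _slug(cls, v: str) -> str:
        if not v or any(c.isspace() for c in v):
            raise ValueError("indicator id must be a non-empty slug")
        return v

    @property
    def cluster(self) -> str:
        return self.category.cluster


# ---------------------------------------------------------------------------
# Band evaluation: benign-first with gap closure
# ---------------------------------------------------------------------------

def classify_value(bands: list[SeverityBand], value: float) -> Pi:
    """Map a numeric value to a Pi score under the benign-first convention.

    Bands are tried in order of increasing Pi, so overlaps resolve to the
    mildest matching band.  A value in a gap between printed bands takes the
    milder of the two adjacent bands (gap closure).
    """
    if math.isnan(value):
        raise ValueError("cannot score NaN")
    ordered = sorted(bands, key=lambda b: b.pi)
    for band in ordered:
        for iv in band.intervals:
            if iv.contains(value):
                return band.pi

    # gap: locate nearest printed interval below and above
    below_pi, below_edge = None, -math.inf
    above_pi, above_edge = None, math.inf
    for band in ordered:
        for iv in band.intervals:
            hi = iv.hi if iv.hi is not None else math.inf
            lo = iv.lo if iv.lo is not None else -math.inf
            if hi <= value and hi > below_edge:
                below_edge, below_pi = hi, band.pi
            if lo >= value and lo < above_edge:
                above_edge, above_pi = lo, band.pi
    neighbors = [p for p in (below_pi, above_pi) if p is not None]
    if not neighbors:
        raise CoverageError(f"value {value} not covered by any band and no neighbor found")
    return min(neighbors)


def normalized_partition(
    bands: list[SeverityBand], domain: tuple[float, float]
) -> list[tuple[float, float, Pi]]:
    """Disjoint cells ``(lo, hi, pi)`` covering the admissible domain.

    The partition is derived from :func:`classify_value`, so it reflects the
    benign-first and gap-closure conventions.  Cell interiors are uniform in
    Pi; boundaries belong to whichever cell benign-first assigns them to.
    Used both for the load-time full-coverage check and by the pond
    simulator to draw values inside a target severity band.
    """
    lo_d, hi_d = domain
    points = {lo_d, hi_d}
    for band in bands:
        for iv in band.intervals:
            for edge in (iv.lo, iv.hi):
                if edge is not None and lo_d <= edge <= hi_d:
                    points.add(edge)
    edges = sorted(points)
    cells: list[tuple[float, float, Pi]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid = (a + b) / 2.0
        pi = classify_value(bands, mid)
        if cells and cells[-1][2] == pi and cells[-1][1] == a:
            cells[-1] = (cells[-1][0], b, pi)
        else:
            cells.append((a, b, pi))
    return cells


def _check_full_coverage(defn: IndicatorDefinition) -> None:
    """Verify that every admissible value maps to exactly one Pi.

    Checked exhaustively on the normalized partition plus a fine grid,
    including every printed endpoint, for each life-stage variant.
    """
    rule = defn.scoring_rule
    if rule.kind is not RuleKind.numeric_bands:
        return
    assert rule.domain is not None
    lo, hi = rule.domain
    stage_sets = {"default": rule.bands}
    if rule.life_stage_variants:
        stage_sets.update(rule.life_stage_variants)
    for stage, bands in stage_sets.items():
        try:
            cells = normalized_partition(bands, (lo, hi))
        except CoverageError as exc:
            raise CoverageError(f"indicator {defn.id!r} ({stage}): {exc}") from exc
        covered_hi = lo
        for a, b, _pi in cells:
            if a != covered_hi:
                raise CoverageError(f"indicator {defn.id!r} ({stage}): hole at {a}")
            covered_hi = b
        if covered_hi != hi:
            raise CoverageError(f"indicator {defn.id!r} ({stage}): domain not covered to {hi}")
        # endpoints and a fine grid must each classify without error
        step = (hi - lo) / 400.0
        for k in range(401):
            classify_value(bands, lo + k * step)


class Registry(BaseModel):
    version: str
    indicators: list[IndicatorDefinition]

    @model_validator(mode="after")
    def _unique_ids(self) -> "Registry":
        seen: set[str] = set()
        for ind in self.indicators:
            key = ind.id.lower()
            if key in seen:
                raise ValueError(f"duplicate indicator id {ind.id!r}")
            seen.add(key)
        if not self.indicators:
            warnings.warn("registry contains no indicators (flagged incomplete)", stacklevel=2)
        return self

    def lookup(self, indicator_id: str) -> IndicatorDefinition:
        """Case-insensitive lookup; unknown ids raise with nearest matches."""
        key = indicator_id.lower()
        for ind in self.indicators:
            if ind.id.lower() == key:
                return ind
        suggestions = difflib.get_close_matches(key, [i.id for i in self.indicators], n=3)
        raise IndicatorNotFoundError(indicator_id, suggestions)

    def __contains__(self, indicator_id: str) -> bool:
        try:
            self.lookup(indicator_id)
            return True
        except IndicatorNotFoundError:
            return False

    def ids(self) -> list[str]:
        return [i.id for i in self.indicators]

    def by_category(self, category: Category) -> list[IndicatorDefinition]:
        return [i for i in self.indicators if i.category is category]

    @property
    def n_external(self) -> int:
        return len(self.by_category(Category.external))

    def to_dict(self) -> dict:
        return self.model_dump(mode="json", exclude_none=True, exclude_defaults=False)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _validate(registry: Registry) -> Registry:
    for defn in registry.indicators:
        _check_full_coverage(defn)
    return registry


def load_registry(path: str | Path) -> Registry:
    """Load and validate a registry document (JSON canonical, YAML accepted)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    try:
        registry = Registry.model_validate(raw)
    except Exception as exc:  # re-raise pydantic errors under the package type
        raise RegistryError(f"invalid registry document {path.name}: {exc}") from exc
    return _validate(registry)


def default_registry_path() -> Path:
    return Path(__file__).parent / "data" / "default_registry.json"


def default_registry() -> Registry:
    """The shipped default catalog (all external and internal indicators)."""
    return load_registry(default_registry_path())
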