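"""Seeded synthetic ponds and Monte-Carlo operating characteristics.

The generator fabricates tidy measurement tables for ponds of ``N`` fish
with configurable per-indicator severity mixtures (probability of latent
Pi=0/1/2 per fish), so every scoring path can be exercised without real
data.  Emission is *band-consistent*: a numeric value drawn for a fish with
latent severity Pi is drawn uniformly inside that severity's normalized
band, so rescoring the emitted table through the registry recovers the
latent state exactly.  Open-ended printed bands are truncated at the
admissible-domain cap stored in the registry (a physiologic ceiling, not a
literature threshold).

The Monte-Carlo harness validates the sampling calculators: it draws
replicate ponds, samples fish without replacement (hypergeometric, the
finite-pond default; with-replacement is available to check the binomial
approximation), applies the detection event, and reports the empirical
detection rate with its standard error for comparison against the analytic
form.

RNG contract: one root seed; independent sub-streams are derived per
replicate index (``numpy.random.SeedSequence.spawn``), so replicate results
do not depend on evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Callable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .registry import IndicatorDefinition, Registry, RuleKind, normalized_partition
from .sampling import PrevalenceDesign, SamplingError, detection_probability
from .scoring import Measurement, ScoreContext

__all__ = [
    "SimConfig",
    "SyntheticPond",
    "OCResult",
    "PrecisionResult",
    "generate_pond",
    "simulate_sentinel_oc",
    "simulate_prevalence_precision",
]


class SimConfig(BaseModel):
    """Configuration of a synthetic pond experiment.

    ``mixtures`` maps indicator id to the per-fish probabilities of latent
    severity (P(Pi=0), P(Pi=1), P(Pi=2)).
    """

    population_size: int = Field(ge=1, default=10_000)
    mixtures: dict[str, tuple[float, float, float]]
    value_mode: str = "draw_within_band"  # or "emit_ordinal"
    life_stage: str = "adult"
    seed: int = 0
    replicates: int = Field(ge=1, default=1)
    pond_id: str = "pond-1"
    date: Optional[Date] = None

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.value_mode not in ("draw_within_band", "emit_ordinal"):
            raise ValueError("value_mode must be draw_within_band or emit_ordinal")
        for ind, mix in self.mixtures.items():
            if len(mix) != 3 or any(p < 0 for p in mix):
                raise ValueError(f"mixture for {ind!r} must be three non-negative probabilities")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"mixture for {ind!r} must sum to 1 (got {sum(mix)})")
        return self


@dataclass
class SyntheticPond:
    config: SimConfig
    latent: dict[str, np.ndarray]  # indicator id -> int array of length N
    measurements: list[Measurement]
    realized_prevalence: dict[str, dict[int, float]]
    #: references used at emission, suitable for rescoring via evaluate_cohort
    context: dict[str, ScoreContext] = field(default_factory=dict)

    def fish_ids(self) -> list[str]:
        width = len(str(self.config.population_size - 1))
        return [f"f{idx:0{width}d}" for idx in range(self.config.population_size)]


# ---------------------------------------------------------------------------
# band-consistent value emission
# ---------------------------------------------------------------------------

def _partition_by_scoring(
    score: Callable[[float], int], lo: float, hi: float, n_grid: int = 2048
) -> list[tuple[float, float, int]]:
    """Partition [lo, hi] into maximal cells of constant score.

    Boundaries between grid points with differing scores are refined by
    bisection; used for rule kinds whose severity regions are defined by a
    scoring function rather than printed intervals.
    """
    xs = np.linspace(lo, hi, n_grid)
    scores = [score(float(x)) for x in xs]
    cells: list[tuple[float, float, int]] = []
    start = lo
    for i in range(1, n_grid):
        if scores[i] != scores[i - 1]:
            a, b = float(xs[i - 1]), float(xs[i])
            sa = scores[i - 1]
            for _ in range(60):
                m = (a + b) / 2.0
                if score(m) == sa:
                    a = m
                else:
                    b = m
            cells.append((start, a, sa))
            start = b
    cells.append((start, hi, scores[-1]))
    return cells


def _emission_cells(
    defn: IndicatorDefinition, life_stage: str
) -> tuple[list[tuple[float, float, int]], Optional[ScoreContext]]:
    """Severity-labelled value cells for uniform within-band draws."""
    rule = defn.scoring_rule
    if rule.kind is RuleKind.numeric_bands:
        cells = normalized_partition(rule.bands_for(life_stage), rule.domain)
        return cells, None

    from .scoring import score_value  # local import to avoid cycle at module load

    if rule.kind is RuleKind.fold_change:
        ref = rule.default_reference()
        if ref is None:
            raise ValueError(f"indicator {defn.id!r} has no reference range for emission")
        ctx = ScoreContext(reference=None)  # scorer uses registry default reference
        lo, hi = ref * 1e-3, ref * rule.ratio_cap
        cells = _partition_by_scoring(lambda v: score_value(defn, v, life_stage), lo, hi)
        return cells, ctx
    if rule.kind is RuleKind.baseline_relative:
        if rule.reference_ranges:  # electrolyte-style panel: emit the primary analyte
            lo_r, hi_r = next(iter(rule.reference_ranges.values()))
            lo, hi = lo_r * 0.5, hi_r * 1.5
            cells = _partition_by_scoring(lambda v: score_value(defn, v, life_stage), lo, hi)
            return cells, None
        base = rule.emission_baseline
        if base is None:
            raise ValueError(f"indicator {defn.id!r} has no emission baseline")
        ctx = ScoreContext(baseline=base)
        cells = _partition_by_scoring(
            lambda v: score_value(defn, v, life_stage, ctx), base * 1e-3, base * 2.0)
        return cells, ctx
    if rule.kind is RuleKind.condition_factor:
        k_mu = rule.emission_baseline or 1.5
        ctx = ScoreContext(k_mu=k_mu)
        cells = _partition_by_scoring(
            lambda v: score_value(defn, v, life_stage, ctx), k_mu * 0.4, k_mu * 1.6)
        return cells, ctx
    raise ValueError(f"indicator {defn.id!r} is observational; no value emission")


def _draw_in_cells(
    rng: np.random.Generator,
    cells: Sequence[tuple[float, float, int]],
    pi: int,
    n: int,
) -> np.ndarray:
    pool = [(a, b) for a, b, p in cells if p == pi and b > a]
    if not pool:
        raise ValueError(f"no admissible value region for Pi={pi}")
    widths = np.array([b - a for a, b in pool])
    probs = widths / widths.sum()
    idx = rng.choice(len(pool), size=n, p=probs)
    u = rng.random(n)
    lo = np.array([pool[i][0] for i in idx])
    hi = np.array([pool[i][1] for i in idx])
    # keep draws strictly interior so boundary conventions cannot flip them
    margin = (hi - lo) * 1e-6
    return lo + margin + u * (hi - lo - 2 * margin)


# ---------------------------------------------------------------------------
# pond generation
# ---------------------------------------------------------------------------

def generate_pond(config: SimConfig, registry: Registry) -> SyntheticPond:
    """Fabricate one pond: latent severities and the emitted measurement table.

    Deterministic given the config (including seed): identical configs yield
    byte-identical tables.  In ``draw_within_band`` mode numeric indicators
    emit values uniformly inside the latent severity's normalized band;
    observational indicators always emit the ordinal score.
    """
    for ind in config.mixtures:
        if ind not in registry:
            registry.lookup(ind)  # raises with suggestions
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.population_size
    width = len(str(n - 1))
    fish_ids = [f"f{idx:0{width}d}" for idx in range(n)]

    latent: dict[str, np.ndarray] = {}
    measurements: list[Measurement] = []
    realized: dict[str, dict[int, float]] = {}
    context: dict[str, ScoreContext] = {}

    for ind_id in sorted(config.mixtures):
        defn = registry.lookup(ind_id)
        mix = np.array(config.mixtures[ind_id], dtype=float)
        pis = rng.choice(3, size=n, p=mix / mix.sum())
        latent[defn.id] = pis
        realized[defn.id] = {k: float(np.mean(pis == k)) for k in (0, 1, 2)}

        emit_values = (config.value_mode == "draw_within_band"
                       and defn.scoring_rule.kind is not RuleKind.ordinal_observational)
        if emit_values:
            cells, ctx = _emission_cells(defn, config.life_stage)
            if ctx is not None:
                context[defn.id] = ctx
            values = np.empty(n)
            for pi in (0, 1, 2):
                mask = pis == pi
                if mask.any():
                    values[mask] = _draw_in_cells(rng, cells, pi, int(mask.sum()))
            for fid, value in zip(fish_ids, values):
                measurements.append(Measurement(
                    pond_id=config.pond_id, fish_id=fid, indicator_id=defn.id,
                    value=float(value), units=defn.units, life_stage=config.life_stage,
                    date=config.date))
        else:
            for fid, pi in zip(fish_ids, pis):
                measurements.append(Measurement(
                    pond_id=config.pond_id, fish_id=fid, indicator_id=defn.id,
                    pi=int(pi), life_stage=config.life_stage, date=config.date))

    return SyntheticPond(config=config, latent=latent, measurements=measurements,
                         realized_prevalence=realized, context=context)


# ---------------------------------------------------------------------------
# operating characteristics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OCResult:
    detection_rate: float
    se: float
    replicates: int
    sample_n: int
    prevalence: float
    analytic: float

    def to_dict(self) -> dict:
        return {
            "detection_rate": self.detection_rate, "se": self.se,
            "replicates": self.replicates, "sample_n": self.sample_n,
            "prevalence": self.prevalence, "analytic": self.analytic,
        }


@dataclass(frozen=True)
class PrecisionResult:
    within_d_fraction: float
    ci_coverage: float
    replicates: int
    sample_n: int
    d: float

    def to_dict(self) -> dict:
        return {
            "within_d_fraction": self.within_d_fraction, "ci_coverage": self.ci_coverage,
            "replicates": self.replicates, "sample_n": self.sample_n, "d": self.d,
        }


def _target_indicator(config: SimConfig, indicator_id: Optional[str]) -> str:
    if indicator_id is not None:
        return indicator_id
    if len(config.mixtures) != 1:
        raise ValueError("specify indicator_id when the config carries several mixtures")
    return next(iter(config.mixtures))


def simulate_sentinel_oc(
    config: SimConfig,
    sample_n: int,
    indicator_id: Optional[str] = None,
    min_detect: int = 1,
    with_replacement: bool = False,
) -> OCResult:
    """Empirical detection rate of sampling ``sample_n`` fish per pond.

    Each replicate draws a fresh pond (every fish independently severe with
    the mixture's Pi=2 probability) and samples without replacement; the
    detection event is ``>= min_detect`` sampled fish at Pi=2 (``min_detect=1``
    matches the detect-one-case design; 2 reproduces the usual sentinel AWE
    rule).  Only the latent severity states matter for detection — emitted
    numeric values rescore to the latent state exactly — so ponds are drawn
    at the latent level for speed.  Returns the mean rate, its Monte-Carlo
    standard error and the analytic binomial detection probability.
    """
    n_pop = config.population_size
    if sample_n > n_pop:
        raise SamplingError("cannot sample more fish than the pond holds")
    ind = _target_indicator(config, indicator_id)
    p2 = config.mixtures[ind][2]

    root = np.random.SeedSequence(config.seed)
    reps = config.replicates
    rngs = [np.random.default_rng(s) for s in root.spawn(reps)]
    hits = 0
    for rng in rngs:
        k2 = rng.binomial(n_pop, p2)  # latent severe fish in this pond
        if with_replacement:
            x = rng.binomial(sample_n, k2 / n_pop)
        else:
            x = rng.hypergeometric(k2, n_pop - k2, sample_n) if 0 < k2 < n_pop else (
                0 if k2 == 0 else sample_n)
        if x >= min_detect:
            hits += 1
    rate = hits / reps
    se = math.sqrt(max(rate * (1 - rate), 1.0 / reps) / reps)
    analytic = detection_probability(sample_n, p2)
    return OCResult(detection_rate=rate, se=se, replicates=reps,
                    sample_n=sample_n, prevalence=p2, analytic=analytic)


def simulate_prevalence_precision(
    config: SimConfig,
    design: PrevalenceDesign,
    indicator_id: Optional[str] = None,
    min_pi: int = 1,
) -> PrecisionResult:
    """Coverage/precision of prevalence estimation at the design's sample size.

    Across replicates, draws a pond, samples ``design.n_final`` fish without
    replacement, estimates the prevalence of fish at Pi >= ``min_pi`` and
    reports (i) the fraction of estimates within +/-d of the realized pond
    prevalence and (ii) the coverage of the normal-approximation confidence
    interval (finite-population corrected).
    """
    n_pop = config.population_size
    n = design.n_final
    if n > n_pop:
        raise SamplingError("design sample size exceeds the pond population")
    ind = _target_indicator(config, indicator_id)
    mix = config.mixtures[ind]
    p_true_cfg = sum(mix[k] for k in range(min_pi, 3))

    root = np.random.SeedSequence(config.seed)
    reps = config.replicates
    rngs = [np.random.default_rng(s) for s in root.spawn(reps)]
    within = 0
    covered = 0
    fpc = math.sqrt((n_pop - n) / (n_pop - 1)) if n_pop > 1 else 0.0
    for rng in rngs:
        k = rng.binomial(n_pop, p_true_cfg)
        p_pond = k / n_pop
        if n == n_pop:
            x = k
        else:
            x = rng.hypergeometric(k, n_pop - k, n) if 0 < k < n_pop else (0 if k == 0 else n)
        phat = x / n
        if abs(phat - p_pond) <= design.d:
            within += 1
        half = design.z * math.sqrt(phat * (1 - phat) / n) * fpc
        if phat - half <= p_pond <= phat + half:
            covered += 1
    return PrecisionResult(within_d_fraction=within / reps, ci_coverage=covered / reps,
                           replicates=reps, sample_n=n, d=design.d)
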