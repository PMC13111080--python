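"""Epidemiological sampling design for pond-level welfare surveillance.

Two classical survey objectives are covered:

* **Prevalence estimation** — how many fish to sample to estimate the
  proportion affected with absolute precision ``d`` at a given confidence:
  ``n0 = Z^2 * P_exp * (1 - P_exp) / d^2``, with the finite population
  correction ``n_adj = n0 / (1 + (n0 - 1) / N)`` when the pond size ``N``
  is known.
* **Sentinel detection** — how many fish to sample to observe at least one
  affected fish with confidence ``CL`` when the true prevalence is at least
  the design prevalence ``p*``: ``n = ln(1 - CL) / ln(1 - p*)`` (binomial
  approximation for large ponds).

Final sample sizes are rounded up (a fish is indivisible and rounding down
would fall short of the nominal confidence/precision).  The analytic
detection probability is available in both the binomial form
``1 - (1 - p)^n`` and the exact finite-population hypergeometric form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

__all__ = [
    "Z_BY_CONFIDENCE",
    "PrevalenceDesign",
    "SentinelDesign",
    "TwoStagePlan",
    "SamplingError",
    "z_value",
    "sample_size_proportion",
    "finite_population_correction",
    "sentinel_sample_size",
    "detection_probability",
    "two_stage_plan",
]


class SamplingError(ValueError):
    pass


#: Conventional Z constants used verbatim for the two standard confidence
#: levels so that published worked examples reproduce exactly; other levels
#: fall back to the standard normal quantile.
Z_BY_CONFIDENCE = {0.95: 1.96, 0.99: 2.576}


def z_value(confidence: float) -> float:
    if not 0 < confidence < 1:
        raise SamplingError("confidence must be in (0, 1)")
    if confidence in Z_BY_CONFIDENCE:
        return Z_BY_CONFIDENCE[confidence]
    return float(stats.norm.ppf(0.5 + confidence / 2.0))


@dataclass(frozen=True)
class PrevalenceDesign:
    z: float
    confidence: Optional[float]
    p_exp: float
    d: float
    population_size: Optional[int]
    n0: float
    n_adj: Optional[float]
    n_final: int

    def summary(self) -> str:
        parts = [f"n0 = {self.n0:.2f}"]
        if self.n_adj is not None:
            parts.append(f"n_adj = {self.n_adj:.2f}")
        parts.append(f"sample {self.n_final} fish")
        return "  =>  ".join(parts)


@dataclass(frozen=True)
class SentinelDesign:
    confidence: float
    design_prevalence: float
    n_raw: float
    n_final: int

    def summary(self) -> str:
        return f"n = {self.n_raw:.1f}  =>  sample {self.n_final} fish"


@dataclass(frozen=True)
class TwoStagePlan:
    n_ext: int
    n_int: int
    frame: str = "same pond, date and context; internal subsample drawn at random from the external sample"
    notes: str = ""

    def __post_init__(self):
        if not 1 <= self.n_int <= self.n_ext:
            raise SamplingError("two-stage plan requires 1 <= n_int <= n_ext")


def finite_population_correction(n0: float, population_size: int) -> float:
    """Adjust an infinite-population sample size for a finite pond.

    ``n_adj = n0 / (1 + (n0 - 1)/N)``; always <= n0, converging to n0 as
    N grows.
    """
    if population_size <= 0:
        raise SamplingError("population size must be positive")
    if n0 <= 0:
        raise SamplingError("n0 must be positive")
    return n0 / (1.0 + (n0 - 1.0) / population_size)


def sample_size_proportion(
    confidence: Optional[float] = None,
    p_exp: float = 0.5,
    d: float = 0.1,
    population_size: Optional[int] = None,
    z: Optional[float] = None,
) -> PrevalenceDesign:
    """Sample size to estimate a prevalence with absolute precision ``d``.

    Supply either ``confidence`` (0.95/0.99 use the conventional Z constants
    1.96/2.576) or ``z`` directly.  ``p_exp`` defaults to 0.5, the most
    conservative (variance-maximizing) expectation.  When the pond
    population ``N`` is given the finite population correction is applied.
    """
    if z is None:
        if confidence is None:
            raise SamplingError("supply either a confidence level or a Z value")
        z = z_value(confidence)
    elif z <= 0:
        raise SamplingError("Z must be positive")
    if not 0 <= p_exp <= 1:
        raise SamplingError("expected prevalence must be in [0, 1]")
    if not 0 < d < 1:
        raise SamplingError("precision d must be in (0, 1)")
    if population_size is not None and population_size < 1:
        raise SamplingError("population size must be >= 1")

    n0 = z**2 * p_exp * (1.0 - p_exp) / d**2
    n_adj: Optional[float] = None
    if p_exp in (0.0, 1.0):  # degenerate: zero variance
        n_final = 0
    elif population_size is not None:
        n_adj = finite_population_correction(n0, population_size)
        n_final = math.ceil(n_adj)
    else:
        n_final = math.ceil(n0)
    return PrevalenceDesign(z=z, confidence=confidence, p_exp=p_exp, d=d,
                            population_size=population_size, n0=n0, n_adj=n_adj,
                            n_final=n_final)


def sentinel_sample_size(confidence: float, design_prevalence: float) -> SentinelDesign:
    """Sample size to detect at least one affected fish.

    ``n = ln(1 - CL) / ln(1 - p*)``, rounded up.  ``p*`` is the minimum
    prevalence the surveillance scheme is designed not to miss.
    """
    if not 0 < confidence < 1:
        raise SamplingError("confidence must be in (0, 1)")
    if not 0 < design_prevalence < 1:
        raise SamplingError("design prevalence must be in (0, 1)")
    n_raw = math.log(1.0 - confidence) / math.log(1.0 - design_prevalence)
    return SentinelDesign(confidence=confidence, design_prevalence=design_prevalence,
                          n_raw=n_raw, n_final=math.ceil(n_raw))


def detection_probability(
    n: int,
    prevalence: float,
    population_size: Optional[int] = None,
) -> float:
    """Probability that a sample of ``n`` fish contains >=1 affected fish.

    Without ``N``: binomial approximation ``1 - (1 - p)^n``.  With ``N``:
    exact hypergeometric complement ``1 - C(N-K, n)/C(N, n)`` for sampling
    without replacement, where ``K = round(p * N)`` affected fish (floored
    at 1 when p > 0, since a positive design prevalence means the case
    class exists).
    """
    if n < 0:
        raise SamplingError("sample size must be non-negative")
    if not 0 <= prevalence <= 1:
        raise SamplingError("prevalence must be in [0, 1]")
    if population_size is not None and n > population_size:
        raise SamplingError("cannot sample more fish than the pond holds")
    if prevalence == 0 or n == 0:
        return 0.0
    if population_size is None:
        return 1.0 - (1.0 - prevalence) ** n
    k = max(1, round(prevalence * population_size))
    # P(X = 0), X ~ Hypergeom(N, K, n)
    p0 = float(stats.hypergeom.pmf(0, population_size, k, n))
    return min(1.0, max(0.0, 1.0 - p0))


def two_stage_plan(
    design: "PrevalenceDesign | SentinelDesign",
    n_int_budget: int,
) -> TwoStagePlan:
    """External/internal two-stage plan for handling events.

    The external-indicator subsample size comes from the chosen design
    (prevalence or sentinel); the internal-indicator subsample is drawn at
    random from the same sampling frame, capped by the cost/time budget.
    """
    if n_int_budget < 1:
        raise SamplingError("internal subsample budget must be >= 1")
    n_ext = design.n_final
    if n_ext < 1:
        raise SamplingError("external design yields an empty sample")
    return TwoStagePlan(
        n_ext=n_ext,
        n_int=min(n_int_budget, n_ext),
        notes="internal subsample constrained by cost/time and procedure biology",
    )
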