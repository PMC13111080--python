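# Methods and design notes

## The model

`tilawell` operationalizes a rule-based welfare-assessment protocol for
farmed tilapia. The unit of observation is one indicator measured on one
fish; the unit of decision is a pond (or batch) sampled on one date. Every
indicator is scored on a three-level ordinal severity scale
*P*ᵢ ∈ {0, 1, 2} — normal, mild/moderate, severe — and three group-level
rules convert a sample of scores into actions:

1. **Population criterion.** The proportion of sampled fish with
   *P*ᵢ ≥ *t* is compared against a printed threshold with the printed
   comparator. Thresholds differ by indicator (10 % for opercular damage,
   ulcers, deformities and ocular lesions; 15 % for peduncle damage,
   parasitosis and hemorrhages; 20 % for the rest; the damage/redox panel
   uses a two-tier rule: alert >25 % at *P*ᵢ ≥ 1, critical ≥10 % at
   *P*ᵢ = 2). Comparators are stored exactly as printed (`>` vs `≥`) and
   never homogenized.
2. **Sentinel criterion.** A minimum count of fish at *P*ᵢ = 2 declares an
   adverse welfare event (AWE) regardless of proportion: two fish for most
   indicators, one for the tissue-damage/redox panel. For glucose and
   cortisol the literature prints stricter sentinel cut-offs (>150 mg/dl /
   <30 mg/dl; >150 ng/ml) than the *P*ᵢ = 2 bands; both are stored, and the
   stricter values gate which fish count as sentinel-grade when raw values
   are available.
3. **Cluster criterion.** Per fish, the External and Internal Indicator
   Clusters are the (optionally weighted) means of the scored *P*ᵢ in each
   dimension: EIC = ΣPᵢ/n over external indicators, IIC likewise over
   internal ones, with *n* the number of indicators actually assessed
   (missing indicators reduce *n*; they are never imputed). Interpretation:
   < 0.5 stable, 0.5–<1.2 mild-to-moderate risk, ≥1.2 consolidated AWE.
   The printed interpretation table has a gap between 1.1 and 1.2; we treat
   the middle band as [0.5, 1.2) since 1.2 is the printed AWE threshold.

The cohort-level AWE flag is the disjunction of the three rules — any
sentinel fired, any fish with any *P*ᵢ = 2, or any fish cluster ≥ 1.2 —
with full provenance of which rule fired on which fish/indicator. The
"any single fish at *P*ᵢ = 2" clause and the "≥2 fish" sentinel rules are
deliberately both exposed: the aggregate AWE definition and the
per-indicator sentinel rules are not mutually consistent in the source
protocol, so the engine reports both signals separately and lets
provenance disambiguate.

## Boundary convention (benign-first)

Printed reference bands overlap at shared endpoints (glucose 40–80 normal
vs 80–100 mild) and occasionally leave gaps (hematocrit Pi0 ends at 45,
Pi1 starts at 46). Scoring is *benign-first*: bands are evaluated in order
of increasing severity, so a shared boundary takes the mildest containing
band, and a value in a gap takes the milder of its two adjacent bands.
This makes severity a total function on each indicator's admissible
domain (verified exhaustively at catalog load time) and avoids false
alarms at boundary values. Two printed ambiguities are resolved by the
same convention and are worth knowing about:

* Eosinophils: the mild band "1–2 %" and the severe "<1 %" are inside the
  printed normal range "0–5 %", so low eosinophil counts score 0. Only
  eosinophilia is scoreable from the printed bands.
* H/L ratio below 0.15: printed as mild *only* when immunostimulant
  supplementation is documented; since low H/L otherwise indicates low
  stress, the default scoring maps it to 0.
* Condition factor: the 10 % deviation boundary is benign (scores 0) but
  the 20 % boundary is severe, following the printed "≥20 % below/above".

Two further printed values needed resolution: the hemorrhage population
threshold is printed as a range (">15–20 %") and is stored as the
conservative lower bound (>15 %); the glucose severe-low bound printed as
"<35–40" is stored as <35 (35–40 is the printed mild band).

## Scoring-rule kinds

* `numeric_bands` — absolute intervals per severity (hematology,
  biochemistry, protein carbonyls), with life-stage variants only where
  printed (total proteins, triglycerides). Juvenile triglyceride bands are
  completed from the printed juvenile normal range (100–400 mg/dl upper
  band, adult band widths reused above it) because only the normal range
  and the >400 mg/dl severe threshold are printed.
* `fold_change` — severity from the ratio of observed to a reference
  value: ≤1.0× normal, >1.0× and <2.0× mild, ≥2.0× severe (hepatic/muscle
  enzymes, MDA). The reference is deployment-configurable; the default is
  the midpoint of the printed operational range, or its upper bound for
  one-sided ranges printed as "< X under optimal conditions" (MDA). A
  value inside the printed operational range always scores 0. The
  antioxidant enzymes (SOD/CAT/GPx) use the symmetric variant: a ≥2×
  change in either direction (induction or exhaustion) is severe; the
  printed mild band "≤1.8×" leaves a gap below 2.0× that the benign-first
  rule closes into the mild band.
* `baseline_relative` — respiratory and heart rate have no universal
  reference values and are scored against a batch baseline. The deviation
  thresholds (±20 % mild, ±50 % severe) are package defaults, **not**
  literature constants, and are flagged as such in the catalog;
  qualitative severe findings (gasping, opercular asynchrony, marked
  arrhythmia) should be entered as ordinal *P*ᵢ = 2. The
  electrolyte/osmolality panel reuses this kind with per-analyte reference
  ranges and the printed rule: one analyte 10–20 % beyond its range is
  mild; >20 %, or two or more analytes out of range, is severe.
* `condition_factor` — Fulton's K = 100·W/L³ (W in g, L in cm; the
  standard definition, which the source protocol references by name
  without printing) relative to the batch mean K̄, computed from the
  cohort itself when not supplied.
* `ordinal_observational` — external indicators scored visually in the
  field arrive as ordinal *P*ᵢ directly.

## Sampling design

Prevalence estimation uses the normal-approximation size
n₀ = Z²·P_exp·(1−P_exp)/d², with the conventional constants Z = 1.96 and
2.576 used verbatim at 95 %/99 % so published worked examples reproduce
to the printed decimals (other confidence levels use the exact normal
quantile). The finite population correction is applied whenever N is
supplied — it is harmless for large N and matches the worked example at
N = 10,000. Sentinel (detect-≥1-case) sizing uses the binomial
approximation n = ln(1−CL)/ln(1−p*). Final sizes round *up*: a fish is
indivisible and rounding down would miss the nominal precision or
confidence. The analytic detection probability is offered both as the
binomial 1−(1−p)ⁿ and as the exact hypergeometric complement for finite
ponds, with K = round(p·N) affected fish floored at 1 when p > 0 (a
positive design prevalence asserts the case class exists).

## The simulator and what it does (not) show

A synthetic pond draws each fish's latent severity independently from a
per-indicator mixture (P₀, P₁, P₂) and, in `draw_within_band` mode, emits
a numeric value uniformly inside the latent severity's *normalized* band
(the disjoint partition produced by the benign-first/gap-closure rules,
truncated at a documented physiologic cap for open-ended bands — e.g.
hematocrit values are drawn in (0, 100], fold-change ratios capped at 5×).
Draws are kept strictly interior to the band, so rescoring the emitted
table recovers the latent severities exactly; this round trip is a tested
invariant and is what allows the operating-characteristics harness to
work at the latent level: detection events depend only on latent
severities, so replicate ponds are drawn as a binomial count of severe
fish followed by a hypergeometric (without-replacement) or binomial
(with-replacement) sample — an exact distributional restatement of
"generate the pond, then sample n fish".

The generator emulates a snapshot: static prevalence, independent fish,
independent indicators. Real ponds violate all three (disease clusters
spatially, indicators co-vary through shared physiology, prevalence moves
in time), so passing operating-characteristics tests validate the
*sampling arithmetic*, not field performance of the thresholds. The
default simulated scenario mirrors the protocol's own worked setting —
N = 10,000 fish, 5 % severe prevalence, samples of 60, 10,000 replicates.

RNG contract: one root seed; per-replicate sub-streams via
`SeedSequence.spawn`, so results are independent of evaluation order and
identical configs give byte-identical measurement tables.

## Reporting

Signals serialize as the strings `green`/`yellow`/`red` (terminal color is
cosmetic): green = no trigger; yellow = a population tier fired without
any AWE; red = at least one AWE trigger (and never red without one — a
tested invariant). A report unions the DOM categories of all triggered
indicators and carries their corrective-action texts verbatim in catalog
order. Dashboard rows are one record per (pond, date, indicator); appends
are idempotent on (pond, date, indicator, registry version). Assessment
cadence is advisory; the store accepts whatever cadence is run. Two
longitudinal helpers operate on consecutive assessments of one pond:
`repeated_detection` (same indicator with ≥1 fish at *P*ᵢ = 2 in two
consecutive assessments — the operationalization chosen for "repeated
detection", which the source leaves without a window) and `rising_trend`
(strictly increasing per-indicator mean raw value across two consecutive
dates, the escalation clause of the damage/redox panel).

## Numerical choices and degenerate inputs

* Deviation-threshold comparisons absorb float round-off with a 1e-9
  tolerance so that values landing exactly on a printed percentage
  boundary (e.g. K at 1.10·K̄) classify as intended.
* P_exp ∈ {0, 1} gives a degenerate n₀ = 0 (zero variance), returned
  flagged rather than raised.
* Empty samples, non-positive references/baselines, unknown indicators and
  unit mismatches raise typed errors; there is no silent unit conversion.
* Cluster weights are normalized internally; negative or all-zero weights
  are rejected.

## Known limitations

* Behavioral indicators are not modeled (deferred by the source protocol).
* Baseline-relative defaults (±20 %/±50 %) are pragmatic placeholders
  until a deployment supplies batch baselines.
* The population "alert" tier of the damage/redox panel is evaluated as
  *P*ᵢ ≥ 1 rather than *P*ᵢ = 1 exactly: counting only *P*ᵢ = 1 would let
  a worsening fish (1 → 2) *un*-trigger an alert, violating monotonicity
  of escalation.
* The hypergeometric detection probability treats K = round(p·N) as fixed;
  for very small ponds the binomial-mixture view can differ slightly.
* No adjustment for imperfect diagnostic sensitivity, clustered sampling
  or stratified designs.
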