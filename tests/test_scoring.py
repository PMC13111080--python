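"""Severity scoring, clusters and AWE decision rules.

The printed indicator tables serve as the fixtures: every band endpoint
asserted here was checked against the operational reference ranges for
adult (and where stated, juvenile) tilapia.
"""

from datetime import date

import pytest

from tilawell.scoring import (
    ClusterInterpretation,
    Measurement,
    ScoreContext,
    ScoringError,
    compute_cluster,
    evaluate_cohort,
    evaluate_measurements,
    fulton_k,
    longitudinal_flags,
    measurements_to_frame,
    population_criterion,
    read_measurements_csv,
    score_baseline_relative,
    score_condition_factor,
    score_electrolyte_panel,
    score_fold_change,
    score_measurement,
    score_value,
    sentinel_awe,
)

# ---------------------------------------------------------------------------
# table-driven scoring of printed band endpoints
# ---------------------------------------------------------------------------

TABLE_CASES = [
    # hematology
    ("hct", 30.0, 0), ("hct", 48.0, 1), ("hct", 19.0, 2), ("hct", 22.0, 1), ("hct", 60.0, 2),
    ("hb", 9.0, 0), ("hb", 6.5, 1), ("hb", 13.0, 1), ("hb", 5.0, 2), ("hb", 15.0, 2),
    ("wbc", 80_000.0, 0), ("wbc", 17_000.0, 1), ("wbc", 180_000.0, 1),
    ("wbc", 10_000.0, 2), ("wbc", 250_000.0, 2),
    ("lymphocytes", 70.0, 0), ("lymphocytes", 55.0, 1), ("lymphocytes", 90.0, 1),
    ("lymphocytes", 45.0, 2), ("lymphocytes", 97.0, 2),
    ("neutrophils", 20.0, 0), ("neutrophils", 35.0, 1), ("neutrophils", 7.0, 1),
    ("neutrophils", 45.0, 2), ("neutrophils", 3.0, 2),
    ("monocytes", 5.0, 0), ("monocytes", 1.5, 1), ("monocytes", 10.0, 1),
    ("monocytes", 0.5, 2), ("monocytes", 14.0, 2),
    ("eosinophils", 3.0, 0), ("eosinophils", 8.0, 1), ("eosinophils", 12.0, 2),
    ("hl_ratio", 0.4, 0), ("hl_ratio", 0.6, 1), ("hl_ratio", 0.8, 2),
    # biochemistry
    ("glucose", 60.0, 0), ("glucose", 90.0, 1), ("glucose", 120.0, 2),
    ("glucose", 37.0, 1), ("glucose", 30.0, 2),
    ("lactate", 3.0, 0), ("lactate", 5.5, 1), ("lactate", 7.0, 2), ("lactate", 1.0, 0),
    ("cortisol", 25.0, 0), ("cortisol", 75.0, 1), ("cortisol", 4.0, 1),
    ("cortisol", 120.0, 2), ("cortisol", 2.0, 2),
    ("total_proteins", 4.5, 0), ("total_proteins", 2.7, 1), ("total_proteins", 6.5, 1),
    ("total_proteins", 2.0, 2), ("total_proteins", 7.5, 2),
    ("cholesterol", 150.0, 0), ("cholesterol", 90.0, 1), ("cholesterol", 215.0, 1),
    ("cholesterol", 70.0, 2), ("cholesterol", 250.0, 2),
    ("triglycerides", 200.0, 0), ("triglycerides", 90.0, 1), ("triglycerides", 320.0, 1),
    ("triglycerides", 70.0, 2), ("triglycerides", 400.0, 2),
    ("albumin", 2.5, 0), ("albumin", 1.4, 1), ("albumin", 3.6, 1),
    ("albumin", 1.0, 2), ("albumin", 4.0, 2),
    ("globulins", 2.0, 0), ("globulins", 1.3, 1), ("globulins", 3.2, 1),
    ("globulins", 1.0, 2), ("globulins", 3.8, 2),
    ("ag_ratio", 1.0, 0), ("ag_ratio", 0.75, 1), ("ag_ratio", 1.6, 1),
    ("ag_ratio", 0.6, 2), ("ag_ratio", 2.0, 2),
    ("plasma_ammonia", 50.0, 0), ("plasma_ammonia", 150.0, 1), ("plasma_ammonia", 250.0, 2),
    # damage / redox (absolute bands)
    ("protein_carbonyls", 1.0, 0), ("protein_carbonyls", 2.0, 1), ("protein_carbonyls", 3.0, 2),
]


@pytest.mark.parametrize("ind_id,value,expected", TABLE_CASES)
def test_printed_band_endpoints(registry, ind_id, value, expected):
    assert score_value(registry.lookup(ind_id), value) == expected


def test_life_stage_variant_dispatch(registry):
    """Juvenile total-protein bands shift down: 5.5 g/dl separates the
    stages (adult-normal, juvenile-mild)."""
    defn = registry.lookup("total_proteins")
    assert score_value(defn, 5.5, life_stage="adult") == 0
    assert score_value(defn, 5.5, life_stage="juvenile") == 1
    assert score_value(defn, 2.3, life_stage="juvenile") == 1
    assert score_value(defn, 2.3, life_stage="adult") == 2  # below the adult mild band


def test_juvenile_triglycerides_run_higher(registry):
    defn = registry.lookup("triglycerides")
    assert score_value(defn, 380.0, life_stage="adult") == 2
    assert score_value(defn, 380.0, life_stage="juvenile") == 0


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def test_fold_change_ratio_bands(registry):
    defn = registry.lookup("alt_ast_ldh")
    assert score_fold_change(defn, 60.0, 40.0) == 1   # ratio 1.5
    assert score_fold_change(defn, 80.0, 40.0) == 2   # ratio 2.0 exactly
    assert score_fold_change(defn, 40.0, 40.0) == 0   # identity ratio
    assert score_fold_change(defn, 30.0, 40.0) == 0   # below reference


def test_fold_change_requires_positive_reference(registry):
    defn = registry.lookup("alt_ast_ldh")
    with pytest.raises(ScoringError):
        score_fold_change(defn, 60.0, 0.0)


def test_fold_change_value_in_printed_range_is_normal(registry):
    # ALT 35 U/L is above the default (midpoint, 22.5 U/L) reference but
    # inside the printed 5-40 U/L operational range, hence normal; 42 is
    # out of range at 1.9x the reference (mild); 50 reaches 2.2x (severe)
    assert score_value(registry.lookup("alt_ast_ldh"), 35.0) == 0
    assert score_value(registry.lookup("alt_ast_ldh"), 42.0) == 1
    assert score_value(registry.lookup("alt_ast_ldh"), 50.0) == 2


def test_symmetric_fold_change_flags_exhaustion(registry):
    """Antioxidant enzymes score severe for a >=2x change in either
    direction (marked induction or exhaustion)."""
    defn = registry.lookup("sod_cat_gpx")
    assert score_fold_change(defn, 100.0, 100.0) == 0
    assert score_fold_change(defn, 160.0, 100.0) == 1
    assert score_fold_change(defn, 250.0, 100.0) == 2
    assert score_fold_change(defn, 40.0, 100.0) == 2   # halved or worse


# ---------------------------------------------------------------------------
# condition factor
# ---------------------------------------------------------------------------

def test_fulton_k_hand_arithmetic():
    assert fulton_k(50.0, 15.0) == pytest.approx(100 * 50 / 3375)


def test_fulton_k_scaling_laws():
    k0 = fulton_k(40.0, 12.0)
    assert fulton_k(80.0, 12.0) == pytest.approx(2 * k0)      # linear in weight
    assert fulton_k(40.0, 24.0) == pytest.approx(k0 / 8)       # cubic in length


def test_fulton_k_rejects_nonpositive():
    with pytest.raises(ScoringError):
        fulton_k(0.0, 10.0)
    with pytest.raises(ScoringError):
        fulton_k(10.0, -1.0)


@pytest.mark.parametrize("factor,expected", [
    (1.0, 0), (1.10, 0), (1.15, 1), (0.85, 1), (1.20, 2), (0.78, 2),
])
def test_condition_factor_deviation_bands(factor, expected):
    """+/-10% of the batch mean is normal (boundary benign), 10-20% mild,
    >=20% severe as printed."""
    assert score_condition_factor(1.5 * factor, 1.5) == expected


def test_condition_factor_requires_positive_mean():
    with pytest.raises(ScoringError):
        score_condition_factor(1.5, 0.0)


# ---------------------------------------------------------------------------
# baseline-relative and electrolyte panel
# ---------------------------------------------------------------------------

def test_baseline_relative_default_thresholds(registry):
    defn = registry.lookup("respiratory_rate")
    assert score_baseline_relative(defn, 88.0, 80.0) == 0   # +10%
    assert score_baseline_relative(defn, 110.0, 80.0) == 1  # +37.5%
    assert score_baseline_relative(defn, 130.0, 80.0) == 2  # +62.5%
    with pytest.raises(ScoringError):
        score_value(defn, 90.0)  # baseline context is mandatory


def test_electrolyte_panel_rules(registry):
    defn = registry.lookup("electrolytes_osmolality")
    assert score_electrolyte_panel(defn, {"osmolality": 300, "na": 145}) == 0
    # one analyte 15% beyond its range bound -> mild
    assert score_electrolyte_panel(defn, {"osmolality": 270 * 0.87}) == 1
    # >20% deviation -> severe
    assert score_electrolyte_panel(defn, {"na": 160 * 1.25}) == 2
    # two analytes out of range -> severe even if each deviation is small
    assert score_electrolyte_panel(defn, {"na": 125.0, "k": 6.5}) == 2
    # small (<10%) excursion beyond the range stays benign
    assert score_electrolyte_panel(defn, {"cl": 145.0}) == 0
    with pytest.raises(ScoringError):
        score_electrolyte_panel(defn, {"calcium": 2.0})


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def test_ordinal_measurement_passthrough(registry):
    m = Measurement("p", "f1", "fin_integrity", pi=2)
    assert score_measurement(registry.lookup("fin_integrity"), m) == 2
    with pytest.raises(ScoringError):
        Measurement("p", "f1", "fin_integrity", pi=3)


def test_unit_mismatch_is_an_error(registry):
    m = Measurement("p", "f1", "glucose", value=4.5, units="mmol/L")
    with pytest.raises(ScoringError, match="unit mismatch"):
        score_measurement(registry.lookup("glucose"), m)


def test_condition_factor_from_weight_and_length(registry):
    defn = registry.lookup("body_condition")
    m = Measurement("p", "f1", "body_condition", weight_g=50.0, length_cm=15.0)
    k = fulton_k(50.0, 15.0)
    assert score_measurement(defn, m, ScoreContext(k_mu=k)) == 0
    assert score_measurement(defn, m, ScoreContext(k_mu=k / 0.78)) == 2


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def test_cluster_examples():
    assert compute_cluster([0, 0, 0, 0], "EIC").value == 0.0
    assert compute_cluster([0, 0, 0, 0], "EIC").interpretation is ClusterInterpretation.stable
    top = compute_cluster([2, 2, 2], "EIC")
    assert top.value == 2.0 and top.interpretation is ClusterInterpretation.consolidated_awe
    mixed = compute_cluster([2, 1, 1, 0, 2], "IIC")
    assert mixed.value == pytest.approx(1.2)
    assert mixed.interpretation is ClusterInterpretation.consolidated_awe
    assert mixed.n_indicators == 5


@pytest.mark.parametrize("value,interp", [
    (0.49, ClusterInterpretation.stable),
    (0.5, ClusterInterpretation.mild_moderate_risk),
    (1.19, ClusterInterpretation.mild_moderate_risk),
    (1.2, ClusterInterpretation.consolidated_awe),
])
def test_cluster_interpretation_bands(value, interp):
    # construct a weighted mean hitting the target exactly
    res = compute_cluster([0, 2], "IIC", weights=[2 - value, value])
    assert res.value == pytest.approx(value)
    assert res.interpretation is interp


def test_cluster_input_validation():
    with pytest.raises(ScoringError):
        compute_cluster([], "EIC")
    with pytest.raises(ScoringError):
        compute_cluster([0, 1], "EIC", weights=[1.0, -0.5])
    with pytest.raises(ScoringError):
        compute_cluster([0, 1], "EIC", weights=[0.0, 0.0])


def test_cluster_weights_normalized():
    res = compute_cluster([2, 0], "IIC", weights=[3.0, 1.0])
    assert res.value == pytest.approx(1.5)
    assert sum(res.weights) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# population and sentinel criteria
# ---------------------------------------------------------------------------

def test_population_criterion_strict_comparator(registry):
    defn = registry.lookup("scale_loss")  # >20% with Pi>=1
    pis = [1] * 13 + [0] * 47
    out = population_criterion(defn, pis)[0]
    assert out.observed_proportion == pytest.approx(13 / 60)
    assert out.triggered  # 21.7% > 20%
    out = population_criterion(defn, [1] * 12 + [0] * 48)[0]
    assert out.observed_proportion == pytest.approx(0.2)
    assert not out.triggered  # exactly 20% with a strict ">"


def test_population_criterion_nonstrict_comparator(registry):
    defn = registry.lookup("total_proteins")  # >=20%
    out = population_criterion(defn, [1] * 12 + [0] * 48)[0]
    assert out.triggered


def test_population_criterion_never_on_all_normal(registry):
    defn = registry.lookup("scale_loss")
    assert not any(t.triggered for t in population_criterion(defn, [0] * 30))
    with pytest.raises(ScoringError):
        population_criterion(defn, [])


def test_two_tier_population_rule(registry):
    """Damage/redox panel: alert for >25% at Pi>=1, critical for >=10% at Pi=2."""
    defn = registry.lookup("alt_ast_ldh")
    pis = [1] * 16 + [0] * 44  # 26.7% mild, no severe
    alert, critical = population_criterion(defn, pis)
    assert alert.triggered and not critical.triggered
    pis = [2] * 6 + [0] * 54  # 10% severe
    alert, critical = population_criterion(defn, pis)
    assert critical.triggered


def test_sentinel_two_fish_rule(registry):
    defn = registry.lookup("scale_loss")
    pis = {f"f{i}": 0 for i in range(58)} | {"s1": 2, "s2": 2}
    out = sentinel_awe(defn, pis)
    assert out.triggered and out.qualifying_fish == ("s1", "s2")


def test_sentinel_single_fish_below_threshold_flagged_for_followup(registry):
    defn = registry.lookup("scale_loss")
    pis = {f"f{i}": 0 for i in range(59)} | {"s1": 2}
    out = sentinel_awe(defn, pis)
    assert not out.triggered
    assert out.followup_fish == ("s1",)


def test_sentinel_single_fish_rule_for_enzymes(registry):
    defn = registry.lookup("alt_ast_ldh")
    out = sentinel_awe(defn, {"f0": 0, "f1": 2})
    assert out.triggered and out.qualifying_fish == ("f1",)


def test_sentinel_severe_extreme_gates_glucose(registry):
    """Glucose fish at Pi=2 only count as sentinel-grade beyond the stricter
    printed cut-offs (>150 or <30 mg/dl)."""
    defn = registry.lookup("glucose")
    pis = {"a": 2, "b": 2, "c": 0}
    raws = {"a": 120.0, "b": 130.0, "c": 60.0}  # Pi=2 but not sentinel-grade
    assert not sentinel_awe(defn, pis, raws).triggered
    raws = {"a": 160.0, "b": 155.0, "c": 60.0}
    out = sentinel_awe(defn, pis, raws)
    assert out.triggered and set(out.qualifying_fish) == {"a", "b"}


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------

def _ordinal_cohort(indicator, pis, pond="p1"):
    return [Measurement(pond, f"f{i:02d}", indicator, pi=p) for i, p in enumerate(pis)]


def test_all_zero_cohort_is_green(registry):
    a = evaluate_cohort(registry, _ordinal_cohort("fin_integrity", [0] * 20))
    assert not a.awe and a.triggers == []
    assert all(c["EIC"].value == 0 for c in a.fish_clusters.values())


def test_fin_sentinel_provenance(registry):
    pis = [0] * 58 + [2, 2]
    a = evaluate_cohort(registry, _ordinal_cohort("fin_integrity", pis))
    assert a.awe
    sentinels = [t for t in a.triggers if t.rule == "sentinel"]
    assert sentinels and sentinels[0].indicator_id == "fin_integrity"


def test_cluster_rule_sets_cohort_awe(registry):
    """A fish whose internal cluster reaches 1.2 consolidates an AWE; the
    cluster trigger is recorded in provenance alongside any Pi=2 trigger."""
    ms = []
    # fish f0 scores [1,1,1,1,2] across five internal indicators -> IIC 1.2
    values = {"hct": 22.0, "hb": 6.5, "wbc": 17000.0, "lymphocytes": 55.0, "glucose": 120.0}
    for ind, v in values.items():
        ms.append(Measurement("p1", "f0", ind, value=v))
        ms.append(Measurement("p1", "f1", ind, value={"hct": 30.0, "hb": 9.0, "wbc": 80000.0,
                                                      "lymphocytes": 70.0, "glucose": 60.0}[ind]))
    a = evaluate_cohort(registry, ms)
    iic = a.fish_clusters["f0"]["IIC"]
    assert iic.value == pytest.approx(1.2)
    assert iic.interpretation is ClusterInterpretation.consolidated_awe
    assert any(t.rule == "cluster" and t.fish_id == "f0" for t in a.triggers)
    assert a.awe


def test_single_pi2_sets_cohort_awe_flag(registry):
    """Any fish at Pi=2 flags the cohort (the aggregate AWE definition),
    even when the indicator's own sentinel rule needs two fish; provenance
    disambiguates the two signals."""
    a = evaluate_cohort(registry, _ordinal_cohort("fin_integrity", [0] * 59 + [2]))
    assert a.awe
    assert not a.indicators["fin_integrity"].sentinel.triggered
    assert any(t.rule == "indicator_pi2" for t in a.triggers)


def test_unresolvable_indicator_lists_offenders(registry):
    ms = [Measurement("p1", "f0", "not_an_indicator", pi=0)]
    with pytest.raises(ScoringError, match="not_an_indicator"):
        evaluate_cohort(registry, ms)


def test_partially_scored_fish_reduce_cluster_n(registry):
    ms = [
        Measurement("p1", "f0", "hct", value=30.0),
        Measurement("p1", "f0", "glucose", value=60.0),
        Measurement("p1", "f1", "hct", value=30.0),
    ]
    a = evaluate_cohort(registry, ms)
    assert a.fish_clusters["f0"]["IIC"].n_indicators == 2
    assert a.fish_clusters["f1"]["IIC"].n_indicators == 1


def test_batch_mean_k_used_when_no_context(registry):
    # ten fish at K=1.5, one emaciated at K=1.05 (30% below the batch mean)
    ms = [Measurement("p1", f"f{i}", "body_condition", value=1.5) for i in range(10)]
    ms.append(Measurement("p1", "thin", "body_condition", value=1.02))
    a = evaluate_cohort(registry, ms)
    assert a.indicators["body_condition"].pis["thin"] == 2
    assert all(p == 0 for f, p in a.indicators["body_condition"].pis.items() if f != "thin")


def test_electrolyte_panel_rows_combined(registry):
    ms = [
        Measurement("p1", "f0", "electrolytes_osmolality", value=300.0, analyte="osmolality"),
        Measurement("p1", "f0", "electrolytes_osmolality", value=125.0, analyte="na"),
        Measurement("p1", "f0", "electrolytes_osmolality", value=6.5, analyte="k"),
    ]
    a = evaluate_cohort(registry, ms)
    assert a.indicators["electrolytes_osmolality"].pis["f0"] == 2  # two analytes out


def test_evaluate_measurements_groups_by_pond_and_date(registry):
    ms = (_ordinal_cohort("fin_integrity", [0, 1], pond="A")
          + _ordinal_cohort("fin_integrity", [2, 2], pond="B"))
    out = evaluate_measurements(registry, ms)
    assert [a.pond_id for a in out] == ["A", "B"]
    assert not out[0].awe and out[1].awe


def test_longitudinal_repeated_detection_and_trend(registry):
    d1, d2 = date(2026, 1, 1), date(2026, 2, 1)
    def batch(day, values):
        return [Measurement("p1", f"f{i}", "alt_ast_ldh", value=v, date=day)
                for i, v in enumerate(values)]
    a1 = evaluate_cohort(registry, batch(d1, [30.0, 42.0]))
    a2 = evaluate_cohort(registry, batch(d2, [35.0, 44.0]))
    flags = longitudinal_flags([a1, a2])
    assert flags["alt_ast_ldh"]["rising_trend"]
    assert not flags["alt_ast_ldh"]["repeated_detection"]  # no Pi=2 yet
    a3 = evaluate_cohort(registry, batch(date(2026, 3, 1), [35.0, 120.0]))
    a4 = evaluate_cohort(registry, batch(date(2026, 4, 1), [35.0, 130.0]))
    assert longitudinal_flags([a3, a4])["alt_ast_ldh"]["repeated_detection"]


def test_measurement_csv_round_trip(registry, tmp_path):
    ms = [
        Measurement("p1", "f0", "hct", value=30.0, units="%", date=date(2026, 5, 1)),
        Measurement("p1", "f1", "fin_integrity", pi=1, date=date(2026, 5, 1)),
    ]
    path = tmp_path / "m.csv"
    measurements_to_frame(ms).to_csv(path, index=False)
    back = read_measurements_csv(path)
    assert [(m.fish_id, m.indicator_id, m.value, m.pi) for m in back] == [
        ("f0", "hct", 30.0, None), ("f1", "fin_integrity", None, 1)]
    a = evaluate_cohort(registry, back)
    assert a.sample_size == 2
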