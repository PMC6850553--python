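"""Generator determinism, marginal calibration, and exposure planting."""

from dataclasses import replace
from datetime import date

import numpy as np
import pytest

from gencompete.cohort import apply_eligibility_cascade, attach_monographs
from gencompete.errors import ConfigError
from gencompete.io import write_monographs_csv, write_products_orange_book
from gencompete.markets import add_covariates, build_markets
from gencompete.recovery import cohort_pipeline
from gencompete.simulate import SimulationConfig, make_attrition_fixture, simulate_cohort


def _write_all(sim, d):
    write_products_orange_book(sim.products, d / "products.txt")
    write_monographs_csv(sim.monographs, d / "monographs.csv")
    sim.sales.to_csv(d / "sales.csv", index=False)


def test_same_seed_byte_identical_files(tmp_path):
    cfg = SimulationConfig(n_drugs=120, n_classes=8, seed=5)
    a, b = tmp_path / "a", tmp_path / "b"
    a.mkdir(), b.mkdir()
    _write_all(simulate_cohort(cfg), a)
    _write_all(simulate_cohort(cfg), b)
    for name in ("products.txt", "monographs.csv", "sales.csv"):
        assert (a / name).read_bytes() == (b / name).read_bytes()


def test_different_seed_differs(tmp_path):
    s1 = simulate_cohort(SimulationConfig(n_drugs=120, n_classes=8, seed=5))
    s2 = simulate_cohort(SimulationConfig(n_drugs=120, n_classes=8, seed=6))
    assert s1.truth["planted_counts"] != s2.truth["planted_counts"]


@pytest.mark.parametrize(
    "bad",
    [
        {"monograph_product_prev": 1.4},
        {"true_irr_count": -1.0},
        {"n_classes": 0},
        {"censor_date": date(1970, 1, 1)},
        {"outcome_model": "bogus"},
        {"exposure_timing": "sometime"},
        {"timeline_model": "wishful"},
        {"count_dispersion": -0.1},
    ],
)
def test_config_validation(bad):
    with pytest.raises(ConfigError):
        simulate_cohort(SimulationConfig(**bad))


def test_marginals_match_config_at_large_n():
    cfg = SimulationConfig(n_drugs=10_000, n_classes=40, seed=3)
    sim = simulate_cohort(cfg)
    t = sim.truth
    assert t["product_monograph_prevalence"] == pytest.approx(0.403, abs=0.02)
    assert t["substance_monograph_prevalence"] == pytest.approx(0.749, abs=0.015)
    assert t["exposure_prevalence"] == pytest.approx(0.403 * 0.51, abs=0.015)
    routes = [p.route for p in sim.products if p.application_type == "NDA"]
    assert np.mean([r == "ORAL" for r in routes]) == pytest.approx(553 / 982, abs=0.02)


def test_null_effect_means_balance():
    cfg = SimulationConfig(
        n_drugs=20_000, n_classes=40, seed=9, true_irr_count=1.0,
        class_effect_sd=0.0, covariate_effects=False,
    )
    t = simulate_cohort(cfg).truth
    ratio = t["mean_count_exposed"] / t["mean_count_unexposed"]
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_marginal_ratio_matches_configured_irr_without_covariates():
    # calibration check: exposed/unexposed mean ratio 7.2/1.7 at large n
    cfg = SimulationConfig(
        n_drugs=20_000, n_classes=40, seed=13, true_irr_count=7.2 / 1.7,
        class_effect_sd=0.0, covariate_effects=False,
    )
    t = simulate_cohort(cfg).truth
    ratio = t["mean_count_exposed"] / t["mean_count_unexposed"]
    assert ratio == pytest.approx(7.2 / 1.7, rel=0.05)


@pytest.mark.parametrize("timing", ["before_first", "before_second"])
def test_pipeline_recovers_planted_exposure_exactly(timing):
    cfg = SimulationConfig(n_drugs=400, n_classes=12, seed=21, exposure_timing=timing)
    sim = simulate_cohort(cfg)
    markets, _ = cohort_pipeline(sim)
    assert len(markets) == 400  # generator emits an already-eligible cohort
    derived = (
        markets.sort_values("ingredient")[f"exp_{timing}"].to_numpy().astype(int)
    )
    assert (derived == np.array(sim.truth["planted_exposure"])).all()


def test_logistic_mode_counts_consistent_with_indicator():
    cfg = SimulationConfig(n_drugs=2000, n_classes=20, seed=2, outcome_model="logistic")
    sim = simulate_cohort(cfg)
    counts = np.array(sim.truth["planted_counts"])
    markets, _ = cohort_pipeline(sim)
    assert set(markets.loc[markets["any_generic"] == 0, "n_generics"]) <= {0}
    assert (counts >= 0).all()


def test_gap_hazard_mode_third_entry_nearly_universal():
    cfg = SimulationConfig(n_drugs=1500, n_classes=20, seed=4, timeline_model="gap_hazard")
    markets, _ = cohort_pipeline(simulate_cohort(cfg))
    sub = markets.loc[markets["n_generics"] >= 2]
    # hazard-driven third entry with years of follow-up: few censored
    assert (sub["n_generics"] >= 3).mean() > 0.9


# ---------------------------------------------------------------------------
# attrition fixture
# ---------------------------------------------------------------------------

PLAN = {
    "pre_1982": 3,
    "no_sales_match": 2,
    "otc_or_discontinued": 1,
}


def _run_cascade(fix):
    markets = build_markets(fix.products, sales=fix.sales)
    markets = attach_monographs(markets, fix.monographs)
    return apply_eligibility_cascade(markets)


def test_attrition_fixture_reproduces_plan():
    fix = make_attrition_fixture(PLAN, n_eligible=4)
    cohort, ledger = _run_cascade(fix)
    counts = dict(zip(ledger.to_frame()["filter_name"], ledger.to_frame()["n_removed"]))
    for name, n in PLAN.items():
        assert counts[name] == n
    assert sum(counts.values()) == 6
    assert len(cohort) == 4


def test_attrition_fixture_every_filter():
    plan = {f: 1 for f in
            ("pre_1982", "generic_or_loe_before_cutoff", "monograph_before_nda",
             "under_patent", "no_sales_match", "no_therapeutic_class",
             "otc_or_discontinued")}
    fix = make_attrition_fixture(plan, n_eligible=2)
    cohort, ledger = _run_cascade(fix)
    counts = dict(zip(ledger.to_frame()["filter_name"], ledger.to_frame()["n_removed"]))
    assert counts == plan
    assert len(cohort) == 2


def test_attrition_fixture_overlapping_first_failure():
    plan = {"pre_1982": 2, "under_patent": 1}
    fix = make_attrition_fixture(plan, n_eligible=3, overlapping=True)
    cohort, ledger = _run_cascade(fix)
    counts = dict(zip(ledger.to_frame()["filter_name"], ledger.to_frame()["n_removed"]))
    assert counts["pre_1982"] == 2
    assert counts["under_patent"] == 1
    assert counts["otc_or_discontinued"] == 0  # overlap never double-counted
    assert len(cohort) == 3


def test_attrition_fixture_empty_plan():
    fix = make_attrition_fixture({}, n_eligible=0)
    assert fix.products == []


def test_attrition_fixture_unknown_filter():
    with pytest.raises(ConfigError):
        make_attrition_fixture({"not_a_filter": 1})
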