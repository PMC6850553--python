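"""Counterfactual savings engine vs hand arithmetic and invariants."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gencompete.errors import ValidationError
from gencompete.savings import (
    PriceCompetitionCurve,
    compute_savings,
    predict_manufacturers,
    predicted_price,
    relative_price,
)

CURVE = PriceCompetitionCurve(((0, 1.0), (1, 0.8), (2, 0.5)))


# ---------------------------------------------------------------------------
# curve
# ---------------------------------------------------------------------------


def test_curve_validation_errors():
    with pytest.raises(ValidationError):
        PriceCompetitionCurve(((1, 0.8),))  # must start at 0
    with pytest.raises(ValidationError):
        PriceCompetitionCurve(((0, 0.9),))  # D(0) must be 1
    with pytest.raises(ValidationError):
        PriceCompetitionCurve(((0, 1.0), (1, 1.2)))  # price > 1
    with pytest.raises(ValidationError):
        PriceCompetitionCurve(((0, 1.0), (1, 0.5), (2, 0.7)))  # increasing
    with pytest.raises(ValidationError):
        PriceCompetitionCurve(((0, 1.0), (0, 0.9)))  # non-increasing n


def test_relative_price_knots_interpolation_extrapolation():
    assert relative_price(CURVE, 0) == 1.0
    assert relative_price(CURVE, 1) == 0.8
    assert relative_price(CURVE, 1.5) == pytest.approx(0.65)
    assert relative_price(CURVE, 7) == 0.5  # constant beyond last knot
    with pytest.raises(ValidationError):
        relative_price(CURVE, -1)


def test_curve_csv_round_trip(tmp_path):
    p = tmp_path / "curve.csv"
    CURVE.to_csv(p)
    assert PriceCompetitionCurve.from_csv(p).points == CURVE.points


# ---------------------------------------------------------------------------
# Eq-level operations
# ---------------------------------------------------------------------------


def test_predict_manufacturers():
    assert predict_manufacturers(3, 1.5) == pytest.approx(2.0)
    for k in range(5):
        assert predict_manufacturers(k, 1.0) == k
    assert predict_manufacturers(0, 2.7) == 0
    with pytest.raises(ValidationError):
        predict_manufacturers(3, 0.0)


def test_predicted_price():
    assert predicted_price(10.0, CURVE, 2, 1) == pytest.approx(16.0)
    assert predicted_price(10.0, CURVE, 2, 2) == pytest.approx(10.0)
    flat = PriceCompetitionCurve(((0, 1.0), (5, 1.0)))
    assert predicted_price(10.0, flat, 4, 0.5) == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# compute_savings
# ---------------------------------------------------------------------------


def _one_market(n_generics=2, exposed=1):
    dates = [date(2004 + j, 6, 1) for j in range(n_generics)]
    return pd.DataFrame(
        [
            {
                "ingredient": "A",
                "route": "ORAL",
                "generic_approval_dates": dates,
                "n_generics": n_generics,
                "exp_before_first": exposed,
            }
        ]
    )


def _panel(dollars=10.0 * 1000, volume=1000.0, years=(2015,)):
    return pd.DataFrame(
        [{"ingredient": "A", "route": "ORAL", "year": y, "dollars": dollars, "volume": volume}
         for y in years]
    )


def test_savings_hand_chain():
    # n_A=2, IRR=2 => n_P=1; P_A=10 => P_P=(0.8/0.5)*10=16; savings=(16-10)*1000
    rows, totals = compute_savings(_one_market(), _panel(), irr=2.0, curve=CURVE, years=[2015])
    assert rows["savings"].iloc[0] == pytest.approx(6000.0)
    assert totals["total_savings"].iloc[0] == pytest.approx(6000.0)
    assert totals["additional_manufacturers"].iloc[0] == 1
    assert rows["sales_predicted"].iloc[0] == pytest.approx(16000.0)


def test_savings_identity_at_irr_one():
    rows, totals = compute_savings(_one_market(), _panel(), irr=1.0, curve=CURVE, years=[2015])
    assert np.allclose(rows["savings"], 0.0)
    assert np.allclose(totals["total_savings"], 0.0)


def test_unexposed_market_contributes_nothing():
    rows, totals = compute_savings(
        _one_market(exposed=0), _panel(), irr=2.0, curve=CURVE, years=[2015]
    )
    assert len(rows) == 0
    assert totals["total_savings"].iloc[0] == 0.0


def test_zero_volume_row_flagged_and_skipped():
    rows, totals = compute_savings(
        _one_market(), _panel(dollars=5000.0, volume=0.0), irr=2.0, curve=CURVE, years=[2015]
    )
    assert (rows["flag"] == "zero_volume").all()
    assert totals["total_savings"].iloc[0] == 0.0


def test_savings_nonnegative_when_irr_ge_one():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(0, 6))
        irr = float(rng.uniform(1.0, 3.0))
        rows, _ = compute_savings(
            _one_market(n_generics=n), _panel(), irr=irr, curve=CURVE, years=[2015]
        )
        if len(rows):
            assert (rows["savings"] >= -1e-9).all()


@given(
    irr_lo=st.floats(min_value=1.0, max_value=5.0),
    irr_delta=st.floats(min_value=0.0, max_value=5.0),
    n=st.integers(min_value=0, max_value=8),
)
def test_savings_monotone_in_irr(irr_lo, irr_delta, n):
    market, panel = _one_market(n_generics=n), _panel()
    _, lo = compute_savings(market, panel, irr=irr_lo, curve=CURVE, years=[2015])
    _, hi = compute_savings(market, panel, irr=irr_lo + irr_delta, curve=CURVE, years=[2015])
    assert hi["total_savings"].iloc[0] >= lo["total_savings"].iloc[0] - 1e-9


def test_savings_additive_over_markets_and_years():
    m1 = _one_market(n_generics=2)
    m2 = _one_market(n_generics=4)
    m2["ingredient"] = "B"
    both = pd.concat([m1, m2], ignore_index=True)
    panel = pd.concat(
        [_panel(years=(2015, 2016)), _panel(years=(2015, 2016)).assign(ingredient="B")],
        ignore_index=True,
    )
    _, t_both = compute_savings(both, panel, irr=1.7, curve=CURVE, years=[2015, 2016])
    _, t1 = compute_savings(m1, panel, irr=1.7, curve=CURVE, years=[2015, 2016])
    _, t2 = compute_savings(m2, panel, irr=1.7, curve=CURVE, years=[2015, 2016])
    assert t_both["total_savings"].sum() == pytest.approx(
        t1["total_savings"].sum() + t2["total_savings"].sum()
    )


def test_straight_line_oracle_small_market_set(small_cohort):
    """Independent re-derivation of the whole chain on a few markets."""
    sim, markets, _ = small_cohort
    sub = markets.loc[markets["exp_before_first"] == 1].head(5)
    irr, year = 1.53, 2016
    rows, totals = compute_savings(sub, sim.sales, irr=irr,
                                   curve=PriceCompetitionCurve(CURVE.points), years=[year])
    panel = {
        (i, r, int(y)): (d, v)
        for i, r, y, d, v in zip(
            sim.sales["ingredient"], sim.sales["route"], sim.sales["year"],
            sim.sales["dollars"], sim.sales["volume"],
        )
    }
    expected_total = 0.0
    for _, m in sub.iterrows():
        dollars, volume = panel[(m["ingredient"], m["route"], year)]
        n_a = sum(1 for d in m["generic_approval_dates"] if d.year <= year)
        n_p = n_a / irr
        d_of = lambda x: float(np.interp(x, [0, 1, 2], [1.0, 0.8, 0.5]))
        p_a = dollars / volume
        p_p = d_of(n_p) / d_of(n_a) * p_a
        expected_total += p_p * volume - dollars
    assert totals["total_savings"].iloc[0] == pytest.approx(expected_total, rel=1e-9)
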