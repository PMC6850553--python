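"""Synthetic cohort generator with known ground truth.

Real inputs for this analysis (drug approval files, monograph directories,
proprietary sales panels) are not redistributable, so every stage of the
pipeline is exercised on generated tables that carry the statistical
structure the models assume:

* drugs nested in therapeutic classes of uneven size, with a shared
  class-level frailty on the linear-predictor scale;
* a drug-product monograph for ~40% of drugs and a substance monograph for
  ~75%, with roughly half of product monographs official before the first
  generic entrant;
* overdispersed generic-entrant counts (gamma–Poisson mixture) whose
  log-mean carries a multiplicative monograph effect plus covariate
  effects (substance monograph, market size, age, vintage, route);
* inter-entrant gap times exponential under proportional hazards, with the
  second-to-third gap scaled by the configured hazard ratio and
  administrative censoring at the study end;
* a drug-year price panel in which unit price declines with the number of
  generic competitors through a competition–price curve, with
  multiplicative log-normal noise.

Monograph official dates are placed so that the pipeline's exposure
computation reproduces the planted exposure indicator exactly; the truth
record stores every generating parameter.  NDA dates are drawn over
1982–2004 and first generic entry is forced after April 1998: later brand
approvals would typically still be patent-protected at the 2018 study end,
and the eligibility cascade excludes pre-1998 generic entry, so the
generator emits an already-eligible cohort.  The same seed yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import MonographRecord, ProductRecord
from .savings import ILLUSTRATIVE_CURVE, PriceCompetitionCurve, relative_price

STUDY_END_DEFAULT = date(2018, 4, 3)
_PANEL_START_GUARD = date(1998, 4, 1)  # first generic entry forced after this

#: Route mix of the study cohort (inhalation, intravenous, oral, topical, other).
ROUTE_MARGINS = {
    "INHALATION": 31 / 982,
    "INTRAVENOUS": 183 / 982,
    "ORAL": 553 / 982,
    "TOPICAL": 93 / 982,
    "OTHER": 122 / 982,
}

# Fixed covariate coefficients of the generating model (log scale).  The
# same structure feeds the count mean, the logistic linear predictor and
# (scaled) the exposure propensity, so adjusted fits are consequential.
_COUNT_COEFS = {
    "substance": 0.15,
    "z_market": 0.30,
    "age_per_year": 0.015,
    "vintage_per_rank": -0.01,
}
_ROUTE_EFFECTS = {
    "INHALATION": -0.30,
    "INTRAVENOUS": -0.10,
    "ORAL": 0.20,
    "TOPICAL": -0.10,
    "OTHER": 0.0,
}
# exposure propensity: oral drugs and large markets are more likely to have
# a monograph donated early (mild confounding by modelled covariates)
_EXPOSURE_COEFS = {"oral": 0.5, "z_market": 0.3}

_TIMING_K = {"before_first": 1, "before_second": 2, "before_third": 3}


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters; defaults are the study-cohort conditions."""

    n_drugs: int = 982
    n_classes: int = 30
    class_effect_sd: float = 0.3
    monograph_product_prev: float = 0.403
    monograph_substance_prev: float = 0.749
    frac_monograph_before_first: float = 0.51
    true_or_any_generic: float = 0.64
    true_irr_count: float = 1.53
    true_hr_gap23: float = 0.99
    baseline_count_mean: float = 1.7
    count_dispersion: float = 1.0
    gap_time_scale_days: float = 245.0
    censor_date: date = STUDY_END_DEFAULT
    price_curve: PriceCompetitionCurve = ILLUSTRATIVE_CURVE
    price_noise_sd: float = 0.1
    seed: int = 0
    # which process drives the primary outcome ("count": entrant count is
    # negative-binomial and any-generic is derived; "logistic": the
    # any-generic indicator is drawn from a logistic model at
    # true_or_any_generic and the count is drawn conditionally)
    outcome_model: str = "count"
    # which exposure timing the planted effect attaches to
    exposure_timing: str = "before_first"
    # "count_driven": the drawn negative-binomial count IS the entrant
    # count (entries placed to fit before the study end); "gap_hazard":
    # beyond the second entrant the timeline is hazard-driven — every
    # market with >= 2 entrants has an exponential time-to-third at
    # h0 * HR^exposure with administrative censoring, and later entrants
    # follow at baseline exponential gaps until the study end.  The count
    # truth holds in the first mode, the gap-time truth in the second;
    # a single process cannot pin both (the count would then be a
    # censoring-dependent functional of the hazards).
    timeline_model: str = "count_driven"
    # switch covariate effects off for marginal-calibration checks
    covariate_effects: bool = True
    nda_start: date = date(1982, 1, 1)
    nda_end: date = date(2004, 12, 31)
    panel_years: tuple = (1997, 2016)

    def validate(self) -> None:
        probs = {
            "monograph_product_prev": self.monograph_product_prev,
            "monograph_substance_prev": self.monograph_substance_prev,
            "frac_monograph_before_first": self.frac_monograph_before_first,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        for name in ("true_or_any_generic", "true_irr_count", "true_hr_gap23",
                     "baseline_count_mean", "gap_time_scale_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.class_effect_sd < 0 or self.count_dispersion < 0 or self.price_noise_sd < 0:
            raise ConfigError("standard deviations and dispersion must be >= 0")
        if self.n_drugs < 1 or self.n_classes < 1:
            raise ConfigError("n_drugs and n_classes must be >= 1")
        if self.censor_date <= self.nda_start:
            raise ConfigError("censor_date must fall after the earliest NDA date")
        if self.nda_end <= self.nda_start:
            raise ConfigError("nda_end must fall after nda_start")
        if self.outcome_model not in ("count", "logistic"):
            raise ConfigError(f"unknown outcome_model: {self.outcome_model!r}")
        if self.exposure_timing not in _TIMING_K:
            raise ConfigError(f"unknown exposure_timing: {self.exposure_timing!r}")
        if self.timeline_model not in ("count_driven", "gap_hazard"):
            raise ConfigError(f"unknown timeline_model: {self.timeline_model!r}")


@dataclass
class SimulatedCohort:
    """Generated tables plus the ground-truth record."""

    products: list  # list[ProductRecord]
    monographs: list  # list[MonographRecord]
    sales: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _days_between(a: date, b: date) -> int:
    return (b - a).days


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> SimulatedCohort:
    """Generate one synthetic cohort at the configured ground truth."""
    cfg = replace(config or SimulationConfig(), **overrides) if overrides else (
        config or SimulationConfig()
    )
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_drugs
    censor = cfg.censor_date

    # --- classes (uneven sizes) and frailty -------------------------------
    w = 0.88 ** np.arange(cfg.n_classes)
    w /= w.sum()
    class_id = rng.choice(cfg.n_classes, size=n, p=w)
    frailty = rng.normal(0.0, cfg.class_effect_sd, size=cfg.n_classes)

    # --- covariates --------------------------------------------------------
    routes = np.array(list(ROUTE_MARGINS))
    route = rng.choice(routes, size=n, p=np.array(list(ROUTE_MARGINS.values())))
    nda_span = _days_between(cfg.nda_start, cfg.nda_end)
    nda_offsets = rng.integers(0, nda_span + 1, size=n)
    nda_dates = np.array([cfg.nda_start + timedelta(days=int(d)) for d in nda_offsets])
    age = np.array([_days_between(d, censor) / 365.25 for d in nda_dates])
    log_size = rng.normal(math.log(3e7), 1.3, size=n)
    z_mkt = (log_size - math.log(3e7)) / 1.3
    substance = rng.random(n) < cfg.monograph_substance_prev
    vintage = (
        pd.Series(nda_offsets).groupby(pd.Series(class_id)).rank(method="min").to_numpy()
    )

    if cfg.covariate_effects:
        cov_lp = (
            _COUNT_COEFS["substance"] * substance
            + _COUNT_COEFS["z_market"] * z_mkt
            + _COUNT_COEFS["age_per_year"] * age
            + _COUNT_COEFS["vintage_per_rank"] * vintage
            + np.array([_ROUTE_EFFECTS[r] for r in route])
        )
        cov_lp = cov_lp - cov_lp.mean()
    else:
        cov_lp = np.zeros(n)

    # --- planted exposure ---------------------------------------------------
    p_base = cfg.monograph_product_prev * cfg.frac_monograph_before_first
    lp_e = np.full(n, _logit(p_base) if 0 < p_base < 1 else -np.inf)
    if cfg.covariate_effects and 0 < p_base < 1:
        lp_e = lp_e + _EXPOSURE_COEFS["oral"] * (
            (route == "ORAL") - ROUTE_MARGINS["ORAL"]
        ) + _EXPOSURE_COEFS["z_market"] * z_mkt
    exposed = rng.random(n) < _expit(lp_e) if p_base > 0 else np.zeros(n, bool)

    # --- outcome: generic-entrant count ------------------------------------
    b = frailty[class_id]
    if cfg.outcome_model == "count":
        eta = (
            math.log(cfg.baseline_count_mean)
            - cfg.class_effect_sd**2 / 2.0
            + b
            + math.log(cfg.true_irr_count) * exposed
            + cov_lp
        )
        mu = np.exp(eta)
        if cfg.count_dispersion > 0:
            lam = rng.gamma(1.0 / cfg.count_dispersion, cfg.count_dispersion * mu)
        else:
            lam = mu
        counts = rng.poisson(lam)
        any_generic = counts >= 1
    else:  # logistic
        lp_y = (
            _logit(0.55)
            + b
            + math.log(cfg.true_or_any_generic) * exposed
            + cov_lp
        )
        any_generic = rng.random(n) < _expit(lp_y)
        extra = rng.poisson(cfg.baseline_count_mean, size=n)
        counts = np.where(any_generic, 1 + extra, 0)

    # --- entrant timelines --------------------------------------------------
    # first entry: uniform 3-10 y after NDA, pushed past April 1998; later
    # entrants at exponential gaps, the 2nd-to-3rd gap under the configured
    # hazard ratio for planted-exposed drugs; entries past the study end are
    # administratively unobserved.
    entrant_dates: list[list[date]] = []
    hr = cfg.true_hr_gap23
    u_first = rng.uniform(0.0, 7.0, size=n)
    for i in range(n):
        k = int(counts[i])
        if k == 0:
            entrant_dates.append([])
            continue
        lo = max(3.0, _days_between(nda_dates[i], _PANEL_START_GUARD) / 365.25)
        t = nda_dates[i] + timedelta(days=int(round((lo + u_first[i]) * 365.25)))
        dates = [t]
        if cfg.timeline_model == "count_driven" or k < 2:
            for j in range(2, k + 1):
                scale = cfg.gap_time_scale_days
                if j == 3 and exposed[i]:
                    scale = scale / hr  # hazard h0*hr => mean gap scale/hr
                gap = rng.exponential(scale)
                t = t + timedelta(days=max(int(round(gap)), 1))
                dates.append(t)
        else:  # gap_hazard: hazard-driven entry beyond the second entrant
            t = t + timedelta(days=max(int(round(rng.exponential(cfg.gap_time_scale_days))), 1))
            dates.append(t)
            j = 3
            while t <= censor:
                scale = cfg.gap_time_scale_days
                if j == 3 and exposed[i]:
                    scale = scale / hr
                t = t + timedelta(days=max(int(round(rng.exponential(scale))), 1))
                if t > censor:
                    break
                dates.append(t)
                j += 1
        entrant_dates.append([d for d in dates if d <= censor])
    observed_counts = np.array([len(d) for d in entrant_dates])

    # --- monograph placement -----------------------------------------------
    # exposed: official date strictly before the k-th entrant (or before the
    # study end when fewer than k entrants exist); unexposed: after the last
    # observed entrant when that keeps the exposure indicator false, else no
    # monograph at all.
    k_timing = _TIMING_K[cfg.exposure_timing]
    u_mono = rng.uniform(0.05, 0.95, size=n)
    u_elig = rng.random(n)
    eligible_unexposed = (~exposed) & (observed_counts >= k_timing)
    n_needed = cfg.monograph_product_prev * n - exposed.sum()
    q = float(np.clip(n_needed / max(eligible_unexposed.sum(), 1), 0.0, 1.0))
    product_mono: list[date | None] = []
    for i in range(n):
        if exposed[i]:
            anchor = (
                entrant_dates[i][k_timing - 1]
                if observed_counts[i] >= k_timing
                else censor
            )
            span = _days_between(nda_dates[i], anchor)
            d = nda_dates[i] + timedelta(days=max(int(u_mono[i] * span), 1))
            if d >= anchor:
                d = anchor - timedelta(days=1)
            product_mono.append(d)
        elif eligible_unexposed[i] and u_elig[i] < q:
            last = entrant_dates[i][-1]
            span = max(_days_between(last, censor), 2)
            d = last + timedelta(days=max(int(u_mono[i] * span), 1))
            if d >= censor:
                d = censor - timedelta(days=1)
            product_mono.append(d)
        else:
            product_mono.append(None)

    u_subst = rng.uniform(-10.0, 5.0, size=n)
    substance_mono = [
        min(
            nda_dates[i] + timedelta(days=int(u_subst[i] * 365.25)),
            censor - timedelta(days=1),
        )
        if substance[i]
        else None
        for i in range(n)
    ]

    # --- loss of exclusivity for never-generic drugs ------------------------
    u_loe = rng.random(n)
    loe_dates: list[date | None] = []
    for i in range(n):
        if observed_counts[i] > 0:
            loe_dates.append(None)
            continue
        lo = max(8.0, _days_between(nda_dates[i], _PANEL_START_GUARD) / 365.25)
        hi = min(lo + 6.0, _days_between(nda_dates[i], date(2017, 6, 30)) / 365.25)
        hi = max(hi, lo + 0.1)
        loe_dates.append(
            nda_dates[i] + timedelta(days=int((lo + u_loe[i] * (hi - lo)) * 365.25))
        )

    # --- sales panel ---------------------------------------------------------
    y0, y1 = cfg.panel_years
    years = np.arange(y0, y1 + 1)
    base_price = np.exp(rng.normal(math.log(150.0), 0.5, size=n))
    base_volume = np.exp(log_size) / base_price
    price_noise = rng.normal(0.0, cfg.price_noise_sd, size=(n, len(years)))
    volume_noise = rng.normal(0.0, 0.15, size=(n, len(years)))
    sales_rows = []
    ingredients = [f"DRUG{i:04d}" for i in range(n)]
    for i in range(n):
        for jy, year in enumerate(years):
            n_comp = sum(1 for d in entrant_dates[i] if d.year <= year)
            price = base_price[i] * relative_price(cfg.price_curve, n_comp) * math.exp(
                price_noise[i, jy]
            )
            volume = base_volume[i] * math.exp(volume_noise[i, jy])
            sales_rows.append(
                (ingredients[i], route[i], int(year), price * volume, volume)
            )
    sales = pd.DataFrame(
        sales_rows, columns=["ingredient", "route", "year", "dollars", "volume"]
    )

    # --- assemble record tables ----------------------------------------------
    products: list[ProductRecord] = []
    monographs: list[MonographRecord] = []
    for i in range(n):
        cls = f"C{class_id[i]:02d}"
        products.append(
            ProductRecord(
                ingredient=ingredients[i],
                route=route[i],
                dosage_form="FORM",
                trade_name=f"BRAND{i:04d}",
                applicant=f"INNOVATOR{i:04d}",
                application_type="NDA",
                application_number=f"N{200000 + i}",
                approval_date=nda_dates[i],
                otc_flag=False,
                discontinued_flag=False,
                therapeutic_class=cls,
                loe_date=loe_dates[i],
            )
        )
        for j, d in enumerate(entrant_dates[i]):
            products.append(
                ProductRecord(
                    ingredient=ingredients[i],
                    route=route[i],
                    dosage_form="FORM",
                    trade_name=f"GEN{i:04d}X{j}",
                    applicant=f"GENERICCO{i:04d}N{j:02d}",
                    application_type="ANDA",
                    application_number=f"A{700000 + 100 * i + j}",
                    approval_date=d,
                    otc_flag=False,
                    discontinued_flag=False,
                    therapeutic_class=cls,
                )
            )
        if product_mono[i] is not None:
            monographs.append(
                MonographRecord(
                    ingredient=ingredients[i],
                    route=route[i],
                    monograph_type="product",
                    official_date=product_mono[i],
                )
            )
        if substance_mono[i] is not None:
            monographs.append(
                MonographRecord(
                    ingredient=ingredients[i],
                    route=None,
                    monograph_type="substance",
                    official_date=substance_mono[i],
                )
            )

    truth = {
        "seed": cfg.seed,
        "n_drugs": n,
        "n_classes": cfg.n_classes,
        "outcome_model": cfg.outcome_model,
        "exposure_timing": cfg.exposure_timing,
        "timeline_model": cfg.timeline_model,
        "true_irr_count": cfg.true_irr_count,
        "true_or_any_generic": cfg.true_or_any_generic,
        "true_hr_gap23": cfg.true_hr_gap23,
        "class_effect_sd": cfg.class_effect_sd,
        "count_dispersion": cfg.count_dispersion,
        "baseline_count_mean": cfg.baseline_count_mean,
        "gap_time_scale_days": cfg.gap_time_scale_days,
        "censor_date": censor.isoformat(),
        "covariate_coefs": dict(_COUNT_COEFS) if cfg.covariate_effects else {},
        "route_effects": dict(_ROUTE_EFFECTS) if cfg.covariate_effects else {},
        "n_exposed": int(exposed.sum()),
        "exposure_prevalence": float(exposed.mean()),
        "product_monograph_prevalence": float(
            np.mean([d is not None for d in product_mono])
        ),
        "substance_monograph_prevalence": float(substance.mean()),
        "mean_count_exposed": float(counts[exposed].mean()) if exposed.any() else float("nan"),
        "mean_count_unexposed": float(counts[~exposed].mean()) if (~exposed).any() else float("nan"),
        "unexposed_monograph_draw_prob": q,
        "planted_exposure": exposed.astype(int).tolist(),
        "planted_counts": counts.astype(int).tolist(),
    }
    return SimulatedCohort(products=products, monographs=monographs, sales=sales, truth=truth)


# ---------------------------------------------------------------------------
# Attrition fixture
# ---------------------------------------------------------------------------

_FIXTURE_FILTERS = (
    "pre_1982",
    "generic_or_loe_before_cutoff",
    "monograph_before_nda",
    "under_patent",
    "no_sales_match",
    "no_therapeutic_class",
    "otc_or_discontinued",
)


def make_attrition_fixture(
    plan: dict[str, int] | None = None,
    n_eligible: int = 4,
    overlapping: bool = False,
) -> SimulatedCohort:
    """Products/monographs/sales engineered to exercise every cascade filter.

    ``plan`` maps filter names to the number of markets planted to fail at
    exactly that step; ``n_eligible`` markets survive the whole cascade.
    With ``overlapping=True`` each planted market additionally violates a
    *later* filter, so first-failure attribution is what keeps the counts
    on plan.  The returned truth record stores the plan.
    """
    plan = dict(plan or {})
    unknown = set(plan) - set(_FIXTURE_FILTERS)
    if unknown:
        raise ConfigError(f"plan references unknown filters: {sorted(unknown)}")
    products: list[ProductRecord] = []
    monographs: list[MonographRecord] = []
    sales_rows = []
    idx = 0

    def base_kwargs(ing):
        return dict(
            ingredient=ing,
            route="ORAL",
            dosage_form="TABLET",
            trade_name=f"T{ing}",
            applicant=f"BRAND_{ing}",
            application_type="NDA",
            application_number=f"N{100000 + idx}",
            approval_date=date(2000, 6, 15),
            otc_flag=False,
            discontinued_flag=False,
            therapeutic_class="C00",
        )

    def add_generic(ing, when=date(2005, 3, 1), cls="C00"):
        products.append(
            ProductRecord(
                ingredient=ing,
                route="ORAL",
                dosage_form="TABLET",
                trade_name=f"G{ing}",
                applicant=f"GEN_{ing}",
                application_type="ANDA",
                application_number=f"A{900000 + idx}",
                approval_date=when,
                otc_flag=False,
                discontinued_flag=False,
                therapeutic_class=cls,
            )
        )

    def add_sales(ing, year=2004):
        sales_rows.append((ing, "ORAL", year, 1.0e7, 1.0e5))

    for filt in _FIXTURE_FILTERS:
        for _ in range(plan.get(filt, 0)):
            ing = f"BAD{idx:03d}"
            kw = base_kwargs(ing)
            if filt == "pre_1982":
                kw["approval_date"] = None
                kw["approved_pre_1982"] = True
            elif filt == "under_patent":
                kw["under_patent_flag"] = True
            elif filt == "no_therapeutic_class":
                kw["therapeutic_class"] = None
            elif filt == "otc_or_discontinued":
                kw["otc_flag"] = True
            products.append(ProductRecord(**kw))
            cls = None if filt == "no_therapeutic_class" else "C00"
            if filt == "generic_or_loe_before_cutoff":
                add_generic(ing, date(1996, 5, 1), cls=cls)
            else:
                add_generic(ing, cls=cls)
            if filt == "monograph_before_nda":
                monographs.append(
                    MonographRecord(ing, "ORAL", "product", date(1999, 1, 1))
                )
            if filt != "no_sales_match":
                add_sales(ing)
                if filt == "generic_or_loe_before_cutoff":
                    add_sales(ing, 1995)
            if overlapping and filt != "otc_or_discontinued":
                # additionally violate the LAST filter; sequential
                # first-failure attribution must still charge this market
                # to `filt`
                for pi in range(len(products) - 1, -1, -1):
                    p = products[pi]
                    if p.ingredient == ing and p.application_type == "NDA":
                        products[pi] = dataclasses.replace(p, discontinued_flag=True)
                        break
            idx += 1

    for _ in range(n_eligible):
        ing = f"GOOD{idx:03d}"
        products.append(ProductRecord(**base_kwargs(ing)))
        add_generic(ing)
        add_sales(ing)
        idx += 1

    sales = pd.DataFrame(
        sales_rows, columns=["ingredient", "route", "year", "dollars", "volume"]
    )
    truth = {"plan": plan, "n_eligible": n_eligible, "overlapping": overlapping}
    return SimulatedCohort(products=products, monographs=monographs, sales=sales, truth=truth)
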