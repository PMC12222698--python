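"""Deterministic inhalation health risk: CDI, RfD, HQ, HI and LCR.

The chronic-daily-intake chain follows the standard USEPA inhalation
risk-assessment model::

    CDI = CA * IR * ET * EF * ED / (BW * AT)          [mg/kg/day]
    RfD = RfC * IR / BW                                [mg/kg/day]
    HQ  = CDI / RfD            HI = sum(HQ)            [dimensionless]
    LCR = CDI * SF                                     [dimensionless]

with CA the pollutant concentration (mg/m³), IR the inhalation rate, ET the
exposure time (h/day), EF the exposure frequency (d/y), ED the exposure
duration (y), BW body weight (kg), AT the averaging time, RfC a regulatory
reference concentration and SF a cancer slope factor per (mg/kg·day).

Unit convention: cohort inhalation rates are tabulated per day (m³/day).
``chronic_daily_intake`` prorates them to the exposed hours (IR_daily/24 per
hour), while ``reference_dose`` uses the daily rate as-is — the reference
dose is a whole-day intake ceiling, not an on-shift one.  A consequence worth
noting: with AT = ED (the non-carcinogenic convention) IR and BW cancel in
HQ, so the hazard quotient reduces to (CA/RfC)·(ET/24)·(EF/365) and is the
same for every cohort.

Averaging time: AT = ED for non-carcinogenic risk and 70 years for
carcinogenic risk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

HOURS_PER_DAY = 24.0
DAYS_PER_YEAR = 365.0

#: Default cancer slope factor for black carbon, treating its potency as
#: equivalent to diesel-exhaust particulate, per (mg/kg·day).
DEFAULT_SLOPE_FACTOR = 1.1

#: Fraction of total BC mass in the fine (< 2.5 µm) size range; the
#: carcinogenic assessment applies to this respirable fraction.
BC_FINE_FRACTION = 2.0 / 3.0

UG_PER_MG = 1000.0


def ug_to_mg_per_m3(value_ug_m3: float) -> float:
    """Convert a concentration from µg/m³ to the mg/m³ the intake chain uses."""
    return value_ug_m3 / UG_PER_MG


@dataclass(frozen=True)
class ExposureFactors:
    """One cohort's exposure-factor bundle feeding the intake chain.

    ``CA`` in mg/m³; ``IR_daily`` in m³/day; ``ET`` h/day; ``EF`` d/y;
    ``ED`` and ``AT_years`` in years; ``BW`` in kg.
    """

    CA: float
    IR_daily: float
    ET: float
    EF: float
    ED: float
    BW: float
    AT_years: float

    def __post_init__(self) -> None:
        for name in ("IR_daily", "ET", "EF", "ED", "BW", "AT_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.CA < 0:
            raise ValueError("CA must be non-negative")
        if self.ET > 24:
            raise ValueError("ET cannot exceed 24 h/day")
        if self.EF > 366:
            raise ValueError("EF cannot exceed 366 d/y")


@dataclass(frozen=True)
class CohortGroup:
    """An age–sex cohort with its mean inhalation rate and body weight."""

    sex: str
    age_band: str
    IR_daily: float
    BW: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.IR_daily <= 0 or self.BW <= 0:
            raise ValueError("IR_daily and BW must be positive")


#: Age bands are upper-exclusive: "16-21" covers ages 16–20 inclusive.
AGE_BANDS = ("16-21", "21-30", "30-40", "40-50", "50-60")

#: USEPA exposure-handbook mean inhalation rates (m³/day) and body weights
#: (kg) for the ten worker cohorts.
DEFAULT_COHORTS: tuple[CohortGroup, ...] = (
    CohortGroup("male", "16-21", 17.21, 77.3),
    CohortGroup("male", "21-30", 18.82, 84.9),
    CohortGroup("male", "30-40", 20.29, 87.0),
    CohortGroup("male", "40-50", 20.94, 90.5),
    CohortGroup("male", "50-60", 20.91, 89.5),
    CohortGroup("female", "16-21", 13.59, 65.9),
    CohortGroup("female", "21-30", 14.57, 71.9),
    CohortGroup("female", "30-40", 14.98, 74.8),
    CohortGroup("female", "40-50", 16.20, 77.1),
    CohortGroup("female", "50-60", 16.19, 77.5),
)

#: Worker-shift exposure pattern: 8 h/day, 313 d/y, 35 y.
DEFAULT_ET = 8.0
DEFAULT_EF = 313.0
DEFAULT_ED = 35.0
CARCINOGENIC_AT_YEARS = 70.0


@dataclass(frozen=True)
class Guideline:
    """A regulatory reference concentration for one pollutant.

    ``RfC`` in mg/m³; ``averaging`` one of {"24h", "annual", "8h"}.
    """

    pollutant: str
    agency: str
    averaging: str
    RfC: float

    def __post_init__(self) -> None:
        if self.RfC <= 0:
            raise ValueError("RfC must be strictly positive")
        if self.averaging not in ("24h", "annual", "8h"):
            raise ValueError("averaging must be one of 24h/annual/8h")


#: Built-in registry: Indian NAAQS (CPCB) and WHO ambient limits for PM, and
#: the OSHA/NIOSH occupational 8-h limit for elemental carbon, all in mg/m³.
DEFAULT_GUIDELINES: dict[tuple[str, str, str], Guideline] = {
    (g.pollutant, g.agency, g.averaging): g
    for g in (
        Guideline("PM10", "CPCB", "24h", 0.100),
        Guideline("PM2.5", "CPCB", "24h", 0.060),
        Guideline("PM10", "CPCB", "annual", 0.060),
        Guideline("PM2.5", "CPCB", "annual", 0.040),
        Guideline("PM10", "WHO", "24h", 0.045),
        Guideline("PM2.5", "WHO", "24h", 0.015),
        Guideline("PM10", "WHO", "annual", 0.015),
        Guideline("PM2.5", "WHO", "annual", 0.005),
        Guideline("BC", "OSHA_NIOSH", "8h", 3.5),
    )
}


def lookup_guideline(
    pollutant: str,
    agency: str,
    averaging: str,
    registry: Mapping[tuple[str, str, str], Guideline] | None = None,
) -> Guideline:
    registry = DEFAULT_GUIDELINES if registry is None else registry
    try:
        return registry[(pollutant, agency, averaging)]
    except KeyError:
        raise KeyError(
            f"no guideline for ({pollutant!r}, {agency!r}, {averaging!r})"
        ) from None


@dataclass(frozen=True)
class RiskResult:
    """Risk quantities for one pollutant × cohort."""

    pollutant: str
    sex: str
    age_band: str
    CDI: float
    HQ: float | None = None
    RfD: float | None = None
    LCR: float | None = None
    risk_class: str | None = None


def chronic_daily_intake(f: ExposureFactors) -> float:
    """CDI in mg/kg/day, prorating the daily inhalation rate over exposed hours."""
    ir_hourly = f.IR_daily / HOURS_PER_DAY
    return (f.CA * ir_hourly * f.ET * f.EF * f.ED) / (
        f.BW * f.AT_years * DAYS_PER_YEAR
    )


def reference_dose(g: Guideline, c: CohortGroup) -> float:
    """RfD = RfC · IR_daily / BW, in mg/kg/day."""
    return g.RfC * c.IR_daily / c.BW


def hazard_quotient(f: ExposureFactors, g: Guideline, c: CohortGroup) -> float:
    """HQ = CDI/RfD under the non-carcinogenic convention AT = ED.

    IR and BW cancel, so HQ = (CA/RfC)·(ET/24)·(EF/365) for every cohort.
    """
    if f.AT_years != f.ED:
        raise ValueError("non-carcinogenic HQ requires AT_years == ED")
    f = replace(f, IR_daily=c.IR_daily, BW=c.BW)
    return chronic_daily_intake(f) / reference_dose(g, c)


def hazard_index(hqs: Iterable[float]) -> float:
    """HI = ΣHQ across pollutants; an empty list yields 0."""
    return float(sum(hqs))


def lifetime_cancer_risk(f: ExposureFactors, slope_factor: float = DEFAULT_SLOPE_FACTOR) -> float:
    """LCR = CDI · SF under the carcinogenic convention AT = 70 y."""
    if slope_factor < 0:
        raise ValueError("slope factor must be non-negative")
    return chronic_daily_intake(f) * slope_factor


#: Conventional decision thresholds.
LCR_NEGLIGIBLE = 1e-6
LCR_HIGH = 1e-4
HQ_THRESHOLD = 1.0


def classify_risk(hq: float | None = None, lcr: float | None = None) -> str:
    """Map an HQ (or HI) and/or LCR to a categorical risk class.

    LCR below 1e−6 is negligible (< 1 case per million), above 1e−4 is high;
    between the two the risk is considerable.  An HQ or HI above 1 flags a
    significant non-carcinogenic threat.
    """
    if lcr is not None:
        if lcr < LCR_NEGLIGIBLE:
            return "negligible"
        if lcr < LCR_HIGH:
            return "considerable"
        return "high"
    if hq is not None:
        return "significant_noncancer" if hq > HQ_THRESHOLD else "acceptable"
    raise ValueError("neither HQ nor LCR populated")


def cohort_risk_table(
    pollutant_ca_mg_m3: Mapping[str, float],
    cohorts: Sequence[CohortGroup] = DEFAULT_COHORTS,
    guidelines: Mapping[str, Guideline] | None = None,
    slope_factors: Mapping[str, float] | None = None,
    *,
    ET: float = DEFAULT_ET,
    EF: float = DEFAULT_EF,
    ED: float = DEFAULT_ED,
) -> pd.DataFrame:
    """Deterministic risk for every cohort × pollutant.

    Parameters
    ----------
    pollutant_ca_mg_m3 :
        Pollutant → exposure concentration in mg/m³.
    guidelines :
        Pollutant → Guideline used for HQ.  Pollutants absent here get no HQ.
    slope_factors :
        Pollutant → SF for LCR.  Pollutants absent here get no LCR.

    Returns a frame with columns sex, age_band, pollutant, CDI, RfD, HQ, LCR,
    risk_class.  The non-carcinogenic columns use AT=ED; the carcinogenic CDI
    uses AT=70 y.
    """
    guidelines = guidelines or {}
    slope_factors = slope_factors or {}
    rows = []
    for c in cohorts:
        for pol, ca in pollutant_ca_mg_m3.items():
            rec: dict = {"sex": c.sex, "age_band": c.age_band, "pollutant": pol}
            if pol in slope_factors:
                f = ExposureFactors(ca, c.IR_daily, ET, EF, ED, c.BW, CARCINOGENIC_AT_YEARS)
                rec["CDI"] = chronic_daily_intake(f)
                rec["LCR"] = lifetime_cancer_risk(f, slope_factors[pol])
                rec["risk_class"] = classify_risk(lcr=rec["LCR"])
            else:
                f = ExposureFactors(ca, c.IR_daily, ET, EF, ED, c.BW, ED)
                g = guidelines.get(pol)
                if g is None:
                    raise KeyError(f"no guideline or slope factor for {pol!r}")
                rec["CDI"] = chronic_daily_intake(f)
                rec["RfD"] = reference_dose(g, c)
                rec["HQ"] = hazard_quotient(f, g, c)
                rec["risk_class"] = classify_risk(hq=rec["HQ"])
            rows.append(rec)
    df = pd.DataFrame(rows)
    for col in ("RfD", "HQ", "LCR"):
        if col not in df.columns:
            df[col] = pd.NA
    return df[["sex", "age_band", "pollutant", "CDI", "RfD", "HQ", "LCR", "risk_class"]]
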