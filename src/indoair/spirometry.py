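"""Spirometry interpretation: predicted values, triplicate handling,
obstructive/restrictive classification and PEFR-based asthma screening.

A spirometry session records up to three forced-expiration manoeuvres of
FVC (forced vital capacity, L), FEV1 (forced expiratory volume in 1 s, L)
and PEFR (peak expiratory flow rate, L/s).  Observed values are compared
with predicted values from sex/age/height reference equations; the decision
tree is the standard screening one:

* obstructive — FEV1/FVC < 70% with FVC ≥ 80% of predicted;
* restrictive — FVC < 80% of predicted with FEV1/FVC ≥ 70%;
* combined — both deficits;
* normal — neither.

Asthma screening follows the NIH peak-flow bands: no symptoms above 80% of
predicted PEFR, mild between 50 and 80%, severe below 50%.

Outputs are screening labels, not clinical diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure_stats import pearson

#: Adult reference-equation coefficients, metric = a·height(m) + b·age(y) + c,
#: from the widely used 1993 European (ECSC/Quanjer) summary equations.
#: Keyed (sex, metric); FVC and FEV1 in litres, PEF in L/s.
ECSC_1993: dict[tuple[str, str], tuple[float, float, float]] = {
    ("male", "FVC"): (5.76, -0.026, -4.34),
    ("male", "FEV1"): (4.30, -0.029, -2.49),
    ("male", "PEFR"): (6.14, -0.043, 0.15),
    ("female", "FVC"): (4.43, -0.026, -2.89),
    ("female", "FEV1"): (3.95, -0.025, -2.60),
    ("female", "PEFR"): (5.50, -0.030, -1.11),
}

EQUATION_SETS: dict[str, Mapping[tuple[str, str], tuple[float, float, float]]] = {
    "ECSC-1993": ECSC_1993,
}

PATTERNS = ("normal", "obstructive", "restrictive", "combined")
ASTHMA_BANDS = ("none", "mild", "severe")

RATIO_THRESHOLD_PCT = 70.0   # FEV1/FVC below this flags obstruction
FVC_THRESHOLD_PCT = 80.0     # FVC below this % of predicted flags restriction
PEFR_NONE_PCT = 80.0         # above: no asthma symptoms
PEFR_SEVERE_PCT = 50.0       # below: severe symptoms

#: ATS repeatability: the two best FEV1 values must agree within 5%.
FEV1_REPEATABILITY_PCT = 5.0


@dataclass(frozen=True)
class Manoeuvre:
    FVC: float
    FEV1: float
    PEFR: float

    def __post_init__(self) -> None:
        if not (0 < self.FEV1 <= self.FVC):
            raise ValueError("require 0 < FEV1 <= FVC")
        if self.PEFR <= 0:
            raise ValueError("PEFR must be positive")


@dataclass(frozen=True)
class SpirometrySession:
    """One subject's demographics plus 1–3 forced-expiration manoeuvres."""

    subject_id: str
    sex: str
    age: float
    height: float
    weight: float
    smoker: bool
    manoeuvres: tuple[Manoeuvre, ...]

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not (15 <= self.age <= 80):
            raise ValueError("age must be within 15-80 years")
        if not (1.2 <= self.height <= 2.2):
            raise ValueError("height must be within 1.2-2.2 m")
        if not (1 <= len(self.manoeuvres) <= 3):
            raise ValueError("a session holds 1-3 manoeuvres")


@dataclass(frozen=True)
class PredictedValues:
    FVC_pred: float
    FEV1_pred: float
    PEFR_pred: float
    equation_set: str = "ECSC-1993"

    def __post_init__(self) -> None:
        if min(self.FVC_pred, self.FEV1_pred, self.PEFR_pred) <= 0:
            raise ValueError("predicted values must be positive")


@dataclass(frozen=True)
class LungClassification:
    pattern: str
    asthma_band: str
    fvc_pct: float
    ratio_pct: float
    pefr_pct: float
    repeatability_ok: bool = True


def predicted_values(
    sex: str, age: float, height: float, equation_set: str = "ECSC-1993"
) -> PredictedValues:
    """Predicted FVC, FEV1 and PEFR for an adult from sex, age and height."""
    if equation_set not in EQUATION_SETS:
        raise ValueError(f"unknown equation set {equation_set!r}")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if not (15 <= age <= 80) or not (1.2 <= height <= 2.2):
        raise ValueError("demographics out of supported range")
    coeffs = EQUATION_SETS[equation_set]
    vals = {}
    for metric in ("FVC", "FEV1", "PEFR"):
        a, b, c = coeffs[(sex, metric)]
        vals[metric] = a * height + b * age + c
    return PredictedValues(vals["FVC"], vals["FEV1"], vals["PEFR"], equation_set)


def best_manoeuvre(session: SpirometrySession) -> tuple[float, float, float, bool]:
    """Per-metric maxima across manoeuvres plus the ATS repeatability flag.

    The composite (FVC, FEV1, PEFR) takes the highest value of each metric,
    even if they come from different manoeuvres.  ``repeatability_ok`` is
    true when the two largest FEV1 values differ by at most 5% of the larger
    (trivially true with a single manoeuvre).
    """
    if not session.manoeuvres:
        raise ValueError("session has no manoeuvres")
    fvc = max(m.FVC for m in session.manoeuvres)
    fev1s = sorted((m.FEV1 for m in session.manoeuvres), reverse=True)
    pefr = max(m.PEFR for m in session.manoeuvres)
    if len(fev1s) >= 2:
        gap_pct = 100.0 * (fev1s[0] - fev1s[1]) / fev1s[0]
        ok = gap_pct <= FEV1_REPEATABILITY_PCT
    else:
        ok = True
    return fvc, fev1s[0], pefr, ok


def classify_pattern_pct(fvc_pct: float, ratio_pct: float) -> str:
    """Ventilatory pattern from FVC %-predicted and the FEV1/FVC percentage.

    Thresholds are strict: a ratio of exactly 70% is not obstructive and an
    FVC of exactly 80% predicted is not restrictive.
    """
    obstructed = ratio_pct < RATIO_THRESHOLD_PCT
    restricted = fvc_pct < FVC_THRESHOLD_PCT
    if obstructed and restricted:
        return "combined"
    if obstructed:
        return "obstructive"
    if restricted:
        return "restrictive"
    return "normal"


def classify_pattern(fvc: float, fev1: float, predicted: PredictedValues) -> str:
    """Assign the ventilatory pattern from observed FVC/FEV1 and predictions."""
    if fvc <= 0:
        raise ValueError("FVC must be positive")
    return classify_pattern_pct(100.0 * fvc / predicted.FVC_pred, 100.0 * fev1 / fvc)


def classify_asthma(pefr: float, pefr_pred: float) -> str:
    """NIH peak-flow band: none above 80% of predicted, mild 50–80%, severe below 50%."""
    if pefr <= 0:
        raise ValueError("observed PEFR must be positive")
    if pefr_pred <= 0:
        raise ValueError("predicted PEFR must be positive")
    pct = 100.0 * pefr / pefr_pred
    if pct > PEFR_NONE_PCT:
        return "none"
    if pct >= PEFR_SEVERE_PCT:
        return "mild"
    return "severe"


def classify_session(
    session: SpirometrySession, equation_set: str = "ECSC-1993"
) -> LungClassification:
    """Full interpretation of one session: pattern, asthma band, percentages."""
    pred = predicted_values(session.sex, session.age, session.height, equation_set)
    fvc, fev1, pefr, ok = best_manoeuvre(session)
    return LungClassification(
        pattern=classify_pattern(fvc, fev1, pred),
        asthma_band=classify_asthma(pefr, pred.PEFR_pred),
        fvc_pct=100.0 * fvc / pred.FVC_pred,
        ratio_pct=100.0 * fev1 / fvc,
        pefr_pct=100.0 * pefr / pred.PEFR_pred,
        repeatability_ok=ok,
    )


def cohort_prevalence(classifications: Sequence[LungClassification]) -> pd.DataFrame:
    """Percent of a cohort in each pattern and asthma band, plus % healthy.

    The ventilatory pattern and the asthma band are independent axes, so the
    reported percentages need not sum to 100 across the combined table.
    "healthy" means a normal pattern AND no asthma symptoms.  Percentages are
    rounded to 2 decimals.
    """
    if not classifications:
        raise ValueError("empty cohort")
    n = len(classifications)
    rows = []
    for pattern in PATTERNS:
        count = sum(1 for c in classifications if c.pattern == pattern)
        rows.append({"axis": "pattern", "category": pattern, "count": count})
    for band in ASTHMA_BANDS:
        count = sum(1 for c in classifications if c.asthma_band == band)
        rows.append({"axis": "asthma", "category": band, "count": count})
    healthy = sum(
        1 for c in classifications if c.pattern == "normal" and c.asthma_band == "none"
    )
    rows.append({"axis": "overall", "category": "healthy", "count": healthy})
    df = pd.DataFrame(rows)
    df["percent"] = (100.0 * df["count"] / n).round(2)
    df.insert(0, "n", n)
    return df


def questionnaire_correlations(
    records: pd.DataFrame, tail: str = "one"
) -> pd.DataFrame:
    """Pairwise Pearson correlations across survey fields and disease flags.

    Binary fields are expected coded 0/1.  Constant columns are skipped with
    a ``skipped`` marker row; p-values are one-tailed by default, matching
    the directional screening question ("does this factor increase risk?").
    """
    cols = list(records.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = records[[a, b]].dropna()
            if len(pair) < 3:
                rows.append({"field_a": a, "field_b": b, "skipped": "fewer than 3 records"})
                continue
            x = pair[a].to_numpy(dtype=float)
            y = pair[b].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"field_a": a, "field_b": b, "skipped": "constant column"})
                continue
            res = pearson(x, y, tail=tail)
            rows.append(
                {"field_a": a, "field_b": b, "r": res.r, "p_value": res.p_value, "n": res.n}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interface

_CSV_COLUMNS = [
    "subject_id", "sex", "age_y", "height_m", "weight_kg", "smoker",
    "fvc1", "fvc2", "fvc3", "fev1_1", "fev1_2", "fev1_3",
    "pefr1", "pefr2", "pefr3",
]


def read_spirometry_csv(path) -> list[SpirometrySession]:
    """Read sessions from the wide CSV schema (triplicate columns; blank cells
    mark missing manoeuvres)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    sessions = []
    for _, row in df.iterrows():
        manoeuvres = []
        for k in (1, 2, 3):
            fvc = row[f"fvc{k}"]
            fev1 = row[f"fev1_{k}"]
            pefr = row[f"pefr{k}"]
            if pd.isna(fvc) or pd.isna(fev1) or pd.isna(pefr):
                continue
            manoeuvres.append(Manoeuvre(float(fvc), float(fev1), float(pefr)))
        sessions.append(
            SpirometrySession(
                subject_id=str(row["subject_id"]),
                sex=str(row["sex"]),
                age=float(row["age_y"]),
                height=float(row["height_m"]),
                weight=float(row["weight_kg"]),
                smoker=bool(row["smoker"]),
                manoeuvres=tuple(manoeuvres),
            )
        )
    return sessions


def write_spirometry_csv(sessions: Iterable[SpirometrySession], path) -> None:
    rows = []
    for s in sessions:
        row: dict = {
            "subject_id": s.subject_id, "sex": s.sex, "age_y": s.age,
            "height_m": s.height, "weight_kg": s.weight, "smoker": int(s.smoker),
        }
        for k in (1, 2, 3):
            m = s.manoeuvres[k - 1] if k <= len(s.manoeuvres) else None
            row[f"fvc{k}"] = m.FVC if m else np.nan
            row[f"fev1_{k}"] = m.FEV1 if m else np.nan
            row[f"pefr{k}"] = m.PEFR if m else np.nan
        rows.append(row)
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def classification_table(
    sessions: Sequence[SpirometrySession], equation_set: str = "ECSC-1993"
) -> pd.DataFrame:
    """Classify every session into a flat results frame."""
    rows = []
    for s in sessions:
        c = classify_session(s, equation_set)
        rows.append(
            {
                "subject_id": s.subject_id,
                "pattern": c.pattern,
                "asthma_band": c.asthma_band,
                "fvc_pct": c.fvc_pct,
                "ratio_pct": c.ratio_pct,
                "pefr_pct": c.pefr_pct,
                "repeatability_ok": c.repeatability_ok,
            }
        )
    return pd.DataFrame(rows)
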