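"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of an indoor/outdoor measurement
campaign at an industrial site — correlated PM10/PM2.5/PM1/BC concentration
series, an optional 31-channel particle-size spectrum, a worker cohort with
planted lung-disease labels, and a lifestyle questionnaire with planted
associations — so that every downstream stage can be tested without field
data.

Dependence between series uses a Gaussian copula: configured pairwise rank
correlations are mapped to Gaussian correlations with the sine transform
``2·sin(π·r/6)``, a latent multivariate normal is drawn, and each coordinate
is pushed through its configured marginal's quantile function.  Marginal
defaults are calibrated to an 8-hour industrial campaign in which indoor
PM10 and PM2.5 run above outdoor (penetration plus resuspension under poor
ventilation) while PM1 and BC run slightly below.

All generators are pure functions of (model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure_stats import ConcentrationSeries, Environment, SizeSpectrumSeries
from .spirometry import (
    ASTHMA_BANDS,
    PATTERNS,
    Manoeuvre,
    SpirometrySession,
    predicted_values,
)

#: GRIMM-style 31-channel lower-edge diameters, µm (0.25–32 µm).
SPECTRUM_BINS_UM = np.array(
    [
        0.25, 0.28, 0.30, 0.35, 0.40, 0.45, 0.50, 0.58, 0.65, 0.70,
        0.80, 1.00, 1.30, 1.60, 2.00, 2.50, 3.00, 3.50, 4.00, 5.00,
        6.50, 7.50, 8.50, 10.0, 12.5, 15.0, 17.5, 20.0, 25.0, 30.0, 32.0,
    ]
)

#: Canonical variable order for the dependence matrix.
VARIABLES = (
    "indoor:PM10", "indoor:PM2.5", "indoor:PM1", "indoor:BC",
    "outdoor:PM10", "outdoor:PM2.5", "outdoor:PM1", "outdoor:BC",
)


@dataclass(frozen=True)
class Marginal:
    family: str  # "normal" or "lognormal"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError("family must be 'normal' or 'lognormal'")
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("mean must be > 0 and sd >= 0")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.sd == 0:
            return np.full(len(u), self.mean)
        if self.family == "normal":
            # truncated below zero: concentrations are non-negative
            a = (0.0 - self.mean) / self.sd
            return stats.truncnorm.ppf(u, a, np.inf, loc=self.mean, scale=self.sd)
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return stats.lognorm.ppf(u, np.sqrt(sigma2), scale=np.exp(mu))


#: Campaign-calibrated marginals (µg/m³): 8-h means ± sd per environment.
DEFAULT_MARGINALS: dict[str, Marginal] = {
    "indoor:PM10": Marginal("normal", 131.29, 12.35),
    "indoor:PM2.5": Marginal("normal", 54.51, 1.91),
    "indoor:PM1": Marginal("lognormal", 35.83, 3.27),
    "indoor:BC": Marginal("lognormal", 2.94, 0.93),
    "outdoor:PM10": Marginal("normal", 115.86, 21.87),
    "outdoor:PM2.5": Marginal("normal", 52.12, 4.98),
    "outdoor:PM1": Marginal("lognormal", 39.28, 5.90),
    "outdoor:BC": Marginal("lognormal", 3.76, 1.04),
}


def _default_correlations() -> np.ndarray:
    """Pairwise rank-correlation targets between the eight series.

    Within-environment blocks encode strong co-emission (PM fractions track
    each other, BC tracks the fine fractions).  Each outdoor pollutant
    couples to the other indoor pollutants only through its indoor twin
    (cross entry = within correlation × penetration correlation), a
    conditional-independence structure that keeps the matrix positive
    semi-definite.
    """
    r_in = np.array(
        [
            [1.00, 0.77, 0.60, 0.55],
            [0.77, 1.00, 0.85, 0.92],
            [0.60, 0.85, 1.00, 0.90],
            [0.55, 0.92, 0.90, 1.00],
        ]
    )
    r_out = np.array(
        [
            [1.00, 0.68, 0.50, 0.45],
            [0.68, 1.00, 0.80, 0.60],
            [0.50, 0.80, 1.00, 0.60],
            [0.45, 0.60, 0.60, 1.00],
        ]
    )
    # indoor-outdoor coupling per pollutant (PM10, PM2.5, PM1, BC)
    penetration = np.array([0.60, 0.60, 0.55, 0.52])
    cross = r_in * penetration[None, :]
    return np.block([[r_in, cross], [cross.T, r_out]])


@dataclass(frozen=True)
class ConcentrationModel:
    """Marginals, dependence structure and sampling grid for the series."""

    marginals: Mapping[str, Marginal] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    correlation: np.ndarray = field(default_factory=_default_correlations)
    n_steps: int = 4800           # 10 days x 8 h x 1-min sampling
    interval_minutes: float = 1.0
    start: str = "2022-09-26 09:00"
    site_id: str = "site-01"
    ar1: float = 0.0              # optional temporal autocorrelation knob

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        k = len(VARIABLES)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError(
                "correlation matrix is not positive semi-definite; project it to "
                "the nearest PSD matrix (clip negative eigenvalues and rescale "
                "the diagonal) before use"
            )
        missing = set(VARIABLES) - set(self.marginals)
        if missing:
            raise ValueError(f"missing marginals: {sorted(missing)}")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must lie in [0, 1)")
        object.__setattr__(self, "correlation", corr)


def _gaussian_from_rank(corr: np.ndarray) -> np.ndarray:
    """Sine transform from rank to latent Gaussian correlations."""
    g = 2.0 * np.sin(np.pi * corr / 6.0)
    np.fill_diagonal(g, 1.0)
    w, v = np.linalg.eigh(g)
    if w.min() < 0:  # numerically repair tiny negative eigenvalues
        w = np.clip(w, 1e-10, None)
        g = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(g))
        g = g / np.outer(d, d)
    return g


def generate_concentrations(
    model: ConcentrationModel = ConcentrationModel(),
    seed: int = 0,
    with_spectrum: bool = False,
    spectrum_mode_um: float = 1.2,
    spectrum_gsd: float = 2.2,
    coarse_fraction: float = 0.15,
) -> tuple[dict[str, ConcentrationSeries], SizeSpectrumSeries | None]:
    """Draw the eight correlated concentration series (and optional spectrum).

    Returns a dict keyed ``"<environment>:<pollutant>"`` and, when
    ``with_spectrum`` is set, an indoor 31-channel spectrum whose channel
    aggregates below 1/2.5/10 µm reproduce the returned indoor PM1/PM2.5/PM10
    series exactly.  Mass above 10 µm is added as ``coarse_fraction`` of the
    PM10 draw so the spectrum has content in the coarse channels too.
    """
    rng = np.random.default_rng(seed)
    g = _gaussian_from_rank(model.correlation)
    chol = np.linalg.cholesky(g + 1e-12 * np.eye(len(g)))
    z = rng.standard_normal((model.n_steps, len(VARIABLES)))
    if model.ar1 > 0:
        phi = model.ar1
        for t in range(1, model.n_steps):
            z[t] = phi * z[t - 1] + np.sqrt(1 - phi * phi) * z[t]
    z = z @ chol.T
    u = stats.norm.cdf(z)
    timestamps = pd.date_range(
        model.start, periods=model.n_steps, freq=pd.Timedelta(minutes=model.interval_minutes)
    )
    values = {}
    for j, name in enumerate(VARIABLES):
        values[name] = model.marginals[name].ppf(u[:, j])

    # a size spectrum needs PM1 < PM2.5 < PM10 pointwise; nudge rare violations
    eps = 1e-6
    values["indoor:PM2.5"] = np.maximum(values["indoor:PM2.5"], values["indoor:PM1"] + eps)
    values["indoor:PM10"] = np.maximum(values["indoor:PM10"], values["indoor:PM2.5"] + eps)
    values["outdoor:PM2.5"] = np.maximum(values["outdoor:PM2.5"], values["outdoor:PM1"] + eps)
    values["outdoor:PM10"] = np.maximum(values["outdoor:PM10"], values["outdoor:PM2.5"] + eps)

    series = {}
    for name, vals in values.items():
        env, pol = name.split(":")
        series[name] = ConcentrationSeries(
            site_id=model.site_id,
            environment=Environment(env),
            pollutant=pol,
            timestamps=timestamps,
            values=vals,
        )
    spectrum = None
    if with_spectrum:
        spectrum = _build_spectrum(
            timestamps,
            values["indoor:PM1"],
            values["indoor:PM2.5"],
            values["indoor:PM10"],
            rng,
            mode_um=spectrum_mode_um,
            gsd=spectrum_gsd,
            coarse_fraction=coarse_fraction,
        )
    return series, spectrum


def _build_spectrum(
    timestamps: pd.DatetimeIndex,
    pm1: np.ndarray,
    pm25: np.ndarray,
    pm10: np.ndarray,
    rng: np.random.Generator,
    mode_um: float,
    gsd: float,
    coarse_fraction: float,
) -> SizeSpectrumSeries:
    """Split bulk PM masses across the 31 channels.

    Within each size group (< 1, 1–2.5, 2.5–10, ≥ 10 µm) the group mass is
    distributed over channels with lognormal weights over the channel
    midpoints (mode ``mode_um``, geometric sd ``gsd``), jittered per time
    step and renormalised so the group totals — hence the PM aggregates —
    are preserved exactly.  A crude number concentration is derived from the
    mass assuming unit-density spheres at the channel midpoint diameter.
    """
    bins = SPECTRUM_BINS_UM
    uppers = np.append(bins[1:], 34.0)
    mids = np.sqrt(bins * uppers)
    log_sigma = np.log(gsd)
    base_w = stats.norm.pdf(np.log(mids), np.log(mode_um), log_sigma)
    groups = [bins < 1.0, (bins >= 1.0) & (bins < 2.5), (bins >= 2.5) & (bins < 10.0), bins >= 10.0]
    group_mass = np.column_stack([pm1, pm25 - pm1, pm10 - pm25, coarse_fraction * pm10])
    n, k = len(timestamps), len(bins)
    mass = np.zeros((n, k))
    jitter = rng.lognormal(0.0, 0.15, size=(n, k))
    for gi, sel in enumerate(groups):
        w = base_w[sel] * jitter[:, sel]
        w = w / w.sum(axis=1, keepdims=True)
        mass[:, sel] = group_mass[:, gi][:, None] * w
    # number concentration: mass (µg/m³) over single-particle mass at unit density
    particle_mass_ug = 1e-6 * (np.pi / 6.0) * mids**3  # µg per particle at 1 g/cm³
    number_per_m3 = mass / particle_mass_ug
    number = number_per_m3 / 1e6  # counts/cm³
    return SizeSpectrumSeries(timestamps=timestamps, bins=bins, mass=mass, number=number)


# ---------------------------------------------------------------------------
# Worker cohort with planted lung-function labels


@dataclass(frozen=True)
class CohortModel:
    """A synthetic worker cohort specification.

    ``pattern_prevalence`` orders (normal, obstructive, restrictive,
    combined); ``asthma_prevalence`` orders (none, mild, severe); the two
    axes are planted independently.  ``margin_pct`` (δ) keeps every planted
    observation at least that many percentage points away from every
    decision threshold, making label recovery exact by construction.
    """

    n_subjects: int = 184
    male_fraction: float = 0.7
    pattern_prevalence: tuple[float, float, float, float] = (0.5327, 0.0434, 0.4239, 0.0)
    asthma_prevalence: tuple[float, float, float] = (0.4674, 0.4261, 0.1065)
    margin_pct: float = 5.0
    smoker_fraction: float = 0.5
    triplicate_jitter: float = 0.02

    def __post_init__(self) -> None:
        for p in (*self.pattern_prevalence, *self.asthma_prevalence):
            if not (0 <= p <= 1):
                raise ValueError("prevalences must lie in [0, 1]")
        if abs(sum(self.pattern_prevalence) - 1) > 1e-9:
            raise ValueError("pattern prevalences must sum to 1")
        if abs(sum(self.asthma_prevalence) - 1) > 1e-9:
            raise ValueError("asthma prevalences must sum to 1")
        if self.margin_pct <= 0:
            raise ValueError("margin must be positive")
        if self.margin_pct >= 15:
            raise ValueError(
                "margin of 15 pp or more empties the mild asthma band (50-80%)"
            )
        if not (0 <= self.triplicate_jitter <= 0.025):
            raise ValueError("triplicate jitter above 2.5% would break ATS repeatability")


def _apportion(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder allocation of n subjects to categories.

    Deterministic so the realised label counts match the configured
    prevalences as closely as integers allow.
    """
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    for k in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[k] += 1
    return counts


def _pattern_region(pattern: str, d: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """(fvc_pct range, ratio_pct range) for a pattern, δ away from thresholds."""
    high_fvc, low_fvc = (80.0 + d, 115.0), (50.0, 80.0 - d)
    high_ratio, low_ratio = (70.0 + d, 90.0), (45.0, 70.0 - d)
    return {
        "normal": (high_fvc, high_ratio),
        "obstructive": (high_fvc, low_ratio),
        "restrictive": (low_fvc, high_ratio),
        "combined": (low_fvc, low_ratio),
    }[pattern]


def _asthma_region(band: str, d: float) -> tuple[float, float]:
    return {
        "none": (80.0 + d, 115.0),
        "mild": (50.0 + d, 80.0 - d),
        "severe": (25.0, 50.0 - d),
    }[band]


def generate_cohort(
    model: CohortModel = CohortModel(), seed: int = 0
) -> tuple[list[SpirometrySession], pd.DataFrame]:
    """Generate spirometry sessions with planted, exactly recoverable labels.

    Each subject receives a pattern and an asthma band from the prevalence
    vectors, then observed percentages are drawn uniformly inside the label's
    threshold region excluding the δ margin; percentages are converted to
    litres through the reference equations and emitted as triplicates whose
    per-metric maxima equal the planted values (the other manoeuvres sit up
    to 2% lower, keeping the session ATS-repeatable).

    Returns the sessions and a ground-truth frame (subject_id, sex, age,
    pattern, asthma_band).
    """
    rng = np.random.default_rng(seed)
    d = model.margin_pct
    sessions, truth = [], []
    n_each = _apportion(model.n_subjects, model.pattern_prevalence)
    patterns = np.repeat(PATTERNS, n_each)
    n_band = _apportion(model.n_subjects, model.asthma_prevalence)
    bands = np.repeat(ASTHMA_BANDS, n_band)
    rng.shuffle(patterns)
    rng.shuffle(bands)
    for i in range(model.n_subjects):
        sex = "male" if rng.random() < model.male_fraction else "female"
        age = float(rng.uniform(18, 60))
        height = float(
            np.clip(rng.normal(1.68 if sex == "male" else 1.56, 0.06), 1.45, 1.85)
        )
        weight = float(np.clip(rng.normal(61, 15), 40, 105))
        pred = predicted_values(sex, age, height)
        (fvc_lo, fvc_hi), (ratio_lo, ratio_hi) = _pattern_region(patterns[i], d)
        pefr_lo, pefr_hi = _asthma_region(bands[i], d)
        fvc_pct = rng.uniform(fvc_lo, fvc_hi)
        ratio_pct = rng.uniform(ratio_lo, ratio_hi)
        pefr_pct = rng.uniform(pefr_lo, pefr_hi)
        fvc = fvc_pct / 100.0 * pred.FVC_pred
        fev1 = ratio_pct / 100.0 * fvc
        pefr = pefr_pct / 100.0 * pred.PEFR_pred
        manoeuvres = [Manoeuvre(fvc, fev1, pefr)]
        for _ in range(2):
            shrink = 1.0 - rng.uniform(0, model.triplicate_jitter, size=3)
            manoeuvres.append(
                Manoeuvre(fvc * shrink[0], min(fev1 * shrink[1], fvc * shrink[0]), pefr * shrink[2])
            )
        subject_id = f"S{i + 1:03d}"
        sessions.append(
            SpirometrySession(
                subject_id=subject_id,
                sex=sex,
                age=age,
                height=height,
                weight=weight,
                smoker=bool(rng.random() < model.smoker_fraction),
                manoeuvres=tuple(manoeuvres),
            )
        )
        truth.append(
            {
                "subject_id": subject_id,
                "sex": sex,
                "age_y": age,
                "pattern": patterns[i],
                "asthma_band": bands[i],
            }
        )
    return sessions, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Lifestyle questionnaire with planted binary associations

#: Survey fields emitted by default (all binary, 0/1).
QUESTIONNAIRE_FIELDS = (
    "smoking", "alcohol", "wood_fuel", "exhaust_fan", "near_road",
    "regular_exercise", "dust_allergy", "urban_home", "kitchen_garden",
)


def generate_questionnaire(
    truth: pd.DataFrame,
    associations: Sequence[tuple[str, str, float]] = (("smoking", "asthma_flag", 0.18),),
    seed: int = 0,
    base_rate: float = 0.5,
) -> pd.DataFrame:
    """Generate a binary survey table with planted point-biserial associations.

    ``truth`` is the ground-truth frame from :func:`generate_cohort`;
    ``associations`` lists (field, target_flag, phi) where target_flag is
    ``"asthma_flag"`` (asthma band ≠ none) or ``"disease_flag"`` (pattern ≠
    normal).  Unlisted fields are independent coin flips at ``base_rate``.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    out = pd.DataFrame({"subject_id": truth["subject_id"]})
    out["asthma_flag"] = (truth["asthma_band"] != "none").astype(int)
    out["disease_flag"] = (truth["pattern"] != "normal").astype(int)
    assoc = {f: (t, r) for f, t, r in associations}
    for _, (_, r) in assoc.items():
        if abs(r) >= 1:
            raise ValueError("association |r| must be < 1")
    for fld in QUESTIONNAIRE_FIELDS:
        if fld in assoc:
            target, r = assoc[fld]
            flag = out[target].to_numpy()
            pf = flag.mean()
            if pf in (0.0, 1.0):
                raise ValueError(f"target {target!r} is constant; cannot plant association")
            pb = base_rate
            p11 = pb * pf + r * np.sqrt(pb * (1 - pb) * pf * (1 - pf))
            p_given_1 = p11 / pf
            p_given_0 = (pb - p11) / (1 - pf)
            if not (0 <= p_given_1 <= 1 and 0 <= p_given_0 <= 1):
                raise ValueError(f"association r={r} infeasible at these marginals")
            u = rng.random(n)
            out[fld] = np.where(flag == 1, u < p_given_1, u < p_given_0).astype(int)
        else:
            out[fld] = (rng.random(n) < base_rate).astype(int)
    return out
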