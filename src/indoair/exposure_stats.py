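"""Descriptive statistics for pollutant concentration time series.

The measurement campaign this package models records particulate matter
(PM10, PM2.5, PM1) and black carbon (BC) with portable optical instruments
in paired indoor/outdoor deployments.  This module provides the containers
for those series and the descriptive layer of the analysis: boxplot- and
histogram-style summaries, Pearson correlations (including size-resolved
correlation of a 31-channel particle spectrum against BC), indoor/outdoor
ratios, normal-vs-lognormal distribution-shape selection, and the projection
of a short campaign's indoor mean to an annual indoor mean using a co-located
regulatory monitor as the scaling anchor.

All concentrations are in µg/m³ unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class Environment(str, Enum):
    INDOOR = "indoor"
    OUTDOOR = "outdoor"


#: Recognised bulk pollutants.  Size-spectrum channels use "channel:<lower edge>".
POLLUTANTS = ("PM10", "PM2.5", "PM1", "BC")


class DegenerateInputError(ValueError):
    """Raised when an input has no variance or no data to work with."""


@dataclass(frozen=True)
class ConcentrationSeries:
    """A timestamped concentration series for one site/environment/pollutant.

    Parameters
    ----------
    site_id : str
        Identifier of the monitored site.
    environment : Environment
        Whether the series was recorded indoors or outdoors.
    pollutant : str
        One of ``POLLUTANTS`` or ``"channel:<lower_edge_um>"``.
    timestamps : pandas.DatetimeIndex
        Strictly increasing sampling times.
    values : numpy.ndarray
        Non-negative concentrations in µg/m³, one per timestamp.
    """

    site_id: str
    environment: Environment
    pollutant: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if len(ts) != len(vals):
            raise ValueError("timestamps and values must have equal length")
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(ts) != len(ts.unique()):
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        if np.any(vals < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "environment", Environment(self.environment))

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with the canonical CSV columns."""
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "site_id": self.site_id,
                "environment": self.environment.value,
                "pollutant": self.pollutant,
                "value_ug_m3": self.values,
            }
        )


@dataclass(frozen=True)
class SizeSpectrumSeries:
    """Optical-spectrometer output: per-channel mass (and number) concentration.

    ``bins`` are the 31 lower-edge aerodynamic diameters in µm (0.25–32 µm);
    ``mass`` is a (time × bin) matrix in µg/m³ and ``number``, when present,
    a matching matrix in counts/cm³.
    """

    timestamps: pd.DatetimeIndex
    bins: np.ndarray
    mass: np.ndarray
    number: np.ndarray | None = None

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        bins = np.asarray(self.bins, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if bins.ndim != 1 or len(bins) != 31:
            raise ValueError("a size spectrum has exactly 31 channels")
        if np.any(np.diff(bins) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if mass.shape != (len(ts), len(bins)):
            raise ValueError("mass matrix must be (time x bin)")
        if np.any(mass < 0):
            raise ValueError("mass concentrations must be non-negative")
        if self.number is not None:
            number = np.asarray(self.number, dtype=float)
            if number.shape != mass.shape or np.any(number < 0):
                raise ValueError("number matrix must match mass shape, non-negative")
            object.__setattr__(self, "number", number)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "bins", bins)
        object.__setattr__(self, "mass", mass)

    def aggregate_below(self, cutoff_um: float) -> np.ndarray:
        """Total mass per time step over channels whose lower edge is < cutoff."""
        sel = self.bins < cutoff_um
        return self.mass[:, sel].sum(axis=1)


@dataclass(frozen=True)
class SummaryStats:
    """Boxplot/histogram characterisation of one concentration series."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    q1: float
    median: float
    q3: float
    outliers: tuple[float, ...]
    modal_bin: tuple[float, float]
    modal_freq: float

    def as_dict(self) -> dict:
        d = {
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "min": self.min, "q1": self.q1, "median": self.median,
            "q3": self.q3, "max": self.max,
            "n_outliers": len(self.outliers),
            "modal_bin_low": self.modal_bin[0],
            "modal_bin_high": self.modal_bin[1],
            "modal_freq": self.modal_freq,
        }
        return d


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its t-distribution p-value."""

    r: float
    p_value: float
    n: int
    tail: str = "two"


@dataclass(frozen=True)
class ProjectionInputs:
    """Inputs for projecting a campaign indoor mean to an annual indoor mean.

    ``c1_annual_ambient`` is the one-year ambient mean from a fixed regulatory
    monitor; ``c2_study_indoor`` and ``c3_study_ambient`` are the campaign-period
    indoor and ambient means.  All in µg/m³ and strictly positive.
    """

    c1_annual_ambient: float
    c2_study_indoor: float
    c3_study_ambient: float

    def __post_init__(self) -> None:
        for name in ("c1_annual_ambient", "c2_study_indoor", "c3_study_ambient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def summarize(series: ConcentrationSeries, bin_count: int = 10) -> SummaryStats:
    """Summarise a series: moments, type-7 quartiles, Tukey outliers, modal bin.

    Quartiles use linear interpolation between order statistics; the standard
    deviation is the sample (n−1) definition.  Outliers are values beyond the
    Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR].  The modal bin is the most
    populated of ``bin_count`` equal-width histogram bins spanning [min, max].
    """
    if len(series) == 0:
        raise DegenerateInputError("no data")
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    x = series.values
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(v) for v in x[(x < lo) | (x > hi)])
    counts, edges = np.histogram(x, bins=bin_count, range=(x.min(), x.max()))
    k = int(np.argmax(counts))
    return SummaryStats(
        n=len(x),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        min=float(x.min()),
        max=float(x.max()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        outliers=outliers,
        modal_bin=(float(edges[k]), float(edges[k + 1])),
        modal_freq=float(counts[k] / len(x)),
    )


def pearson(x: Sequence[float], y: Sequence[float], tail: str = "two") -> CorrelationResult:
    """Pearson r between two equal-length sequences with a t-based p-value.

    ``tail="one"`` halves the two-sided p-value, i.e. tests in the direction
    of the observed sign.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("degenerate input: zero variance")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    res = stats.pearsonr(x, y)
    p = float(res.pvalue)
    if tail == "one":
        p = p / 2.0
    return CorrelationResult(r=float(res.statistic), p_value=p, n=len(x), tail=tail)


def size_resolved_correlation(
    spectrum: SizeSpectrumSeries,
    bc: ConcentrationSeries,
    tail: str = "two",
) -> pd.DataFrame:
    """Correlate each spectrum channel with a BC series after an exact inner join.

    Returns one row per channel with ``bin_low_um``, ``r_mass``, ``p_mass``
    (and ``r_number``/``p_number`` when the spectrum carries number
    concentrations), plus ``n`` matched and ``n_dropped`` unmatched timestamps.
    """
    spec_idx = pd.DatetimeIndex(spectrum.timestamps)
    bc_idx = pd.DatetimeIndex(bc.timestamps)
    common = spec_idx.intersection(bc_idx)
    if len(common) == 0:
        raise ValueError("no overlapping timestamps")
    n_dropped = (len(spec_idx) - len(common)) + (len(bc_idx) - len(common))
    si = spec_idx.get_indexer(common)
    bi = bc_idx.get_indexer(common)
    bc_vals = bc.values[bi]
    rows = []
    for j, edge in enumerate(spectrum.bins):
        row: dict = {"bin_low_um": float(edge), "n": len(common), "n_dropped": n_dropped}
        res = pearson(spectrum.mass[si, j], bc_vals, tail=tail)
        row["r_mass"], row["p_mass"] = res.r, res.p_value
        if spectrum.number is not None:
            res_n = pearson(spectrum.number[si, j], bc_vals, tail=tail)
            row["r_number"], row["p_number"] = res_n.r, res_n.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def io_ratio(indoor: SummaryStats, outdoor: SummaryStats) -> tuple[float, float]:
    """Indoor/outdoor mean ratio and the percent excess (ratio − 1)·100.

    A ratio above 1 indicates indoor accumulation (penetration from outside
    plus resuspension under poor ventilation).
    """
    if outdoor.mean == 0:
        raise ValueError("outdoor mean must be non-zero")
    ratio = indoor.mean / outdoor.mean
    return ratio, (ratio - 1.0) * 100.0


def annual_projection(p: ProjectionInputs) -> float:
    """Project the campaign indoor mean to an annual indoor mean (µg/m³).

    The campaign indoor mean is rescaled by the ratio of the annual to the
    campaign-period ambient mean at a co-located fixed monitor::

        C4 = C1 * C2 / C3

    which assumes the indoor/ambient ratio observed during the campaign holds
    year-round.
    """
    return p.c1_annual_ambient * p.c2_study_indoor / p.c3_study_ambient


@dataclass(frozen=True)
class ShapeFit:
    """Outcome of normal-vs-lognormal model selection for one series."""

    selected: str
    loglik_normal: float
    loglik_lognormal: float
    params_normal: tuple[float, float] = field(default=(np.nan, np.nan))
    params_lognormal: tuple[float, float] = field(default=(np.nan, np.nan))


def distribution_shape(series: ConcentrationSeries) -> ShapeFit:
    """Choose between a normal and a lognormal description of a series.

    Both candidates are fit by maximum likelihood and the higher log-likelihood
    wins (equal parameter counts, so this matches AIC selection).  The
    lognormal candidate is infeasible when any value is non-positive.
    """
    x = series.values
    if len(x) < 20:
        raise ValueError("need at least 20 observations for shape selection")
    if np.ptp(x) == 0:
        raise DegenerateInputError("degenerate input: constant series")
    mu, sigma = float(np.mean(x)), float(np.std(x))
    ll_norm = float(np.sum(stats.norm.logpdf(x, mu, sigma)))
    if np.any(x <= 0):
        return ShapeFit("normal", ll_norm, -np.inf, params_normal=(mu, sigma))
    logx = np.log(x)
    lmu, lsigma = float(np.mean(logx)), float(np.std(logx))
    ll_lnorm = float(np.sum(stats.lognorm.logpdf(x, lsigma, scale=np.exp(lmu))))
    selected = "normal" if ll_norm >= ll_lnorm else "lognormal"
    return ShapeFit(selected, ll_norm, ll_lnorm, (mu, sigma), (lmu, lsigma))


# ---------------------------------------------------------------------------
# CSV interfaces


def read_concentration_csv(path) -> list[ConcentrationSeries]:
    """Read a long-format concentration CSV into one series per
    (site, environment, pollutant) group.

    Expected columns: timestamp (ISO-8601), site_id, environment, pollutant,
    value_ug_m3.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "site_id", "environment", "pollutant", "value_ug_m3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for (site, env, pol), grp in df.groupby(["site_id", "environment", "pollutant"], sort=True):
        grp = grp.sort_values("timestamp")
        out.append(
            ConcentrationSeries(
                site_id=str(site),
                environment=Environment(env),
                pollutant=str(pol),
                timestamps=pd.DatetimeIndex(grp["timestamp"]),
                values=grp["value_ug_m3"].to_numpy(dtype=float),
            )
        )
    return out


def write_concentration_csv(series: Sequence[ConcentrationSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)


def read_spectrum_csv(path) -> SizeSpectrumSeries:
    """Read a spectrum CSV: timestamp + 31 ``m_<edge>`` mass columns and
    optional ``n_<edge>`` number columns."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    mass_cols = sorted(
        (c for c in df.columns if c.startswith("m_")), key=lambda c: float(c[2:])
    )
    if len(mass_cols) != 31:
        raise ValueError(f"expected 31 mass channels, found {len(mass_cols)}")
    bins = np.array([float(c[2:]) for c in mass_cols])
    number_cols = sorted(
        (c for c in df.columns if c.startswith("n_")), key=lambda c: float(c[2:])
    )
    number = df[number_cols].to_numpy(dtype=float) if len(number_cols) == 31 else None
    return SizeSpectrumSeries(
        timestamps=pd.DatetimeIndex(df["timestamp"]),
        bins=bins,
        mass=df[mass_cols].to_numpy(dtype=float),
        number=number,
    )


def write_spectrum_csv(spectrum: SizeSpectrumSeries, path) -> None:
    data = {"timestamp": spectrum.timestamps}
    for j, edge in enumerate(spectrum.bins):
        data[f"m_{edge:g}"] = spectrum.mass[:, j]
    if spectrum.number is not None:
        for j, edge in enumerate(spectrum.bins):
            data[f"n_{edge:g}"] = spectrum.number[:, j]
    pd.DataFrame(data).to_csv(path, index=False)
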