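"""Monte Carlo counterpart of the deterministic risk chain.

Each risk variable (CA, IR, ET, EF, ED, BW, RfD) carries a sampling
distribution; the intake chain is evaluated row-wise over the draws and the
resulting HQ or LCR sample is summarised.  Inputs are sampled independently.
A contribution-to-variance sensitivity analysis (the tornado-plot statistic
popularised by spreadsheet risk tools) attributes output variance to inputs
via squared Spearman rank correlations, signed by the direction of
association.

Default spreads, chosen to represent realistic occupational variability and
overridable per variable:

* CA — lognormal, moment-matched to the observed series mean and sd;
* IR, BW — normal with 10% coefficient of variation, truncated at zero and
  at ±4 sd (truncated mass is counted and exposed on the result);
* ET — uniform on 7–9 h/day around the 8-h shift;
* EF — triangular 280/313/346 d/y;
* ED — uniform 25–45 y;
* RfD — point (a regulatory constant, not a variable quantity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .deterministic_risk import (
    CARCINOGENIC_AT_YEARS,
    DAYS_PER_YEAR,
    HOURS_PER_DAY,
    CohortGroup,
)

RISK_VARIABLES = ("CA", "IR", "ET", "EF", "ED", "BW", "RfD")
FAMILIES = ("lognormal", "normal", "uniform", "triangular", "point")


@dataclass(frozen=True)
class DistributionSpec:
    """A named sampling distribution for one risk variable.

    ``params`` by family: normal/lognormal — mean, sd in natural units;
    uniform — low, high; triangular — low, mode, high; point — value.
    """

    variable: str
    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.variable not in RISK_VARIABLES:
            raise ValueError(f"unknown risk variable {self.variable!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.family in ("normal", "lognormal"):
            if len(p) != 2 or p[1] < 0:
                raise ValueError("normal/lognormal need (mean, sd) with sd >= 0")
            if self.family == "lognormal" and p[0] <= 0:
                raise ValueError("lognormal mean must be positive")
        elif self.family == "uniform":
            if len(p) != 2 or p[0] > p[1]:
                raise ValueError("uniform needs (low, high) with low <= high")
        elif self.family == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]):
                raise ValueError("triangular needs low <= mode <= high")
        elif len(p) != 1:
            raise ValueError("point needs a single value")

    @property
    def is_point(self) -> bool:
        if self.family == "point":
            return True
        if self.family in ("normal", "lognormal"):
            return self.params[1] == 0
        if self.family == "uniform":
            return self.params[0] == self.params[1]
        return self.params[0] == self.params[2]


@dataclass(frozen=True)
class MCConfig:
    n_iterations: int = 50_000
    seed: int = 0
    antithetic: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class MCResult:
    """Summary of a Monte Carlo HQ or LCR sample."""

    target: str
    mean: float
    sd: float
    percentiles: dict[str, float]
    exceedance: float
    n: int
    truncated_fraction: float
    samples: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SensitivityResult:
    """Signed per-variable contribution to output variance, in percent."""

    contributions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(abs(v) for v in self.contributions.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError("absolute contributions must sum to 100 +/- 0.5")


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Map a natural-scale (mean, sd) to the log-scale (µ, σ) of a lognormal."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def default_specs(
    ca_mean: float,
    ca_sd: float,
    cohort: CohortGroup,
    rfd: float | None = None,
) -> dict[str, DistributionSpec]:
    """The documented default distribution set for one cohort.

    ``ca_mean``/``ca_sd`` are in mg/m³ (the units the intake chain uses).
    """
    specs = {
        "CA": DistributionSpec("CA", "lognormal", (ca_mean, ca_sd)),
        "IR": DistributionSpec("IR", "normal", (cohort.IR_daily, 0.10 * cohort.IR_daily)),
        "ET": DistributionSpec("ET", "uniform", (7.0, 9.0)),
        "EF": DistributionSpec("EF", "triangular", (280.0, 313.0, 346.0)),
        "ED": DistributionSpec("ED", "uniform", (25.0, 45.0)),
        "BW": DistributionSpec("BW", "normal", (cohort.BW, 0.10 * cohort.BW)),
    }
    if rfd is not None:
        specs["RfD"] = DistributionSpec("RfD", "point", (rfd,))
    return specs


def _ppf(spec: DistributionSpec, u: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse-CDF transform of uniforms; returns (values, truncated mass).

    Every family is sampled through its quantile function so that antithetic
    pairing works uniformly.  Normal draws are truncated to
    [max(0, mean − 4·sd), mean + 4·sd] — physiology cannot be negative — and
    the probability mass cut off by the truncation is reported.
    """
    p = spec.params
    if spec.is_point:
        value = p[0] if spec.family != "triangular" else p[1]
        return np.full(len(u), value), 0.0
    if spec.family == "normal":
        mean, sd = p
        lo, hi = max(0.0, mean - 4 * sd), mean + 4 * sd
        a, b = (lo - mean) / sd, (hi - mean) / sd
        kept = stats.norm.cdf(b) - stats.norm.cdf(a)
        return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd), float(1.0 - kept)
    if spec.family == "lognormal":
        mu, sigma = lognormal_from_moments(*p)
        return stats.lognorm.ppf(u, sigma, scale=np.exp(mu)), 0.0
    if spec.family == "uniform":
        lo, hi = p
        return lo + (hi - lo) * u, 0.0
    # triangular
    lo, mode, hi = p
    fc = (mode - lo) / (hi - lo)
    left = u < fc
    x = np.empty(len(u))
    x[left] = lo + np.sqrt(u[left] * (hi - lo) * (mode - lo))
    x[~left] = hi - np.sqrt((1 - u[~left]) * (hi - lo) * (hi - mode))
    return x, 0.0


def sample_parameters(
    specs: Mapping[str, DistributionSpec], cfg: MCConfig
) -> tuple[dict[str, np.ndarray], float]:
    """Draw an (n × variables) table of parameter values.

    Returns the draws and the average truncated probability mass across the
    normal variables.  Reproducible for a given seed; variables are sampled
    in sorted name order.  With ``antithetic`` the second half of each
    variable's uniforms mirrors the first (u, 1−u).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_iterations
    draws: dict[str, np.ndarray] = {}
    trunc_mass = 0.0
    for name in sorted(specs):
        spec = specs[name]
        if spec.variable != name:
            raise ValueError(f"spec for {name!r} declares variable {spec.variable!r}")
        if cfg.antithetic:
            half = rng.random((n + 1) // 2)
            u = np.concatenate([half, 1.0 - half])[:n]
        else:
            u = rng.random(n)
        x, t = _ppf(spec, u)
        draws[name] = x
        trunc_mass += t
    return draws, trunc_mass / max(1, len(specs))


def run_monte_carlo(
    specs: Mapping[str, DistributionSpec],
    cfg: MCConfig,
    target: str,
    slope_factor: float | None = None,
) -> MCResult:
    """Propagate the parameter distributions through the intake chain.

    ``target`` is "HQ" (requires an RfD spec; AT = ED) or "LCR" (requires a
    slope factor; AT = 70 y).  With all-point specs the sample collapses to
    the deterministic value.
    """
    if target not in ("HQ", "LCR"):
        raise ValueError("target must be 'HQ' or 'LCR'")
    required = {"CA", "IR", "ET", "EF", "ED", "BW"}
    if target == "HQ":
        required.add("RfD")
    missing = required - set(specs)
    if missing:
        raise ValueError(f"missing distribution specs: {sorted(missing)}")
    if target == "LCR" and (slope_factor is None or slope_factor <= 0):
        raise ValueError("LCR requires a positive slope factor")
    draws, trunc = sample_parameters({k: specs[k] for k in required}, cfg)
    cdi_num = (
        draws["CA"] * (draws["IR"] / HOURS_PER_DAY) * draws["ET"] * draws["EF"] * draws["ED"]
    )
    if target == "HQ":
        at_years = draws["ED"]  # non-carcinogenic convention AT = ED
        cdi = cdi_num / (draws["BW"] * at_years * DAYS_PER_YEAR)
        samples = cdi / draws["RfD"]
        threshold = 1.0
    else:
        cdi = cdi_num / (draws["BW"] * CARCINOGENIC_AT_YEARS * DAYS_PER_YEAR)
        samples = cdi * slope_factor
        threshold = 1e-4
    pct = np.percentile(samples, [2.5, 5, 50, 95, 97.5])
    return MCResult(
        target=target,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if len(samples) > 1 else 0.0,
        percentiles={
            "p2.5": float(pct[0]),
            "p5": float(pct[1]),
            "p50": float(pct[2]),
            "p95": float(pct[3]),
            "p97.5": float(pct[4]),
        },
        exceedance=float(np.mean(samples > threshold)),
        n=cfg.n_iterations,
        truncated_fraction=trunc,
        samples=samples,
    )


def percent_difference(deterministic: float, probabilistic_mean: float) -> float:
    """Percent gap between the two estimates, relative to the Monte Carlo mean."""
    if probabilistic_mean == 0:
        raise ValueError("probabilistic mean must be non-zero")
    return 100.0 * (probabilistic_mean - deterministic) / probabilistic_mean


def sensitivity_analysis(
    specs: Mapping[str, DistributionSpec],
    cfg: MCConfig,
    target: str,
    slope_factor: float | None = None,
) -> SensitivityResult:
    """Signed contribution-to-variance of each varying input.

    For each non-point variable i, the Spearman rank correlation ρᵢ between
    its draws and the target sample is computed; the contribution is
    sign(ρᵢ)·ρᵢ²/Σⱼρⱼ²·100.  Point variables contribute nothing and are
    omitted.
    """
    varying = [k for k, s in specs.items() if not s.is_point]
    if not varying:
        raise ValueError("nothing to vary: all specs are point distributions")
    required = {"CA", "IR", "ET", "EF", "ED", "BW"}
    if target == "HQ":
        required.add("RfD")
    draws, _ = sample_parameters({k: specs[k] for k in required}, cfg)
    # recompute target row-wise on the same draws
    cdi_num = (
        draws["CA"] * (draws["IR"] / HOURS_PER_DAY) * draws["ET"] * draws["EF"] * draws["ED"]
    )
    if target == "HQ":
        samples = cdi_num / (draws["BW"] * draws["ED"] * DAYS_PER_YEAR) / draws["RfD"]
    elif target == "LCR":
        if slope_factor is None or slope_factor <= 0:
            raise ValueError("LCR requires a positive slope factor")
        samples = cdi_num / (draws["BW"] * CARCINOGENIC_AT_YEARS * DAYS_PER_YEAR) * slope_factor
    else:
        raise ValueError("target must be 'HQ' or 'LCR'")
    rhos = {}
    for name in varying:
        if name not in draws:
            continue
        rho = stats.spearmanr(draws[name], samples).statistic
        rhos[name] = float(rho)
    total = sum(r * r for r in rhos.values())
    if total == 0:
        raise ValueError("target shows no rank association with any input")
    contributions = {
        name: float(np.sign(r) * (r * r) / total * 100.0) for name, r in rhos.items()
    }
    return SensitivityResult(contributions=contributions)
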