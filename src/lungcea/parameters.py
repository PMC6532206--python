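"""Model parameters for the lung-transplant service cost-utility model.

The decision problem compares two configurations of a national adult
lung-transplant service: a standard-transplant-only service and a service
that additionally uses ex-vivo lung perfusion (EVLP) to recondition donor
lungs, expressed as a proportional uplift on standard transplant activity.

Every model input is a published summary statistic: waiting-list transition
probabilities per registration year, post-transplant survival points,
SF-6D health-state utilities, and per-stage costs in 2016/17 GBP.  Each
uncertain parameter carries a :class:`DistributionSpec` (Beta for
probabilities and utilities, Gamma for costs) used by the probabilistic
sensitivity analysis; the deterministic model uses the point values.

Method-of-moments fitters (`beta_from_mean_count`, `beta_from_mean_variance`,
`gamma_from_mean_se`) derive distribution parameters from summary data, and
are also used by :mod:`lungcea.synthetic` to re-estimate parameters from
pseudo-trial records.

Currency convention: all monetary values are real GBP stored as floats.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields, is_dataclass
from typing import Any, Iterator, Optional

import numpy as np

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "TransitionBand",
    "SurvivalPoints",
    "UtilitySet",
    "CostSet",
    "RemovedStateAccrual",
    "ModelParameters",
    "beta_from_mean_count",
    "beta_from_mean_variance",
    "gamma_from_mean_se",
    "load_base_case",
    "get_value",
    "set_value",
    "iter_paths",
    "TX_TYPES",
    "BANDS",
]

TX_TYPES = ("standard", "evlp")
BANDS = ("year1", "year2", "year3plus")


class ParameterError(ValueError):
    """Raised for invalid model-parameter or distribution inputs."""


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling law for one uncertain parameter.

    family
        ``"beta"`` (shape_a=α, shape_b=β), ``"gamma"`` (shape_a=shape,
        shape_b=scale in GBP) or ``"fixed"`` (degenerate at ``point_value``).
    point_value
        Deterministic value used outside the PSA.  For several published
        rows the printed point value differs slightly from the printed
        distribution's mean; both are preserved as printed.
    """

    family: str
    shape_a: float
    shape_b: float
    point_value: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.family != "fixed":
            if not (self.shape_a > 0 and self.shape_b > 0):
                raise ParameterError("distribution shape parameters must be positive")
        if self.family == "beta" and not (0.0 <= self.point_value <= 1.0):
            raise ParameterError("beta point value must lie in [0, 1]")
        if self.family == "gamma" and self.point_value < 0:
            raise ParameterError("gamma point value must be non-negative")

    def mean(self) -> float:
        """Mean of the sampling law (not necessarily equal to point_value)."""
        if self.family == "beta":
            return self.shape_a / (self.shape_a + self.shape_b)
        if self.family == "gamma":
            return self.shape_a * self.shape_b
        return self.point_value

    def variance(self) -> float:
        if self.family == "beta":
            n = self.shape_a + self.shape_b
            return self.shape_a * self.shape_b / (n * n * (n + 1.0))
        if self.family == "gamma":
            return self.shape_a * self.shape_b**2
        return 0.0

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.family == "beta":
            return rng.beta(self.shape_a, self.shape_b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape_a, self.shape_b, size=size)
        if size is None:
            return self.point_value
        return np.full(size, self.point_value)

    def as_fixed(self) -> "DistributionSpec":
        """Zero-variance limit: degenerate at the point value."""
        return DistributionSpec("fixed", self.shape_a, self.shape_b, self.point_value)


def beta_from_mean_count(mean: float, effective_n: float) -> DistributionSpec:
    """Beta spec from a proportion and its effective sample size.

    α = mean·n, β = (1−mean)·n, so the distribution mean equals ``mean``
    exactly and α+β equals ``effective_n``.
    """
    if not (0.0 <= mean <= 1.0):
        raise ParameterError(f"mean {mean} outside [0, 1]")
    if not effective_n > 0:
        raise ParameterError(f"effective_n must be positive, got {effective_n}")
    if mean in (0.0, 1.0):
        raise ParameterError("degenerate proportion; use a fixed spec instead")
    return DistributionSpec("beta", mean * effective_n, (1.0 - mean) * effective_n, mean)


def beta_from_mean_variance(mean: float, variance: float) -> DistributionSpec:
    """Beta spec from a mean and variance (used for utility parameters)."""
    if not (0.0 < mean < 1.0):
        raise ParameterError(f"mean {mean} outside (0, 1)")
    if not (0.0 < variance < mean * (1.0 - mean)):
        raise ParameterError(
            f"variance {variance} not in (0, mean(1-mean)={mean * (1 - mean):.6g})"
        )
    k = mean * (1.0 - mean) / variance - 1.0
    return DistributionSpec("beta", mean * k, (1.0 - mean) * k, mean)


def gamma_from_mean_se(mean: float, se: float) -> DistributionSpec:
    """Gamma spec from a mean cost and the standard error of that mean."""
    if not mean > 0:
        raise ParameterError(f"mean must be positive, got {mean}")
    if not se > 0:
        raise ParameterError(f"se must be positive, got {se}")
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return DistributionSpec("gamma", shape, scale, mean)


def _beta_printed(point: float, alpha: float, beta: float) -> DistributionSpec:
    """Beta spec carrying the published α/β alongside the published point value."""
    return DistributionSpec("beta", alpha, beta, point)


def _gamma_printed(point: float, shape: float, scale: float) -> DistributionSpec:
    return DistributionSpec("gamma", shape, scale, point)


@dataclass
class TransitionBand:
    """Annual waiting-list exit probabilities for one registration-year band."""

    p_removed: float
    p_death: float
    p_std_tx: float

    def __post_init__(self) -> None:
        for name in ("p_removed", "p_death", "p_std_tx"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.p_removed + self.p_death + self.p_std_tx > 1.0 + 1e-12:
            raise ParameterError("band exit probabilities sum above 1")


@dataclass
class SurvivalPoints:
    """Post-transplant survival at 1/3/5/10 years with a maximum life expectancy.

    The survival curve is taken piecewise-linear through (0,1), the four
    points, and (t_max, 0); see :mod:`lungcea.survival`.
    """

    s1: float
    s3: float
    s5: float
    s10: float
    t_max: float = 25.0

    def __post_init__(self) -> None:
        vals = (1.0, self.s1, self.s3, self.s5, self.s10, 0.0)
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ParameterError("survival points must lie in [0, 1]")
        if any(a < b - 1e-12 for a, b in zip(vals, vals[1:-1])):
            raise ParameterError("survival points must be non-increasing")
        if not self.t_max > 10.0:
            raise ParameterError("t_max must exceed the last observed point (10 y)")


@dataclass
class UtilitySet:
    """SF-6D health-state utilities; transplant utilities are per transplant type."""

    u_wait: float
    u_tx_year1: dict[str, float]
    u_tx_post: dict[str, float]

    def __post_init__(self) -> None:
        for v in [self.u_wait, *self.u_tx_year1.values(), *self.u_tx_post.values()]:
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"utility {v} outside [0, 1]")


@dataclass
class CostSet:
    """Annual and episode costs in GBP; transplant costs are per transplant type."""

    c_wait_per_year: float
    c_tx: dict[str, float]
    c_post_year1: dict[str, float]
    c_post_year2: dict[str, float]
    c_post_year3plus: dict[str, float]

    def __post_init__(self) -> None:
        vals = [self.c_wait_per_year]
        for d in (self.c_tx, self.c_post_year1, self.c_post_year2, self.c_post_year3plus):
            vals.extend(d.values())
        if any(v < 0 for v in vals):
            raise ParameterError("costs must be non-negative")


@dataclass
class RemovedStateAccrual:
    """Optional terminal accrual for patients removed from the waiting list.

    By default removal is absorbing with no accrual; the exploratory analysis
    credits removed patients with a short palliative period before death.
    """

    months: float
    monthly_cost: float
    utility: float

    def __post_init__(self) -> None:
        if self.months < 0 or self.monthly_cost < 0:
            raise ParameterError("months and monthly_cost must be non-negative")
        if not (0.0 <= self.utility <= 1.0):
            raise ParameterError("utility outside [0, 1]")


@dataclass
class ModelParameters:
    """Complete parameter set for one model run.

    A single instance serves both service arms: the standard arm ignores
    ``evlp_uplift`` and the EVLP-specific slots.  ``psa_specs`` maps dotted
    parameter paths (e.g. ``"transitions.year1.p_std_tx"``) to the sampling
    laws used by the PSA.
    """

    transitions: dict[str, TransitionBand]
    evlp_uplift: float
    survival: dict[str, SurvivalPoints]
    utilities: UtilitySet
    costs: CostSet
    discount_rate: float = 0.035
    cohort_size: int = 1000
    horizon_years: int = 60
    conversion_ratio: tuple[int, int] = (53, 18)
    psa_specs: dict[str, DistributionSpec] = field(default_factory=dict)
    removed_accrual: Optional[RemovedStateAccrual] = None

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be non-negative")
        if self.horizon_years < 3:
            raise ParameterError("horizon_years must be at least 3")
        if self.cohort_size <= 0:
            raise ParameterError("cohort_size must be positive")
        if self.evlp_uplift < 0:
            raise ParameterError("evlp_uplift must be non-negative")
        missing = [b for b in BANDS if b not in self.transitions]
        if missing:
            raise ParameterError(f"missing transition bands: {missing}")

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def with_fixed_specs(self) -> "ModelParameters":
        """Zero-variance copy: every sampling law degenerates to its point value."""
        p = self.copy()
        p.psa_specs = {k: s.as_fixed() for k, s in p.psa_specs.items()}
        return p


# -- dotted-path access -------------------------------------------------------

def _step(obj: Any, key: str) -> Any:
    if isinstance(obj, dict):
        return obj[key]
    return getattr(obj, key)


def get_value(params: ModelParameters, path: str) -> float:
    """Read a scalar parameter by dotted path."""
    obj: Any = params
    for key in path.split("."):
        obj = _step(obj, key)
    return obj


def set_value(params: ModelParameters, path: str, value: float) -> None:
    """Set a scalar parameter by dotted path, in place."""
    keys = path.split(".")
    obj: Any = params
    for key in keys[:-1]:
        obj = _step(obj, key)
    if isinstance(obj, dict):
        if keys[-1] not in obj:
            raise ParameterError(f"unknown parameter path {path!r}")
        obj[keys[-1]] = value
    else:
        if not hasattr(obj, keys[-1]):
            raise ParameterError(f"unknown parameter path {path!r}")
        setattr(obj, keys[-1], value)


def iter_paths(params: ModelParameters) -> Iterator[str]:
    """All scalar parameter paths (used by serialization and field-diff tests)."""

    def walk(obj: Any, prefix: str) -> Iterator[str]:
        if isinstance(obj, dict):
            for k, v in obj.items():
                yield from walk(v, f"{prefix}{k}.")
        elif is_dataclass(obj) and not isinstance(obj, DistributionSpec):
            for f in fields(obj):
                yield from walk(getattr(obj, f.name), f"{prefix}{f.name}.")
        elif isinstance(obj, (int, float)):
            yield prefix[:-1]

    for f in fields(ModelParameters):
        if f.name in ("psa_specs", "conversion_ratio", "removed_accrual"):
            continue
        yield from walk(getattr(params, f.name), f"{f.name}.")


# -- published base case ------------------------------------------------------

# (point value, alpha, beta) for Beta rows; (point mean, shape, scale) for Gamma.
_BASE_BETAS: dict[str, tuple[float, float, float]] = {
    "transitions.year1.p_removed": (0.020, 5.02, 245.98),
    "transitions.year2.p_removed": (0.030, 2.51, 80.32),
    "transitions.year3plus.p_removed": (0.077, 2.51, 30.12),
    "transitions.year1.p_death": (0.150, 37.65, 213.35),
    "transitions.year2.p_death": (0.212, 17.57, 65.26),
    "transitions.year3plus.p_death": (0.077, 2.51, 30.12),
    "transitions.year1.p_std_tx": (0.510, 128.0, 122.99),
    "transitions.year2.p_std_tx": (0.364, 30.1, 52.71),
    "transitions.year3plus.p_std_tx": (0.462, 15.1, 17.57),
    "evlp_uplift": (0.10, 18.0, 184.0),
    "survival.standard.s1": (0.772, 257.91, 77.04),
    # The published 3-year row prints α=25.19 (implied mean 0.207), inconsistent
    # with its mean 0.72 and the other rows' effective n; refit at the printed
    # mean with the implied total count 321.7.
    "survival.standard.s3": (0.72, 0.72 * 321.7, 0.28 * 321.7),
    "survival.standard.s5": (0.53, 167.15, 148.23),
    "survival.standard.s10": (0.34, 116.90, 226.93),
    "utilities.u_wait": (0.563, 2292.2, 1782.4),
    "utilities.u_tx_year1.standard": (0.702, 465.8, 197.3),
    "utilities.u_tx_post.standard": (0.734, 439.7, 159.4),
}

_BASE_GAMMAS: dict[str, tuple[float, float, float]] = {
    "costs.c_wait_per_year": (23829.0, 103.1, 239.3),
    "costs.c_tx.standard": (51778.0, 304.2, 175.5),
    "costs.c_tx.evlp": (137527.0, 98.4, 1441.1),
    "costs.c_post_year1.standard": (9700.0, 93.5, 107.1),
    "costs.c_post_year2.standard": (3812.0, 93.4, 42.1),
    "costs.c_post_year3plus.standard": (3506.0, 93.4, 38.7),
    "costs.c_post_year1.evlp": (5919.0, 20.2, 302.7),
    "costs.c_post_year2.evlp": (2326.0, 20.2, 118.9),
    "costs.c_post_year3plus.evlp": (2140.0, 20.2, 109.4),
}

# Survival and utilities are common to both transplant types in the base case;
# the EVLP slots mirror the standard ones so scenario analyses can diverge them.
_MIRRORED: dict[str, str] = {
    "survival.evlp.s1": "survival.standard.s1",
    "survival.evlp.s3": "survival.standard.s3",
    "survival.evlp.s5": "survival.standard.s5",
    "survival.evlp.s10": "survival.standard.s10",
    "utilities.u_tx_year1.evlp": "utilities.u_tx_year1.standard",
    "utilities.u_tx_post.evlp": "utilities.u_tx_post.standard",
}


def load_base_case() -> ModelParameters:
    """The published base-case parameter set for both service arms.

    Point values equal the printed means; each uncertain parameter's
    ``psa_specs`` entry carries the printed Beta/Gamma parameters.
    """
    b = {k: v[0] for k, v in _BASE_BETAS.items()}
    g = {k: v[0] for k, v in _BASE_GAMMAS.items()}

    params = ModelParameters(
        transitions={
            band: TransitionBand(
                p_removed=b[f"transitions.{band}.p_removed"],
                p_death=b[f"transitions.{band}.p_death"],
                p_std_tx=b[f"transitions.{band}.p_std_tx"],
            )
            for band in BANDS
        },
        evlp_uplift=b["evlp_uplift"],
        survival={
            t: SurvivalPoints(
                s1=b["survival.standard.s1"],
                s3=b["survival.standard.s3"],
                s5=b["survival.standard.s5"],
                s10=b["survival.standard.s10"],
                t_max=25.0,
            )
            for t in TX_TYPES
        },
        utilities=UtilitySet(
            u_wait=b["utilities.u_wait"],
            u_tx_year1={t: b["utilities.u_tx_year1.standard"] for t in TX_TYPES},
            u_tx_post={t: b["utilities.u_tx_post.standard"] for t in TX_TYPES},
        ),
        costs=CostSet(
            c_wait_per_year=g["costs.c_wait_per_year"],
            c_tx={t: g[f"costs.c_tx.{t}"] for t in TX_TYPES},
            c_post_year1={t: g[f"costs.c_post_year1.{t}"] for t in TX_TYPES},
            c_post_year2={t: g[f"costs.c_post_year2.{t}"] for t in TX_TYPES},
            c_post_year3plus={t: g[f"costs.c_post_year3plus.{t}"] for t in TX_TYPES},
        ),
    )

    specs: dict[str, DistributionSpec] = {}
    for path, (point, a, bb) in _BASE_BETAS.items():
        specs[path] = _beta_printed(point, a, bb)
    for path, (point, sh, sc) in _BASE_GAMMAS.items():
        specs[path] = _gamma_printed(point, sh, sc)
    for path, src in _MIRRORED.items():
        specs[path] = specs[src]
    params.psa_specs = specs
    return params


# -- serialization ------------------------------------------------------------

def params_to_dict(params: ModelParameters) -> dict:
    """Flat, text-serializable representation (values, specs, settings)."""
    out: dict[str, Any] = {
        "values": {p: get_value(params, p) for p in iter_paths(params)},
        "specs": {
            path: {
                "family": s.family,
                "shape_a": s.shape_a,
                "shape_b": s.shape_b,
                "point_value": s.point_value,
            }
            for path, s in params.psa_specs.items()
        },
        "settings": {
            "cohort_size": params.cohort_size,
            "horizon_years": params.horizon_years,
            "conversion_ratio": list(params.conversion_ratio),
        },
    }
    if params.removed_accrual is not None:
        ra = params.removed_accrual
        out["removed_accrual"] = {
            "months": ra.months,
            "monthly_cost": ra.monthly_cost,
            "utility": ra.utility,
        }
    return out


def params_from_dict(data: dict) -> ModelParameters:
    """Inverse of :func:`params_to_dict` (starts from the base-case skeleton)."""
    params = load_base_case()
    for path, value in data.get("values", {}).items():
        if path.startswith(("cohort_size", "horizon_years")):
            setattr(params, path, int(value))
        else:
            set_value(params, path, float(value))
    if "specs" in data:
        params.psa_specs = {
            path: DistributionSpec(d["family"], d["shape_a"], d["shape_b"], d["point_value"])
            for path, d in data["specs"].items()
        }
    st = data.get("settings", {})
    if "cohort_size" in st:
        params.cohort_size = int(st["cohort_size"])
    if "horizon_years" in st:
        params.horizon_years = int(st["horizon_years"])
    if "conversion_ratio" in st:
        params.conversion_ratio = tuple(st["conversion_ratio"])
    if "removed_accrual" in data:
        ra = data["removed_accrual"]
        params.removed_accrual = RemovedStateAccrual(
            months=ra["months"], monthly_cost=ra["monthly_cost"], utility=ra["utility"]
        )
    return params
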