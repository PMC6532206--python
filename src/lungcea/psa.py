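"""Probabilistic sensitivity analysis.

Each draw samples every uncertain parameter from its assigned law (Beta for
probabilities and utilities, Gamma for costs) and runs BOTH service arms on
the same sampled parameter set (common random numbers): parameters the arms
share — transitions, survival, utilities, waiting-list cost — are by
construction identical across arms within a draw, which is what makes the
percentile intervals on the increments coherent.

Parameters that are duplicated per transplant type but represent a single
quantity (base-case survival and utilities, and any scenario that equalises
cost rows across types) are sampled once per draw; this is detected by the
declared shared groups below, which only bind while the two slots carry an
identical sampling law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .engine import ArmResult, run_deterministic
from .parameters import ModelParameters, ParameterError, set_value

__all__ = ["PSADraw", "PSAResult", "sample_parameters", "run_psa", "SHARED_GROUPS"]

# Parameter slots that represent one quantity duplicated per transplant type.
# A group shares a single draw only while its members' specs are identical.
SHARED_GROUPS: tuple[tuple[str, ...], ...] = (
    ("survival.standard.s1", "survival.evlp.s1"),
    ("survival.standard.s3", "survival.evlp.s3"),
    ("survival.standard.s5", "survival.evlp.s5"),
    ("survival.standard.s10", "survival.evlp.s10"),
    ("utilities.u_tx_year1.standard", "utilities.u_tx_year1.evlp"),
    ("utilities.u_tx_post.standard", "utilities.u_tx_post.evlp"),
    ("costs.c_tx.standard", "costs.c_tx.evlp"),
    ("costs.c_post_year1.standard", "costs.c_post_year1.evlp"),
    ("costs.c_post_year2.standard", "costs.c_post_year2.evlp"),
    ("costs.c_post_year3plus.standard", "costs.c_post_year3plus.evlp"),
)

_GROUP_OF = {p: g for g in SHARED_GROUPS for p in g}


def _clamp_survival(params: ModelParameters) -> None:
    # independent Beta draws can violate monotonicity; clamp sequentially
    for sp in params.survival.values():
        sp.s3 = min(sp.s3, sp.s1)
        sp.s5 = min(sp.s5, sp.s3)
        sp.s10 = min(sp.s10, sp.s5)


def sample_parameters(params: ModelParameters, rng: np.random.Generator) -> ModelParameters:
    """One PSA draw: a copy of ``params`` with every uncertain value sampled.

    Paths are visited in sorted order so draws are reproducible for a given
    seed; shared per-type slots with identical specs receive one draw.
    Sampled survival points are made monotone by sequential clamping; bands
    whose sampled exit probabilities sum above 1 are renormalized at run
    time by the engine.
    """
    out = params.copy()
    drawn: dict[int, float] = {}
    for path in sorted(params.psa_specs):
        spec = params.psa_specs[path]
        group = _GROUP_OF.get(path)
        key = None
        if group is not None and all(
            params.psa_specs.get(p) == spec for p in group if p in params.psa_specs
        ):
            key = id(SHARED_GROUPS) + SHARED_GROUPS.index(group)
        if key is not None and key in drawn:
            value = drawn[key]
        else:
            value = float(spec.sample(rng))
            if key is not None:
                drawn[key] = value
        set_value(out, path, value)
    _clamp_survival(out)
    return out


@dataclass
class PSADraw:
    """Paired arm results for one sampled parameter set."""

    params: ModelParameters
    standard: ArmResult
    evlp: ArmResult

    @property
    def inc_cost(self) -> float:
        return self.evlp.mean_cost - self.standard.mean_cost

    @property
    def inc_qaly(self) -> float:
        return self.evlp.mean_qaly - self.standard.mean_qaly

    @property
    def inc_ly(self) -> float:
        return self.evlp.mean_ly - self.standard.mean_ly


_SUMMARY_COLS = (
    "cost_standard",
    "cost_evlp",
    "qaly_standard",
    "qaly_evlp",
    "ly_standard",
    "ly_evlp",
    "inc_cost",
    "inc_qaly",
    "inc_ly",
)


@dataclass
class PSAResult:
    """All draws of one PSA run plus summary statistics."""

    draws: list[PSADraw]
    seed: int
    n_sims: int
    summary: dict[str, dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        frame = self.to_frame()
        self.summary = {
            col: {
                "mean": float(frame[col].mean()),
                "ci_lower": float(np.percentile(frame[col], 2.5)),
                "ci_upper": float(np.percentile(frame[col], 97.5)),
            }
            for col in _SUMMARY_COLS
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per draw: arm costs/QALYs/life-years and increments."""
        return pd.DataFrame(
            {
                "draw": np.arange(len(self.draws)),
                "cost_standard": [d.standard.mean_cost for d in self.draws],
                "cost_evlp": [d.evlp.mean_cost for d in self.draws],
                "qaly_standard": [d.standard.mean_qaly for d in self.draws],
                "qaly_evlp": [d.evlp.mean_qaly for d in self.draws],
                "ly_standard": [d.standard.mean_ly for d in self.draws],
                "ly_evlp": [d.evlp.mean_ly for d in self.draws],
                "inc_cost": [d.inc_cost for d in self.draws],
                "inc_qaly": [d.inc_qaly for d in self.draws],
                "inc_ly": [d.inc_ly for d in self.draws],
            }
        )

    @property
    def inc_cost(self) -> np.ndarray:
        return np.array([d.inc_cost for d in self.draws])

    @property
    def inc_qaly(self) -> np.ndarray:
        return np.array([d.inc_qaly for d in self.draws])

    @property
    def inc_ly(self) -> np.ndarray:
        return np.array([d.inc_ly for d in self.draws])


def run_psa(
    params: ModelParameters,
    n_sims: int = 1000,
    seed: int = 1234,
    params_evlp: Optional[ModelParameters] = None,
    evlp_arm_kind: str = "evlp",
    keep_traces: bool = False,
) -> PSAResult:
    """Run a paired probabilistic sensitivity analysis.

    Parameters
    ----------
    params
        Parameter set for the standard arm (and, by default, the EVLP arm).
    params_evlp
        Optional distinct parameter set for the EVLP-service arm (used by
        scenarios that diverge the arms).  Parameters whose sampling laws
        are identical in both sets receive common draws.
    evlp_arm_kind
        ``"evlp"`` normally; ``"standard"`` runs the second arm without
        EVLP transplants (used by the within-trial-activity scenario).
    """
    if n_sims < 2:
        raise ParameterError("n_sims must be at least 2")
    if not isinstance(seed, (int, np.integer)):
        raise ParameterError("seed must be an integer")
    rng = np.random.default_rng(int(seed))
    two_sets = params_evlp is not None and params_evlp is not params
    draws: list[PSADraw] = []
    _warned = False
    for _ in range(n_sims):
        sampled_std = sample_parameters(params, rng)
        if two_sets:
            sampled_evlp = _sample_second(params_evlp, params, sampled_std, rng)
        else:
            sampled_evlp = sampled_std
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", RuntimeWarning)
            res_std = run_deterministic(sampled_std, "standard")
            res_evlp = run_deterministic(sampled_evlp, evlp_arm_kind)
        if caught and not _warned:
            # boundary draws whose exit probabilities sum above 1 are
            # renormalized by the engine; report once per PSA run
            warnings.warn(
                f"some draws renormalized ({caught[0].message})", RuntimeWarning
            )
            _warned = True
        if not keep_traces:
            res_std.trace = None  # type: ignore[assignment]
            res_evlp.trace = None  # type: ignore[assignment]
        draws.append(PSADraw(params=sampled_evlp, standard=res_std, evlp=res_evlp))
    return PSAResult(draws=draws, seed=int(seed), n_sims=n_sims)


def _sample_second(
    params_b: ModelParameters,
    params_a: ModelParameters,
    sampled_a: ModelParameters,
    rng: np.random.Generator,
) -> ModelParameters:
    """Sample the second arm's set, reusing arm A's draws where specs agree."""
    from .parameters import get_value

    out = params_b.copy()
    for path in sorted(params_b.psa_specs):
        spec = params_b.psa_specs[path]
        if params_a.psa_specs.get(path) == spec:
            set_value(out, path, get_value(sampled_a, path))
        else:
            set_value(out, path, float(spec.sample(rng)))
    _clamp_survival(out)
    return out
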