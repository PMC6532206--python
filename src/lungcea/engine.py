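"""Deterministic Markov cohort engine for one service arm.

States: waiting list; removed from the list (absorbing, no accrual unless a
terminal-care accrual is configured); death (absorbing); receiving a
transplant (standard or EVLP); post-year-1 survival.  Cycle length is one
year; the cohort (1000 patients) starts on the waiting list and the run
continues until the list has drained (checked against the horizon).

Accrual convention (frozen; see docs/methods.md for the calibration):

* Waiting list.  Patients who remain listed through cycle ``t`` accrue a
  full year of waiting-list cost, utility and life-years at discount
  ``(1+r)^-(t-1)``.  Patients exiting during the cycle accrue half a year
  of waiting utility and life-years (they leave mid-cycle on average) and
  no waiting-list cost.
* Transplant.  The transplant episode cost (surgery, and for EVLP the
  assessment process scaled by the conversion ratio) is booked in the exit
  cycle.  The recovery year occupies the following cycle: one year at the
  year-1 utility, one life-year, and the year-1 post-transplant cost.
* Post year 1.  The fraction ``s1`` surviving the recovery year is
  credited the AUC mean post-transplant survival as additional whole years
  (final fraction prorated), at the 2-years-onwards utility, with the
  year-2 cost in the first such year and the year-3+ cost thereafter,
  discounted year by year.
* No half-cycle correction; transitions are constant from year 3 onwards.

Exit probabilities in the EVLP arm gain an extra EVLP-transplant exit equal
to ``uplift`` times the standard-transplant probability; if the four exit
probabilities ever sum above 1 they are renormalized proportionally and the
remain probability clamped at 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .parameters import ModelParameters, ParameterError, TransitionBand
from .survival import auc_mean_survival

__all__ = [
    "ARMS",
    "WaitingFlows",
    "CohortTrace",
    "ArmResult",
    "TruncationError",
    "discount_factor",
    "waiting_list_step",
    "run_deterministic",
]

ARMS = ("standard", "evlp")

_RESIDUAL_TOL = 1e-6  # persons; waiting-list residual allowed at the horizon


class TruncationError(RuntimeError):
    """Horizon too short: the waiting list has not drained."""


class WaitingFlows(NamedTuple):
    removed: float
    death: float
    std_tx: float
    evlp_tx: float
    remain: float


def discount_factor(year_index: int, rate: float) -> float:
    """Discount factor for model year ``year_index`` (first year undiscounted)."""
    if year_index < 1:
        raise ParameterError(f"year_index must be >= 1, got {year_index}")
    if rate < 0:
        raise ParameterError("rate must be non-negative")
    return (1.0 + rate) ** (-(year_index - 1))


def waiting_list_step(occupancy: float, band: TransitionBand, uplift: float) -> WaitingFlows:
    """One cycle of waiting-list exits for ``occupancy`` persons.

    The EVLP exit probability is ``uplift`` times the standard-transplant
    probability (0 in the standard arm).  If the exit probabilities sum
    above 1 the four exits are renormalized proportionally and the remain
    flow clamped to 0 (a warning is emitted).
    """
    if occupancy < 0:
        raise ParameterError("occupancy must be non-negative")
    if uplift < 0:
        raise ParameterError("uplift must be non-negative")
    p = np.array(
        [band.p_removed, band.p_death, band.p_std_tx, uplift * band.p_std_tx],
        dtype=float,
    )
    total = p.sum()
    if total > 1.0:
        warnings.warn(
            f"exit probabilities sum to {total:.4f} > 1; renormalizing",
            RuntimeWarning,
            stacklevel=2,
        )
        p /= total
        total = 1.0
    residual = 1.0 - total
    flows = occupancy * np.append(p, residual)
    return WaitingFlows(*flows)


@dataclass
class CohortTrace:
    """Per-cycle occupancies, flows and discounted accruals for one arm.

    Occupancies are persons (cohort scale); ``waiting_start`` is the list
    occupancy at the start of the cycle and ``waiting_end`` after exits.
    ``tx_std_year1``/``tx_evlp_year1`` hold the recovery-year occupancy
    (the previous cycle's entrants); ``tx_std_post``/``tx_evlp_post`` the
    cumulative post-year-1 survivors.  Accrual columns are discounted GBP /
    QALYs / life-years booked in the cycle, including the post-year-1
    streams of earlier entrants.
    """

    cycles: np.ndarray
    waiting_start: np.ndarray
    waiting_end: np.ndarray
    to_removed: np.ndarray
    to_death: np.ndarray
    to_std_tx: np.ndarray
    to_evlp_tx: np.ndarray
    tx_std_year1: np.ndarray
    tx_evlp_year1: np.ndarray
    tx_std_post: np.ndarray
    tx_evlp_post: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    disc_ly: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle table (one row per cycle)."""
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "waiting_start": self.waiting_start,
                "waiting_end": self.waiting_end,
                "to_removed": self.to_removed,
                "to_death": self.to_death,
                "to_std_tx": self.to_std_tx,
                "to_evlp_tx": self.to_evlp_tx,
                "tx_std_year1": self.tx_std_year1,
                "tx_evlp_year1": self.tx_evlp_year1,
                "tx_std_post": self.tx_std_post,
                "tx_evlp_post": self.tx_evlp_post,
                "disc_cost": self.disc_cost,
                "disc_qaly": self.disc_qaly,
                "disc_ly": self.disc_ly,
            }
        )


@dataclass
class ArmResult:
    """Discounted per-patient means and cohort transplant counts for one arm."""

    arm: str
    mean_cost: float
    mean_ly: float
    mean_qaly: float
    n_std_tx: float
    n_evlp_tx: float
    trace: CohortTrace


class _Bundle:
    """Per-entrant discounted accrual profile for one transplant type.

    Arrays are indexed by cycle offset from the exit cycle (0 = exit cycle,
    1 = recovery year, 2.. = post-year-1 stream) and hold accruals per unit
    entrant, discounted *relative to the exit cycle*.
    """

    def __init__(self, params: ModelParameters, tx_type: str) -> None:
        r = params.discount_rate
        nu = 1.0 / (1.0 + r)
        surv = params.survival[tx_type]
        s1 = surv.s1
        auc = auc_mean_survival(surv)
        n_full = int(math.floor(auc))
        frac = auc - n_full

        length = n_full + 3
        cost = np.zeros(length)
        qaly = np.zeros(length)
        ly = np.zeros(length)

        cost[0] = params.costs.c_tx[tx_type]
        cost[1] = nu * params.costs.c_post_year1[tx_type]
        qaly[1] = nu * params.utilities.u_tx_year1[tx_type]
        ly[1] = nu

        u_post = params.utilities.u_tx_post[tx_type]
        c2 = params.costs.c_post_year2[tx_type]
        c3 = params.costs.c_post_year3plus[tx_type]
        for j in range(1, n_full + 1):
            d = nu ** (1 + j)  # year j of the post stream, after the recovery year
            c = c2 if j == 1 else c3
            cost[1 + j] += s1 * d * c
            qaly[1 + j] += s1 * d * u_post
            ly[1 + j] += s1 * d
        if frac > 0:
            d = nu ** (2 + n_full)
            c = c2 if n_full == 0 else c3
            cost[2 + n_full] += s1 * d * frac * c
            qaly[2 + n_full] += s1 * d * frac * u_post
            ly[2 + n_full] += s1 * d * frac

        self.cost, self.qaly, self.ly = cost, qaly, ly
        self.s1 = s1
        self.length = length


def run_deterministic(params: ModelParameters, arm: str) -> ArmResult:
    """Run the cohort model for one service arm at the parameter point values."""
    if arm not in ARMS:
        raise ParameterError(f"arm must be one of {ARMS}, got {arm!r}")
    uplift = params.evlp_uplift if arm == "evlp" else 0.0
    n = params.cohort_size
    horizon = params.horizon_years
    r = params.discount_rate

    bundles = {t: _Bundle(params, t) for t in ("standard", "evlp")}
    max_tail = max(b.length for b in bundles.values())
    span = horizon + max_tail + 1

    cost = np.zeros(span)
    qaly = np.zeros(span)
    ly = np.zeros(span)

    w_start = np.zeros(horizon + 1)
    w_end = np.zeros(horizon + 1)
    f_rem = np.zeros(horizon + 1)
    f_die = np.zeros(horizon + 1)
    f_std = np.zeros(horizon + 1)
    f_evlp = np.zeros(horizon + 1)

    u_wait = params.utilities.u_wait
    c_wait = params.costs.c_wait_per_year
    ra = params.removed_accrual

    occ = float(n)
    for t in range(1, horizon + 1):
        band = params.transitions["year1" if t == 1 else "year2" if t == 2 else "year3plus"]
        flows = waiting_list_step(occ, band, uplift)
        df = discount_factor(t, r)

        w_start[t] = occ
        w_end[t] = flows.remain
        f_rem[t], f_die[t] = flows.removed, flows.death
        f_std[t], f_evlp[t] = flows.std_tx, flows.evlp_tx

        # waiting-list accrual: full year for remainers, half for exiters, no
        # waiting cost for exiters
        exits = occ - flows.remain
        cost[t] += df * c_wait * flows.remain
        qaly[t] += df * u_wait * (flows.remain + 0.5 * exits)
        ly[t] += df * (flows.remain + 0.5 * exits)

        # transplant bundles, discounted relative to the exit cycle
        for tx_type, entrants in (("standard", flows.std_tx), ("evlp", flows.evlp_tx)):
            if entrants > 0:
                b = bundles[tx_type]
                sl = slice(t, t + b.length)
                cost[sl] += df * entrants * b.cost
                qaly[sl] += df * entrants * b.qaly
                ly[sl] += df * entrants * b.ly

        # optional terminal accrual for removed patients (exploratory analysis)
        if ra is not None and flows.removed > 0:
            yrs = ra.months / 12.0
            cost[t] += df * flows.removed * ra.months * ra.monthly_cost
            qaly[t] += df * flows.removed * yrs * ra.utility
            ly[t] += df * flows.removed * yrs

        occ = flows.remain

    if occ > _RESIDUAL_TOL * n:
        raise TruncationError(
            f"waiting-list residual {occ:.3g} persons after {horizon} cycles; "
            "increase horizon_years"
        )

    n_std = float(f_std.sum())
    n_evlp = float(f_evlp.sum())

    cycles = np.arange(1, span)
    year1_std = np.zeros(span)
    year1_evlp = np.zeros(span)
    year1_std[2 : horizon + 2] = f_std[1:]
    year1_evlp[2 : horizon + 2] = f_evlp[1:]
    post_std = np.cumsum(np.roll(year1_std, 1)) * bundles["standard"].s1
    post_evlp = np.cumsum(np.roll(year1_evlp, 1)) * bundles["evlp"].s1

    def pad(a: np.ndarray) -> np.ndarray:
        out = np.zeros(span)
        out[: len(a)] = a
        return out

    trace = CohortTrace(
        cycles=cycles,
        waiting_start=pad(w_start)[1:],
        waiting_end=pad(w_end)[1:],
        to_removed=pad(f_rem)[1:],
        to_death=pad(f_die)[1:],
        to_std_tx=pad(f_std)[1:],
        to_evlp_tx=pad(f_evlp)[1:],
        tx_std_year1=year1_std[1:],
        tx_evlp_year1=year1_evlp[1:],
        tx_std_post=post_std[1:],
        tx_evlp_post=post_evlp[1:],
        disc_cost=cost[1:],
        disc_qaly=qaly[1:],
        disc_ly=ly[1:],
    )
    return ArmResult(
        arm=arm,
        mean_cost=float(cost.sum()) / n,
        mean_ly=float(ly.sum()) / n,
        mean_qaly=float(qaly.sum()) / n,
        n_std_tx=n_std,
        n_evlp_tx=n_evlp,
        trace=trace,
    )
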