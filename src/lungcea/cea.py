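"""Cost-effectiveness statistics: ICER, net monetary benefit, CE plane, CEAC.

Two-strategy comparisons only (EVLP service vs standard service).  The ICER
divides the difference in mean costs by the difference in mean effects;
dominance (cheaper and more effective, or dearer and less effective) is
flagged instead of reporting a ratio.  The cost-effectiveness acceptability
curve is computed by net-monetary-benefit comparison per draw, with ties
resolved in favour of the comparator (the standard service).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .parameters import ParameterError
from .psa import PSAResult

__all__ = [
    "ICERResult",
    "icer",
    "net_monetary_benefit",
    "ce_plane_shares",
    "ceac",
    "CEACCurve",
    "IncrementalResult",
    "summarize_incrementals",
    "default_wtp_grid",
    "plot_ce_plane",
    "plot_ceac",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness ratio, or a dominance flag.

    ``ratio`` is GBP per effect unit when defined; ``flag`` is one of
    ``"dominant"`` (less costly, more effective), ``"dominated"`` (more
    costly, less effective) or ``"undefined"`` (zero effect difference).
    """

    ratio: Optional[float]
    flag: Optional[str] = None

    def rounded(self, nearest: float = 1000.0) -> Optional[float]:
        """Presentation rounding to the nearest ``nearest`` GBP."""
        if self.ratio is None:
            return None
        return round(self.ratio / nearest) * nearest

    def __str__(self) -> str:
        if self.flag is not None:
            return self.flag
        return f"{self.ratio:,.0f}"


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """ICER of the intervention vs the comparator, with dominance handling."""
    if delta_effect == 0.0:
        if delta_cost == 0.0:
            return ICERResult(ratio=0.0)
        return ICERResult(ratio=None, flag=UNDEFINED)
    if delta_effect > 0 and delta_cost <= 0:
        return ICERResult(ratio=None, flag=DOMINANT)
    if delta_effect < 0 and delta_cost >= 0:
        return ICERResult(ratio=None, flag=DOMINATED)
    return ICERResult(ratio=delta_cost / delta_effect)


def net_monetary_benefit(cost, qaly, wtp: float):
    """NMB = wtp · qaly − cost (scalar or elementwise on arrays)."""
    if wtp < 0:
        raise ParameterError("willingness-to-pay must be non-negative")
    return wtp * np.asarray(qaly) - np.asarray(cost)


def _increments(draws: Union[PSAResult, Sequence]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(draws, PSAResult):
        return draws.inc_cost, draws.inc_qaly
    dc = np.array([d.inc_cost for d in draws])
    dq = np.array([d.inc_qaly for d in draws])
    return dc, dq


def ce_plane_shares(draws: Union[PSAResult, Sequence]) -> dict[str, float]:
    """Fraction of PSA draws in each cost-effectiveness-plane quadrant.

    Quadrants by sign of (incremental cost, incremental QALYs) for the EVLP
    service; boundary draws are assigned against the intervention (zero
    incremental QALYs counts as west, zero incremental cost as north).
    """
    dc, dq = _increments(draws)
    if len(dc) == 0:
        raise ParameterError("at least one draw is required")
    north = dc >= 0
    east = dq > 0
    n = float(len(dc))
    return {
        "NE": float(np.sum(north & east)) / n,
        "NW": float(np.sum(north & ~east)) / n,
        "SE": float(np.sum(~north & east)) / n,
        "SW": float(np.sum(~north & ~east)) / n,
    }


@dataclass
class CEACCurve:
    """Probability each service is cost-effective across a WTP grid."""

    wtp: np.ndarray
    p_evlp: np.ndarray
    p_standard: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp, "p_evlp": self.p_evlp, "p_standard": self.p_standard}
        )

    def at(self, wtp: float) -> tuple[float, float]:
        """(p_evlp, p_standard) at the grid point closest to ``wtp``."""
        i = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.p_evlp[i]), float(self.p_standard[i])


def default_wtp_grid() -> np.ndarray:
    """£0–£150,000 per QALY in £1,000 steps."""
    return np.arange(0.0, 150001.0, 1000.0)


def ceac(draws: Union[PSAResult, Sequence], wtp_grid: Optional[Sequence[float]] = None) -> CEACCurve:
    """Cost-effectiveness acceptability curve by per-draw NMB comparison.

    At each willingness-to-pay the EVLP service wins a draw only if its net
    monetary benefit is strictly greater (ties favour the standard service).
    """
    dc, dq = _increments(draws)
    if len(dc) == 0:
        raise ParameterError("at least one draw is required")
    grid = np.asarray(default_wtp_grid() if wtp_grid is None else wtp_grid, dtype=float)
    if np.any(grid < 0):
        raise ParameterError("WTP values must be non-negative")
    # EVLP NMB minus standard NMB = wtp*dq - dc
    p_evlp = np.array([float(np.mean(w * dq - dc > 0)) for w in grid])
    return CEACCurve(wtp=grid, p_evlp=p_evlp, p_standard=1.0 - p_evlp)


@dataclass
class IncrementalResult:
    """Mean increments (EVLP − standard) with percentile CIs and ICERs."""

    inc_cost: float
    inc_cost_ci: tuple[float, float]
    inc_qaly: float
    inc_qaly_ci: tuple[float, float]
    inc_ly: float
    inc_ly_ci: tuple[float, float]
    icer_qaly: ICERResult
    icer_ly: ICERResult


def summarize_incrementals(result: PSAResult) -> IncrementalResult:
    """Increments summarized over draws; ICERs from the summary means."""
    s = result.summary
    return IncrementalResult(
        inc_cost=s["inc_cost"]["mean"],
        inc_cost_ci=(s["inc_cost"]["ci_lower"], s["inc_cost"]["ci_upper"]),
        inc_qaly=s["inc_qaly"]["mean"],
        inc_qaly_ci=(s["inc_qaly"]["ci_lower"], s["inc_qaly"]["ci_upper"]),
        inc_ly=s["inc_ly"]["mean"],
        inc_ly_ci=(s["inc_ly"]["ci_lower"], s["inc_ly"]["ci_upper"]),
        icer_qaly=icer(s["inc_cost"]["mean"], s["inc_qaly"]["mean"]),
        icer_ly=icer(s["inc_cost"]["mean"], s["inc_ly"]["mean"]),
    )


def plot_ce_plane(result: PSAResult, path: str) -> None:
    """Scatter of (incremental QALYs, incremental cost) across draws."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dc, dq = result.inc_cost, result.inc_qaly
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=6, alpha=0.5)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (GBP)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path: str) -> None:
    """CEAC for both services against willingness-to-pay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.p_standard, label="Standard service")
    ax.plot(curve.wtp, curve.p_evlp, label="EVLP service")
    ax.set_xlabel("Willingness-to-pay (GBP per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
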