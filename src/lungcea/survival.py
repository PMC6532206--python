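"""Area-under-the-curve survival extrapolation.

Post-transplant survival enters the Markov model without tunnel states:
the published survival points at 1, 3, 5 and 10 years are joined piecewise
linearly, anchored at S(0)=1 and S(t_max)=0 (maximum life expectancy after
transplant, 25 years in the base case), and the area under that curve is
the mean post-transplant survival credited to recipients.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterError, SurvivalPoints

__all__ = ["MeanSurvival", "auc_mean_survival", "expected_post_year1_years", "mean_survival"]


@dataclass(frozen=True)
class MeanSurvival:
    """AUC decomposition of mean post-transplant survival (undiscounted years).

    auc_total
        Mean survival from transplant (area under the whole curve).
    auc_year1
        Area over [0, 1]: expected years lived in the first post-transplant
        year, 0.5·(1+s1) under the linear curve.
    e_post
        Expected additional years beyond year 1, conditional on surviving
        year 1: (auc_total − auc_year1) / s1.
    """

    auc_total: float
    auc_year1: float
    e_post: float


def _knots(points: SurvivalPoints) -> list[tuple[float, float]]:
    return [
        (0.0, 1.0),
        (1.0, points.s1),
        (3.0, points.s3),
        (5.0, points.s5),
        (10.0, points.s10),
        (points.t_max, 0.0),
    ]


def auc_mean_survival(points: SurvivalPoints) -> float:
    """Trapezoid area under the piecewise-linear survival curve, in years."""
    knots = _knots(points)
    svals = [s for _, s in knots]
    if any(a < b - 1e-12 for a, b in zip(svals, svals[1:-1])):
        raise ParameterError("survival points must be non-increasing")
    return sum(
        0.5 * (s0 + s1) * (t1 - t0)
        for (t0, s0), (t1, s1) in zip(knots, knots[1:])
    )


def expected_post_year1_years(auc_total: float, s1: float) -> float:
    """Mean years lived beyond year 1 among year-1 survivors.

    The unconditional AUC splits into the year-1 area 0.5·(1+s1) plus
    s1 times this conditional remainder.
    """
    if s1 <= 0.0:
        raise ZeroDivisionError("s1 must be positive to condition on year-1 survival")
    auc_year1 = 0.5 * (1.0 + s1)
    if auc_total < auc_year1 - 1e-12:
        raise ParameterError(
            f"auc_total {auc_total} below the year-1 area {auc_year1:.4f}"
        )
    return max(auc_total - auc_year1, 0.0) / s1


def mean_survival(points: SurvivalPoints) -> MeanSurvival:
    """Full AUC decomposition for one set of survival points."""
    total = auc_mean_survival(points)
    year1 = 0.5 * (1.0 + points.s1)
    return MeanSurvival(
        auc_total=total,
        auc_year1=year1,
        e_post=expected_post_year1_years(total, points.s1),
    )
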