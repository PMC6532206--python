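"""Independent oracles used by the test suite.

These deliberately avoid the cohort engine's code paths: a per-patient
Monte-Carlo microsimulation of the same decision process, and closed-form
expressions for cumulative transplant counts.
"""

from __future__ import annotations

import math

import numpy as np

from lungcea import ModelParameters, auc_mean_survival


def geometric_tail_std_transplants(params: ModelParameters) -> float:
    """Closed-form cumulative standard transplants per cohort member.

    p1 + r1·p2 + r1·r2·p3/(1−r3) with pi the band transplant probability and
    ri the band remain probability (standard arm, no uplift).
    """
    b1, b2, b3 = (params.transitions[b] for b in ("year1", "year2", "year3plus"))
    r = [1.0 - (b.p_removed + b.p_death + b.p_std_tx) for b in (b1, b2, b3)]
    return b1.p_std_tx + r[0] * b2.p_std_tx + r[0] * r[1] * b3.p_std_tx / (1.0 - r[2])


def microsimulate(
    params: ModelParameters, arm: str, n_patients: int, seed: int
) -> dict[str, float]:
    """Per-patient Monte-Carlo simulation of one arm under the same rules.

    Each patient's waiting-list path is sampled year by year; transplant
    recipients accrue the surgery cost in the exit year, a full recovery
    year the following year, and (with probability s1) the AUC mean
    survival as further years.  Returns means and standard errors.
    """
    rng = np.random.default_rng(seed)
    uplift = params.evlp_uplift if arm == "evlp" else 0.0
    r = params.discount_rate
    nu = 1.0 / (1.0 + r)
    horizon = params.horizon_years

    exit_year = np.zeros(n_patients, dtype=int)
    exit_kind = np.full(n_patients, -1, dtype=int)  # 0 rm, 1 death, 2 std, 3 evlp
    waiting = np.ones(n_patients, dtype=bool)
    for t in range(1, horizon + 1):
        band = params.transitions[
            "year1" if t == 1 else "year2" if t == 2 else "year3plus"
        ]
        p = np.array(
            [band.p_removed, band.p_death, band.p_std_tx, uplift * band.p_std_tx]
        )
        if p.sum() > 1.0:
            p = p / p.sum()
        edges = np.cumsum(p)
        u = rng.random(n_patients)
        for kind in range(4):
            lo = 0.0 if kind == 0 else edges[kind - 1]
            hit = waiting & (u >= lo) & (u < edges[kind])
            exit_year[hit] = t
            exit_kind[hit] = kind
        waiting &= u >= edges[3]
        if not waiting.any():
            break
    assert not waiting.any(), "horizon too short for microsimulation"

    df_exit = nu ** (exit_year - 1)

    # waiting-list years fully waited, discounted: sum_{t=1..exit-1} nu^(t-1)
    full_years = exit_year - 1
    disc_full = np.where(
        full_years > 0, (1.0 - nu**full_years) / (1.0 - nu), 0.0
    )

    cost = params.costs.c_wait_per_year * disc_full
    qaly = params.utilities.u_wait * (disc_full + 0.5 * df_exit)
    ly = disc_full + 0.5 * df_exit

    n_std = 0.0
    n_evlp = 0.0
    for kind, tx in ((2, "standard"), (3, "evlp")):
        mask = exit_kind == kind
        m = int(mask.sum())
        if m == 0:
            continue
        if kind == 2:
            n_std = m
        else:
            n_evlp = m
        surv = params.survival[tx]
        auc = auc_mean_survival(surv)
        n_full = int(math.floor(auc))
        frac = auc - n_full
        # discounted post-stream relative to the recovery year
        disc_stream = nu * (1.0 - nu**n_full) / (1.0 - nu) + frac * nu ** (n_full + 1)
        cost_stream = params.costs.c_post_year2[tx] * nu + params.costs.c_post_year3plus[
            tx
        ] * (disc_stream - nu)

        d = df_exit[mask]
        survives = rng.random(m) < surv.s1
        cost[mask] += d * (
            params.costs.c_tx[tx]
            + nu * params.costs.c_post_year1[tx]
            + nu * np.where(survives, cost_stream, 0.0)
        )
        qaly[mask] += d * nu * (
            params.utilities.u_tx_year1[tx]
            + params.utilities.u_tx_post[tx] * np.where(survives, disc_stream, 0.0)
        )
        ly[mask] += d * nu * (1.0 + np.where(survives, disc_stream, 0.0))

    out = {}
    for name, vals in (("cost", cost), ("qaly", qaly), ("ly", ly)):
        out[f"mean_{name}"] = float(vals.mean())
        out[f"se_{name}"] = float(vals.std(ddof=1) / math.sqrt(n_patients))
    out["n_std_tx"] = n_std / n_patients
    out["n_evlp_tx"] = n_evlp / n_patients
    return out
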