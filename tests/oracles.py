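"""Independent oracles used by the test suite.

These recompute the same quantities as the package through entirely
different routes (explicit design-matrix projections, textbook closed
forms, forward simulation, leave-one-out refits) so agreement is evidence
of correctness rather than of shared code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def forward_depletion_cycle(
    supply: float, uptake_conc: float, v_cap: float, v_t: float
) -> float:
    """Simulate one pour-through cycle forward; return the leachate assay.

    The plant absorbs ``uptake_conc * v_t`` mg while transpiring ``v_t`` L
    out of ``v_cap`` L held at capacity; the DI refill restores the volume,
    diluting the residual mass back over ``v_cap``.
    """
    supplied_mass = supply * v_cap
    absorbed_mass = uptake_conc * v_t
    residual_mass = supplied_mass - absorbed_mass
    return residual_mass / v_cap


def welch_closed_form(a, b) -> tuple[float, float, float]:
    """Textbook Welch t, Welch-Satterthwaite df and two-tailed p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of an OLS projection onto span(x)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def split_plot_projection_ss(df: pd.DataFrame) -> dict[str, float]:
    """Split-plot sums of squares by sequential design-matrix projections.

    ``df`` needs columns subject, group, time, value (balanced layout).
    Effects are added in the order intercept, group, subject, time,
    group:time; in the balanced design the increments are the classical
    strata SS.
    """
    df = df.sort_values(["group", "subject", "time"], kind="stable")
    y = df["value"].to_numpy(dtype=float)
    one = np.ones((len(df), 1))
    g = pd.get_dummies(df["group"], dtype=float).to_numpy()
    s = pd.get_dummies(df["subject"], dtype=float).to_numpy()
    t = pd.get_dummies(df["time"], dtype=float).to_numpy()
    gt = pd.get_dummies(
        df["group"].astype(str) + ":" + df["time"].astype(str), dtype=float
    ).to_numpy()
    st = pd.get_dummies(
        df["subject"].astype(str) + ":" + df["time"].astype(str), dtype=float
    ).to_numpy()

    rss_1 = _rss(one, y)
    rss_g = _rss(np.hstack([one, g]), y)
    rss_s = _rss(np.hstack([one, s]), y)
    rss_st_main = _rss(np.hstack([one, s, t]), y)
    rss_full = _rss(np.hstack([one, s, t, gt]), y)
    rss_sat = _rss(st, y)  # saturated: exact fit, RSS ~ 0
    return {
        "group": rss_1 - rss_g,
        "subject_error": rss_g - rss_s,
        "time": rss_s - rss_st_main,
        "group:time": rss_st_main - rss_full,
        "residual": rss_full - rss_sat,
    }


def cooks_distance_loo(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distance by literal leave-one-out refits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    s2 = float((y - fitted) @ (y - fitted)) / (n - p)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i, *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
        diff = fitted - x @ beta_i
        out[i] = float(diff @ diff) / (p * s2)
    return out
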