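"""Statistical layer: repeated-measures ANOVA, marginal-mean contrasts,
Welch tests and influence diagnostics.

The uptake trial is a balanced split-plot: cultivar is a between-subjects
factor, sampling date a within-subjects factor, and replicate plants are
the subjects, nested in cultivar.  For the balanced complete layout the
mixed-model sums of squares have closed forms over cell means, which is
what :func:`rm_anova` implements:

* between-subjects stratum — cultivar tested against subject-within-
  cultivar error,
* within stratum — date and cultivar x date tested against the
  subject x date residual.

The uncorrected univariate F is reported (matching common practice when no
sphericity correction is stated), with the Greenhouse-Geisser epsilon
attached for information.  Pairwise marginal-mean contrasts use the
appropriate stratum mean squares and a Bonferroni familywise adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import DegenerateInputError, InvalidInputError, UnbalancedDesignError

#: Reporting floor for p-values.
P_FLOOR = 1e-16


def _floor_p(p: float) -> float:
    return float(max(p, P_FLOOR))


# ---------------------------------------------------------------------------
# Design container
# ---------------------------------------------------------------------------


@dataclass
class RMDesign:
    """Balanced repeated-measures layout for one response variable.

    ``data`` needs columns ``subject``, ``group`` (between factor),
    ``time`` (within factor) and ``value``.  Every subject x time cell must
    be present exactly once, subjects must be nested in groups, and groups
    must hold equally many subjects.
    """

    data: pd.DataFrame
    groups: tuple = field(init=False)
    times: tuple = field(init=False)
    subjects: tuple = field(init=False)
    n_per_group: int = field(init=False)

    def __post_init__(self) -> None:
        required = {"subject", "group", "time", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise InvalidInputError(f"RMDesign missing columns: {sorted(missing)}")
        df = self.data
        nesting = df.groupby("subject")["group"].nunique()
        if (nesting > 1).any():
            raise UnbalancedDesignError("each subject must belong to exactly one group")
        counts = df.groupby(["subject", "time"], sort=False).size()
        if (counts != 1).any():
            raise UnbalancedDesignError(
                "design is unbalanced: every subject x time cell must appear "
                "exactly once (handle missing data listwise upstream)"
            )
        times = tuple(sorted(df["time"].unique()))
        per_subject = df.groupby("subject")["time"].nunique()
        if (per_subject != len(times)).any():
            raise UnbalancedDesignError("every subject must be observed at every time")
        sizes = df.drop_duplicates("subject").groupby("group").size()
        if sizes.nunique() != 1:
            raise UnbalancedDesignError("groups must contain equally many subjects")
        self.groups = tuple(sorted(df["group"].unique()))
        self.times = times
        self.subjects = tuple(sorted(df["subject"].unique()))
        self.n_per_group = int(sizes.iloc[0])

    def cube(self) -> np.ndarray:
        """Responses as an array shaped (groups, subjects-per-group, times)."""
        wide = self.data.pivot_table(
            index=["group", "subject"], columns="time", values="value", sort=True
        )
        g, n, t = len(self.groups), self.n_per_group, len(self.times)
        return wide.to_numpy().reshape(g, n, t)


# ---------------------------------------------------------------------------
# Welch's two-sample t-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Welch's two-sample t-test (unpooled variances, two-tailed).

    Degrees of freedom follow Welch-Satterthwaite; with equal sizes and
    variances this reduces to the Student df ``n1 + n2 - 2``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
        raise DegenerateInputError("a sample has zero variance; Welch t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=_floor_p(res.pvalue))


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Split-plot ANOVA results plus stratum error terms.

    ``table`` rows: group, subject_error, time, group:time, residual with
    SS, df, MS, F, p.  ``gg_epsilon`` is the Greenhouse-Geisser sphericity
    estimate (informational; F and p are uncorrected).  ``degenerate`` is
    set when an error stratum has zero mean square, in which case F and p
    are NaN rather than infinite.
    """

    table: pd.DataFrame
    gg_epsilon: float
    degenerate: bool

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _gg_epsilon(cube: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    g, n, t = cube.shape
    if t < 2:
        return 1.0
    centered = cube - cube.mean(axis=1, keepdims=True)  # remove group profiles
    flat = centered.reshape(g * n, t)
    dof = g * (n - 1)
    if dof < 1:
        return 1.0
    s = flat.T @ flat / dof
    m = np.eye(t) - np.ones((t, t)) / t
    ms = m @ s @ m
    tr = np.trace(ms)
    denom = (t - 1) * np.trace(ms @ ms)
    if denom <= 0:
        return 1.0
    return float(tr**2 / denom)


def rm_anova(design: RMDesign) -> AnovaTable:
    """Univariate mixed-model ANOVA for the balanced group x time layout."""
    cube = design.cube()
    g, n, t = cube.shape
    if g < 2 or n < 2 or t < 2:
        raise InvalidInputError(
            "rm_anova needs >= 2 groups, >= 2 subjects per group, >= 2 times"
        )
    gm = cube.mean()
    subj_means = cube.mean(axis=2)  # (g, n)
    group_means = cube.mean(axis=(1, 2))  # (g,)
    time_means = cube.mean(axis=(0, 1))  # (t,)
    cell_means = cube.mean(axis=1)  # (g, t)

    ss_total = float(((cube - gm) ** 2).sum())
    ss_subjects = float(t * ((subj_means - gm) ** 2).sum())
    ss_group = float(n * t * ((group_means - gm) ** 2).sum())
    ss_subj_err = ss_subjects - ss_group
    ss_time = float(g * n * ((time_means - gm) ** 2).sum())
    ss_cells = float(n * ((cell_means - gm) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_time
    ss_resid = ss_total - ss_subjects - ss_time - ss_inter

    df_group = g - 1
    df_subj = g * (n - 1)
    df_time = t - 1
    df_inter = (g - 1) * (t - 1)
    df_resid = g * (n - 1) * (t - 1)

    ms_subj = ss_subj_err / df_subj
    ms_resid = ss_resid / df_resid
    degenerate = ms_subj <= 0 or ms_resid <= 0

    def f_and_p(ss: float, df1: int, ms_err: float, df2: int) -> tuple[float, float]:
        if ms_err <= 0:
            return float("nan"), float("nan")
        f = (ss / df1) / ms_err
        return f, _floor_p(sps.f.sf(f, df1, df2))

    f_g, p_g = f_and_p(ss_group, df_group, ms_subj, df_subj)
    f_t, p_t = f_and_p(ss_time, df_time, ms_resid, df_resid)
    f_i, p_i = f_and_p(ss_inter, df_inter, ms_resid, df_resid)

    table = pd.DataFrame(
        {
            "SS": [ss_group, ss_subj_err, ss_time, ss_inter, ss_resid],
            "df": [df_group, df_subj, df_time, df_inter, df_resid],
            "MS": [
                ss_group / df_group,
                ms_subj,
                ss_time / df_time,
                ss_inter / df_inter,
                ms_resid,
            ],
            "F": [f_g, np.nan, f_t, f_i, np.nan],
            "p": [p_g, np.nan, p_t, p_i, np.nan],
        },
        index=["group", "subject_error", "time", "group:time", "residual"],
    )
    return AnovaTable(table=table, gg_epsilon=_gg_epsilon(cube), degenerate=degenerate)


# ---------------------------------------------------------------------------
# Pairwise marginal-mean contrasts with Bonferroni adjustment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseComparison:
    contrast: str
    estimate: float
    se: float
    df: float
    t: float
    p_raw: float
    p_adjusted: float


def pairwise_emmeans_bonferroni(
    design: RMDesign, family: str = "group_within_time"
) -> list[PairwiseComparison]:
    """Pairwise estimated-marginal-mean contrasts, Bonferroni-adjusted.

    Families:

    * ``"group_within_time"`` — all group pairs at each time (default; the
      per-element family is then m = number of times for two groups).
      The standard error for a between-group difference at a fixed time
      combines both error strata,
      ``SE^2 = 2 * [(t-1) * MS_resid + MS_subj] / (t * n)``, with
      Satterthwaite-combined df.
    * ``"time_within_group"`` — all time pairs inside each group, a pure
      within-stratum contrast: ``SE^2 = 2 * MS_resid / n``.

    Adjusted p = min(1, m * p_raw) with m the family size.
    """
    anova = rm_anova(design)
    if anova.degenerate:
        raise DegenerateInputError("error strata are zero; contrasts undefined")
    cube = design.cube()
    g, n, t = cube.shape
    cell = cube.mean(axis=1)  # (g, t)
    ms_subj = anova.table.loc["subject_error", "MS"]
    ms_resid = anova.table.loc["residual", "MS"]
    df_subj = anova.table.loc["subject_error", "df"]
    df_resid = anova.table.loc["residual", "df"]

    comparisons: list[PairwiseComparison] = []
    if family == "group_within_time":
        var_num = (t - 1) * ms_resid + ms_subj
        se = float(np.sqrt(2.0 * var_num / (t * n)))
        # Satterthwaite combination of the two strata.
        df = var_num**2 / (
            ((t - 1) * ms_resid) ** 2 / df_resid + ms_subj**2 / df_subj
        )
        for k, time in enumerate(design.times):
            for i, j in combinations(range(g), 2):
                est = float(cell[i, k] - cell[j, k])
                comparisons.append(
                    _compare(
                        f"{design.groups[i]} - {design.groups[j]} @ {time}",
                        est,
                        se,
                        float(df),
                    )
                )
    elif family == "time_within_group":
        se = float(np.sqrt(2.0 * ms_resid / n))
        for i, group in enumerate(design.groups):
            for k, l in combinations(range(t), 2):
                est = float(cell[i, k] - cell[i, l])
                comparisons.append(
                    _compare(
                        f"{design.times[k]} - {design.times[l]} @ {group}",
                        est,
                        se,
                        float(df_resid),
                    )
                )
    else:
        raise InvalidInputError(f"unknown contrast family {family!r}")
    if not comparisons:
        raise InvalidInputError("contrast family is empty")
    return bonferroni_adjust(comparisons)


def _compare(label: str, estimate: float, se: float, df: float) -> PairwiseComparison:
    tval = estimate / se
    p = _floor_p(2.0 * sps.t.sf(abs(tval), df))
    return PairwiseComparison(
        contrast=label, estimate=estimate, se=se, df=df, t=tval, p_raw=p, p_adjusted=p
    )


def bonferroni_adjust(
    comparisons: list[PairwiseComparison], m: int | None = None
) -> list[PairwiseComparison]:
    """Familywise Bonferroni adjustment: p_adj = min(1, m * p_raw)."""
    if not comparisons:
        raise InvalidInputError("empty comparison family")
    m = len(comparisons) if m is None else m
    return [
        PairwiseComparison(
            contrast=c.contrast,
            estimate=c.estimate,
            se=c.se,
            df=c.df,
            t=c.t,
            p_raw=c.p_raw,
            p_adjusted=min(1.0, m * c.p_raw),
        )
        for c in comparisons
    ]


# ---------------------------------------------------------------------------
# Influence diagnostics
# ---------------------------------------------------------------------------


def cell_means_design_matrix(design: RMDesign) -> tuple[np.ndarray, np.ndarray]:
    """Full-rank cell-means (group x time) dummy matrix and response vector."""
    df = design.data.sort_values(["group", "subject", "time"], kind="stable")
    cells = pd.Categorical(
        df["group"].astype(str) + ":" + df["time"].astype(str)
    )
    x = pd.get_dummies(cells, dtype=float).to_numpy()
    return x, df["value"].to_numpy(dtype=float)


def influence_diagnostics(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-observation leverage (hat diagonal) and Cook's distance.

    Cook's distance uses the standard OLS formula
    ``D_i = r_i^2 * h_i / (p * (1 - h_i))`` with internally studentized
    residuals ``r_i``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise InvalidInputError("design matrix is rank deficient")
    fit = sm.OLS(y, x).fit()
    infl = OLSInfluence(fit)
    return pd.DataFrame(
        {
            "leverage": infl.hat_matrix_diag,
            "cooks_distance": infl.cooks_distance[0],
        }
    )
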