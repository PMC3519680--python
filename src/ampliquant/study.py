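"""Group-level summaries, two-factor significance testing, gel contraction.

Expression ratios (or area ratios) measured over a dose x time grid are
summarized as mean +/- SEM per group and tested with a two-way ANOVA
(treatment, time, interaction; type-II sums of squares so mildly unbalanced
designs are handled), followed by Bonferroni-corrected pairwise treatment
comparisons within each timepoint using the pooled residual variance.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "AreaRecord",
    "area_ratio",
    "area_ratio_table",
    "summarize_groups",
    "two_way_anova",
]


@dataclass(frozen=True)
class GroupSummary:
    metric: str
    treatment: float
    timepoint: float
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class AreaRecord:
    """One gel's area at one timepoint (any consistent unit)."""

    gel_id: str
    treatment: float
    timepoint_h: float
    area: float

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"area must be positive, got {self.area}")


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA table plus Bonferroni post tests.

    ``anova`` has rows for treatment, time, interaction and residual with
    columns sum_sq, df, F, p.  ``posthoc`` has one row per treatment pair
    per timepoint with the pooled-variance t statistic, raw and
    Bonferroni-adjusted p (family = all pairwise treatment comparisons
    within that timepoint; the family size is a column).
    """

    anova: pd.DataFrame
    posthoc: pd.DataFrame
    alpha: float = 0.05
    log_transformed: bool = False


def area_ratio(record_t: AreaRecord, record_0: AreaRecord) -> float:
    """Gel area at time t divided by the same gel's area at 0 hours."""
    if record_t.gel_id != record_0.gel_id:
        raise ValueError(
            f"gel ids differ: {record_t.gel_id!r} vs {record_0.gel_id!r}"
        )
    if record_0.timepoint_h != 0:
        raise ValueError("reference record must be at 0 hours")
    return record_t.area / record_0.area


def area_ratio_table(areas: pd.DataFrame) -> pd.DataFrame:
    """Per-gel contraction ratios vs the gel's own 0-hour area.

    ``areas`` has columns gel_id, treatment_ng_per_ml, timepoint_h, area.
    """
    ref = areas[areas["timepoint_h"] == 0].set_index("gel_id")["area"]
    missing = sorted(set(areas["gel_id"]) - set(ref.index))
    if missing:
        raise ValueError(f"gels lacking a 0-hour area: {', '.join(missing)}")
    out = areas.copy()
    out["area_ratio"] = out["area"] / out["gel_id"].map(ref)
    return out


def summarize_groups(
    values: pd.DataFrame,
    value: str,
    by: Sequence[str] = ("treatment_ng_per_ml", "timepoint_h"),
) -> pd.DataFrame:
    """Mean, SEM (sd/sqrt(n), n-1 denominator) and n per group.

    Groups of size 1 get a missing SEM.
    """
    def _sem(s: pd.Series) -> float:
        return s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan

    grp = values.groupby(list(by))[value]
    out = grp.agg(mean="mean", n="count").reset_index()
    out["sem"] = grp.apply(_sem).values
    return out[list(by) + ["mean", "sem", "n"]]


def _check_cells(
    tab: pd.DataFrame, treatment: str, time: str
) -> None:
    doses = sorted(tab[treatment].unique())
    times = sorted(tab[time].unique())
    if len(doses) < 2 or len(times) < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels per factor")
    counts = tab.groupby([treatment, time]).size()
    for dose, tp in itertools.product(doses, times):
        if (dose, tp) not in counts.index:
            raise ValueError(
                f"empty design cell: {treatment}={dose}, {time}={tp}"
            )


def two_way_anova(
    values: pd.DataFrame,
    value: str,
    treatment: str = "treatment_ng_per_ml",
    time: str = "timepoint_h",
    alpha: float = 0.05,
    log_transform: bool = False,
) -> AnovaResult:
    """Two-way ANOVA (treatment x time) with Bonferroni post tests.

    Type-II sums of squares (statsmodels OLS) so that the mildly unbalanced
    groups that arise from lost samples are handled; on balanced data all
    SS types coincide.  Post tests compare every treatment pair within each
    timepoint with a pooled-MSE t test, Bonferroni-corrected over the pairs
    of that timepoint.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    tab = values[[treatment, time, value]].dropna().copy()
    _check_cells(tab, treatment, time)
    tab["_y"] = np.log(tab[value]) if log_transform else tab[value]

    doses = sorted(tab[treatment].unique())
    times = sorted(tab[time].unique())

    degenerate = np.ptp(tab["_y"].to_numpy()) == 0
    if degenerate:
        # no variation at all: no effect to test
        rows = [
            dict(factor=f, sum_sq=0.0, df=d, F=np.nan, p=1.0)
            for f, d in (
                ("treatment", len(doses) - 1),
                ("time", len(times) - 1),
                ("interaction", (len(doses) - 1) * (len(times) - 1)),
                ("residual", len(tab) - len(doses) * len(times)),
            )
        ]
        anova = pd.DataFrame(rows)
        mse, df_resid = 0.0, len(tab) - len(doses) * len(times)
    else:
        tab = tab.rename(columns={treatment: "dose", time: "tp"})
        model = ols("_y ~ C(dose) * C(tp)", data=tab).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        anova = pd.DataFrame(
            dict(
                factor=["treatment", "time", "interaction", "residual"],
                sum_sq=aov["sum_sq"].to_numpy(),
                df=aov["df"].to_numpy().astype(int),
                F=aov["F"].to_numpy(),
                p=aov["PR(>F)"].to_numpy(),
            )
        )
        mse = aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"]
        df_resid = int(aov.loc["Residual", "df"])
        tab = tab.rename(columns={"dose": treatment, "tp": time})

    post_rows = []
    pairs = list(itertools.combinations(doses, 2))
    family = len(pairs)
    for tp in times:
        sub = tab[tab[time] == tp]
        for d1, d2 in pairs:
            y1 = sub.loc[sub[treatment] == d1, "_y"]
            y2 = sub.loc[sub[treatment] == d2, "_y"]
            diff = y1.mean() - y2.mean()
            if mse > 0:
                se = np.sqrt(mse * (1 / len(y1) + 1 / len(y2)))
                t = diff / se
                p_raw = 2 * stats.t.sf(abs(t), df_resid)
            else:
                t, p_raw = np.nan, 1.0
            p_adj = min(1.0, p_raw * family)
            post_rows.append(
                dict(
                    timepoint=tp,
                    treatment_1=d1,
                    treatment_2=d2,
                    mean_diff=diff,
                    t=t,
                    p_raw=p_raw,
                    p_bonferroni=p_adj,
                    family_size=family,
                    significant=p_adj < alpha,
                )
            )
    return AnovaResult(
        anova=anova,
        posthoc=pd.DataFrame(post_rows),
        alpha=alpha,
        log_transformed=log_transform,
    )
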