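"""Group statistics on the discrete loading variables.

Two families of comparisons, mirroring common practice in running
biomechanics: an independent-samples t-test between sexes at each belt
speed, and a one-way repeated-measures ANOVA (speed as the within-subject
factor) within each sex, followed by Tukey HSD pairwise speed contrasts
computed on the within-subject error term.

The omnibus F test is inherently one-tailed; pairwise contrasts are
two-sided with the Tukey family-wise adjustment.  A Greenhouse-Geisser
correction is applied to the omnibus p-value when the sphericity
estimate epsilon falls below 0.75.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError

DEFAULT_ALPHA = 0.05

#: Greenhouse-Geisser correction kicks in below this sphericity epsilon.
GG_EPSILON_THRESHOLD = 0.75


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical contrast: label, statistic, p, mean difference."""

    contrast: str
    statistic: float
    p_value: float
    mean_difference: float
    significant: bool
    alpha: float = DEFAULT_ALPHA
    kind: str = "t"  # "t" | "rm_anova" | "tukey"


def sex_ttest(
    female: np.ndarray,
    male: np.ndarray,
    speed: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> ComparisonResult:
    """Independent-samples t-test of female vs male values at one speed.

    Student's pooled-variance test by default (``equal_var=False`` gives
    Welch).  The mean difference is female minus male.
    """
    female = np.asarray(female, dtype=float)
    male = np.asarray(male, dtype=float)
    if female.size < 2 or male.size < 2:
        raise InsufficientDataError("need at least 2 subjects per sex")
    t, p = sps.ttest_ind(female, male, equal_var=equal_var)
    label = "female vs male" + (f" @{speed}" if speed is not None else "")
    return ComparisonResult(
        contrast=label,
        statistic=float(t),
        p_value=float(p),
        mean_difference=float(female.mean() - male.mean()),
        significant=bool(p < alpha),
        alpha=alpha,
        kind="t",
    )


def _complete_pivot(table: pd.DataFrame) -> pd.DataFrame:
    pivot = table.pivot(index="subject_id", columns="speed", values="value")
    if pivot.isna().any().any():
        raise InsufficientDataError(
            "repeated-measures table has missing subject x speed cells"
        )
    if pivot.shape[0] < 2 or pivot.shape[1] < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 speeds")
    return pivot


def speed_rm_anova(
    table: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> list[ComparisonResult]:
    """Within-sex speed effect: omnibus RM-ANOVA plus Tukey HSD contrasts.

    Parameters
    ----------
    table : DataFrame
        Long format with columns ``subject_id``, ``speed``, ``value``;
        every subject must be measured at every speed (no imputation).

    Returns
    -------
    list of ComparisonResult
        First the omnibus F (contrast ``"speed (omnibus)"``), then one
        Tukey contrast per unordered speed pair, labelled e.g.
        ``"2.7 vs 3.0"`` with mean difference first minus second.
    """
    pivot = _complete_pivot(table)
    n, k = pivot.shape
    values = pivot.to_numpy()

    grand = values.mean()
    cond_means = values.mean(axis=0)
    subj_means = values.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((values - grand) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df_err

    scale = ss_tot + 1e-300
    if ss_cond / scale < 1e-12:  # no condition effect at all
        f_stat, p_omni = 0.0, 1.0
    elif ms_err == 0.0:
        f_stat, p_omni = np.inf, 0.0
    else:
        f_stat, p_omni = _omnibus_pingouin(table)

    results = [
        ComparisonResult(
            contrast="speed (omnibus)",
            statistic=float(f_stat),
            p_value=float(p_omni),
            mean_difference=float(cond_means.max() - cond_means.min()),
            significant=bool(p_omni < alpha),
            alpha=alpha,
            kind="rm_anova",
        )
    ]

    # Tukey HSD on the within-subject error term
    speeds = list(pivot.columns)
    se = np.sqrt(ms_err / n)
    for i, j in itertools.combinations(range(k), 2):
        diff = cond_means[i] - cond_means[j]
        if se == 0.0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
        results.append(
            ComparisonResult(
                contrast=f"{speeds[i]} vs {speeds[j]}",
                statistic=float(q),
                p_value=float(min(max(p, 0.0), 1.0)),
                mean_difference=float(diff),
                significant=bool(p < alpha),
                alpha=alpha,
                kind="tukey",
            )
        )
    return results


def _omnibus_pingouin(table: pd.DataFrame) -> tuple[float, float]:
    """Omnibus F and p via pingouin, GG-corrected when epsilon < 0.75."""
    import pingouin as pg  # deferred: heavy import

    res = pg.rm_anova(
        data=table,
        dv="value",
        within="speed",
        subject="subject_id",
        correction=True,
        detailed=True,
    ).set_index("Source")
    row = res.drop(index="Error").iloc[0]
    f_stat = float(row["F"])
    eps = float(row["eps"])
    if np.isfinite(eps) and eps < GG_EPSILON_THRESHOLD and "p_GG_corr" in row:
        p = float(row["p_GG_corr"])
    else:
        p = float(row["p_unc"])
    return f_stat, p


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "kind": r.kind,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "mean_difference": r.mean_difference,
                "significant": r.significant,
                "alpha": r.alpha,
            }
            for r in results
        ]
    )
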