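"""Survival association and the study's hypothesis-testing toolkit.

Kaplan-Meier curves with two-group log-rank tests, stage-adjusted Cox
proportional-hazards regression (Breslow tie handling by default), plus
paired t, Fisher's exact, Kruskal-Wallis and Benjamini-Hochberg FDR
adjustment. Survival times are expected to be censored upstream (60-month
horizon at table-read time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests


@dataclass
class SurvivalFit:
    """Kaplan-Meier curves plus log-rank and optional Cox summaries."""

    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    cox_hr: float | None = None
    cox_ci_low: float | None = None
    cox_ci_high: float | None = None
    cox_p: float | None = None
    flagged: bool = False
    flag_reason: str = ""


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    group: Sequence,
) -> SurvivalFit:
    """Product-limit estimates per group and the log-rank test across groups.

    Each group must be non-empty; with two groups the statistic is the
    usual 1-df log-rank chi-square.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    if times.shape != events.shape or times.shape != group.shape:
        raise ValueError("times, events and group must have equal length")
    labels = pd.unique(group)
    if len(labels) < 2:
        raise ValueError("log-rank needs at least two groups")
    curves: dict[str, pd.DataFrame] = {}
    for lab in labels:
        mask = group == lab
        if not mask.any():
            raise ValueError(f"group {lab!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(lab))
        tbl = kmf.event_table
        curves[str(lab)] = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(dtype=float),
                "at_risk": tbl["at_risk"].to_numpy(),
                "events": tbl["observed"].to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
    if events.sum() == 0:
        return SurvivalFit(km_curves=curves, logrank_stat=0.0, logrank_p=1.0)
    res = multivariate_logrank_test(times, group, events)
    return SurvivalFit(
        km_curves=curves,
        logrank_stat=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def cox_adjusted(
    times: Sequence[float],
    events: Sequence[int],
    exposure_flag: Sequence[int],
    stage: Sequence[int] | None = None,
    ties: str = "breslow",
) -> SurvivalFit:
    """Proportional-hazards fit of an exposure flag, stage-adjusted.

    Covariates are the binary exposure flag plus (optionally) ordinal
    cTNM stage. Partial-likelihood maximisation with Breslow tie handling
    by default (``ties="efron"`` available). Reports the exposure hazard
    ratio with Wald 95% CI and p-value. A constant exposure flag, or a
    monotone likelihood (complete separation, recognised by a diverging
    coefficient or unusable standard error), yields a flagged result with
    no finite HR.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    flag = np.asarray(exposure_flag, dtype=float)
    if np.all(flag == flag[0]):
        return SurvivalFit(flagged=True, flag_reason="exposure flag is constant")
    cols = {"exposure": flag}
    if stage is not None:
        stage = np.asarray(stage, dtype=float)
        if not np.all(stage == stage[0]):
            cols["stage"] = stage
    X = pd.DataFrame(cols)
    try:
        model = PHReg(times, X, status=events, ties=ties)
        fit = model.fit(disp=False)
    except Exception as exc:  # singular design, failed convergence
        return SurvivalFit(flagged=True, flag_reason=f"fit failed: {exc}")
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 50 or abs(beta) > 20:
        return SurvivalFit(flagged=True, flag_reason="monotone likelihood (separation)")
    z = stats.norm.ppf(0.975)
    return SurvivalFit(
        cox_hr=float(np.exp(beta)),
        cox_ci_low=float(np.exp(beta - z * se)),
        cox_ci_high=float(np.exp(beta + z * se)),
        cox_p=float(2.0 * stats.norm.sf(abs(beta / se))),
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired Student's t-test; identical vectors give (0, 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired t-test needs equal-length vectors")
    diff = x - y
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; returns (odds ratio, p)."""
    res = stats.fisher_exact(np.asarray(table, dtype=int))
    return float(res[0]), float(res[1])


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H-test across two or more groups."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    res = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
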