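"""Prognostic evaluation of the stemness score.

Three tools: a plain two-group log-rank test; the multiple-cutoff log-rank
scan (LRMC) that dichotomizes the continuous score Delta(r) at a percentile
grid of candidate cutoffs and reports the best-separating one; and a
multivariate Cox proportional-hazards regression in which the score-derived
group indicator competes with clinical covariates.

Scanning cutoffs and reporting the minimum p-value is anti-conservative, so
the scan can attach a permutation-adjusted p (score labels permuted against
the survival outcomes, scan repeated, adjusted p = fraction of permutations
with a best p at least as small).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LifelinesConvergence
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ConvergenceError, ValidationError

__all__ = [
    "LrmcResult",
    "logrank",
    "lrmc_scan",
    "cox_multivariate",
    "km_curve",
]


@dataclass
class LrmcResult:
    """Outcome of the multiple-cutoff log-rank scan."""

    scan: pd.DataFrame            # cutoff, statistic, p, n_low, n_high
    best_cutoff: float
    best_p: float
    best_statistic: float
    adjusted_p: float | None = None
    n_permutations: int = 0

    @property
    def cutoffs(self) -> np.ndarray:
        return self.scan["cutoff"].to_numpy()


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValidationError("times must be positive")
    if not set(np.unique(e)).issubset({0, 1}):
        raise ValidationError("events must be 0/1")
    return t, e


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    t, e = _check_surv(times, events)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {len(levels)}")
    mask = g == levels[0]
    if mask.all() or (~mask).all():
        raise ValidationError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValidationError("no events observed; log-rank undefined")
    res = _ll_logrank(t[mask], t[~mask], event_observed_A=e[mask],
                      event_observed_B=e[~mask])
    return float(res.test_statistic), float(res.p_value)


def lrmc_scan(
    records: pd.DataFrame,
    percentiles: tuple[float, float, float] = (10.0, 90.0, 5.0),
    min_group_frac: float = 0.10,
    n_permutations: int = 0,
    seed: int | None = None,
    score_col: str = "delta_r",
) -> LrmcResult:
    """Log-rank test with multiple cutoffs over the stemness score.

    Candidate cutoffs are percentiles of ``records[score_col]`` (default 10th
    to 90th in steps of 5), kept only when both resulting groups hold at least
    ``min_group_frac`` of the cohort. The best cutoff minimizes the log-rank
    p-value. With ``n_permutations > 0``, an adjusted p for that minimum is
    estimated by permuting the scores against (time, event).
    """
    for col in ("time", "event", score_col):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    t, e = _check_surv(records["time"], records["event"])
    score = records[score_col].to_numpy(dtype=float)
    if np.unique(score).size < 2:
        raise ValidationError("need >= 2 distinct score values to scan")
    lo, hi, step = percentiles
    grid = np.arange(lo, hi + 1e-9, step)
    candidates = np.unique(np.percentile(score, grid))

    def scan_once(sc: np.ndarray) -> pd.DataFrame:
        rows = []
        n = sc.size
        min_n = int(np.ceil(min_group_frac * n))
        for cut in candidates:
            high = sc > cut
            n_high, n_low = int(high.sum()), int((~high).sum())
            if n_high < min_n or n_low < min_n:
                continue
            if e.sum() == 0:
                continue
            res = _ll_logrank(t[high], t[~high], event_observed_A=e[high],
                              event_observed_B=e[~high])
            rows.append({"cutoff": float(cut),
                         "statistic": float(res.test_statistic),
                         "p": float(res.p_value),
                         "n_high": n_high, "n_low": n_low})
        return pd.DataFrame(rows)

    scan = scan_once(score)
    if scan.empty:
        raise ValidationError("no candidate cutoff satisfies the group-size constraint")
    best_row = scan.loc[scan["p"].idxmin()]
    best_p = float(best_row["p"])

    adjusted_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(score)
            perm_scan = scan_once(perm)
            if not perm_scan.empty and perm_scan["p"].min() <= best_p:
                hits += 1
        adjusted_p = (hits + 1) / (n_permutations + 1)
        adjusted_p = max(adjusted_p, best_p)  # adjustment can never help

    return LrmcResult(scan=scan, best_cutoff=float(best_row["cutoff"]),
                      best_p=best_p, best_statistic=float(best_row["statistic"]),
                      adjusted_p=adjusted_p, n_permutations=n_permutations)


def cox_multivariate(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards regression.

    ``covariates`` are column names (numeric, or categorical strings which are
    one-hot encoded against their first level). Returns one row per model
    term: hazard_ratio, ci_low, ci_high, p.
    """
    for col in (time_col, event_col, *covariates):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    _check_surv(records[time_col], records[event_col])
    n_events = int(records[event_col].sum())
    if n_events == 0:
        raise ValidationError("no events observed; Cox model undefined")
    design = pd.get_dummies(records[covariates], drop_first=True, dtype=float)
    if n_events < design.shape[1]:
        raise ValidationError(
            f"{n_events} events cannot support {design.shape[1]} covariates"
        )
    df = pd.concat([records[[time_col, event_col]], design], axis=1)
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col=time_col, event_col=event_col)
    except (_LifelinesConvergence, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox model failed to converge: {exc}") from exc
    summary = fitter.summary
    out = pd.DataFrame({
        "hazard_ratio": summary["exp(coef)"],
        "ci_low": summary["exp(coef) lower 95%"],
        "ci_high": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    })
    out.index.name = "covariate"
    return out


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival step function (time, survival) for export."""
    from lifelines import KaplanMeierFitter

    t, e = _check_surv(times, events)
    km = KaplanMeierFitter().fit(t, event_observed=e)
    df = km.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    return df
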