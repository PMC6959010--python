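"""Dose-inhibition curve fitting and phenotype-differential drug screening.

Viability (percent of control) as a function of drug dose is fit with a
six-model logistic ensemble built from the four-parameter logistic

    v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

under the constraint grid {hill free, hill = 1} x {unconstrained, top = 100,
bottom = 0}. (The "3 parameter" family fixes the hill slope at 1; note the
naming counts curve parameters, not free ones — "4 parameter Top 100" has
three free parameters.) The model with the lowest residual standard error,
sqrt(RSS / (n - p)), supplies the reported IC50 and activity area. IC50 is
the curve midpoint (relative IC50); fits whose midpoint falls beyond the
highest tested dose are reported as right-censored ("> max dose").

Activity area (AA) is the mean per-dose inhibition max(0, 1 - v/100) over the
tested doses, in [0, 1]; higher = more sensitive. A trapezoid-on-log-dose
alternative is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitFailureError, ValidationError
from .labels import CSM, NSE
from .signature import welch_t_test
from .synthetic import four_pl

__all__ = [
    "MODEL_SET",
    "DoseResponseFit",
    "DrugScreenResult",
    "fit_dose_response",
    "activity_area",
    "screen_differential_drugs",
]

# model_id -> (fix_top, fix_bottom, fix_hill); None = free
MODEL_SET: dict[str, tuple[float | None, float | None, float | None]] = {
    "3P": (None, None, 1.0),
    "3P_top100": (100.0, None, 1.0),
    "3P_bottom0": (None, 0.0, 1.0),
    "4P": (None, None, None),
    "4P_top100": (100.0, None, None),
    "4P_bottom0": (None, 0.0, None),
}

_HILL_SEEDS = (0.5, 1.0, 2.0)


@dataclass
class DoseResponseFit:
    model_id: str
    bottom: float
    top: float
    ic50: float
    hill: float
    residual_se: float
    activity_area: float
    converged: bool
    n_points: int
    max_dose: float

    @property
    def ic50_censored(self) -> bool:
        return not (self.ic50 <= self.max_dose)

    @property
    def ic50_label(self) -> str:
        """IC50 as printed: the value, or the '> max dose' sentinel."""
        if self.ic50_censored:
            return f"> {self.max_dose:g}"
        return f"{self.ic50:.6g}"

    def predict(self, dose) -> np.ndarray:
        return four_pl(dose, self.bottom, self.top, self.ic50, self.hill)


@dataclass
class DrugScreenResult:
    drug: str
    metric: str
    mean_csm: float
    mean_nse: float
    n_csm: int
    n_nse: int
    t_statistic: float
    p_value: float
    more_sensitive: str  # phenotype hit harder by the drug


def _n_free(model_id: str) -> int:
    return sum(v is None for v in MODEL_SET[model_id][:2]) + 1 \
        + (MODEL_SET[model_id][2] is None)


def _fit_one_model(model_id: str, doses: np.ndarray, viability: np.ndarray):
    """Least-squares fit of one ensemble member on log10 dose.

    Returns (params dict, residual_se) or None when the model cannot be fit.
    """
    fix_top, fix_bottom, fix_hill = MODEL_SET[model_id]
    n, p = viability.size, _n_free(model_id)
    if n <= p:
        return None
    log_d = np.log10(doses)
    lo_ic, hi_ic = log_d.min() - 4.0, log_d.max() + 4.0

    vmin, vmax = float(viability.min()), float(viability.max())
    half = (vmin + vmax) / 2.0
    ic50_init = float(doses[np.argmin(np.abs(viability - half))])

    def unpack(theta):
        i = 0
        if fix_bottom is None:
            bottom = theta[i]; i += 1
        else:
            bottom = fix_bottom
        if fix_top is None:
            top = theta[i]; i += 1
        else:
            top = fix_top
        log_ic50 = theta[i]; i += 1
        hill = theta[i] if fix_hill is None else fix_hill
        return bottom, top, log_ic50, hill

    def residuals(theta):
        bottom, top, log_ic50, hill = unpack(theta)
        pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_d - log_ic50)))
        return pred - viability

    hill_seeds = _HILL_SEEDS if fix_hill is None else (1.0,)
    best = None
    for hill0 in hill_seeds:
        theta0, lo, hi = [], [], []
        if fix_bottom is None:
            theta0.append(min(vmin, 99.0)); lo.append(-50.0); hi.append(150.0)
        if fix_top is None:
            theta0.append(max(vmax, 1.0)); lo.append(-50.0); hi.append(200.0)
        theta0.append(math.log10(ic50_init)); lo.append(lo_ic); hi.append(hi_ic)
        if fix_hill is None:
            theta0.append(hill0); lo.append(0.05); hi.append(20.0)
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = optimize.least_squares(residuals, theta0, bounds=(lo, hi),
                                         method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if not sol.success or not np.all(np.isfinite(sol.fun)):
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return None
    rss, theta = best
    bottom, top, log_ic50, hill = unpack(theta)
    residual_se = math.sqrt(rss / (n - p))
    return {"bottom": float(bottom), "top": float(top),
            "ic50": float(10.0 ** log_ic50), "hill": float(hill),
            "residual_se": residual_se}


def fit_dose_response(
    doses,
    viability_pct,
    model_set: tuple[str, ...] | None = None,
) -> tuple[DoseResponseFit, dict[str, DoseResponseFit]]:
    """Fit the model ensemble and select by lowest residual standard error.

    ``doses`` and ``viability_pct`` are parallel arrays; repeated doses encode
    replicates. Returns the winning fit and every converged fit by model id.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability_pct, dtype=float)
    if doses.shape != viability.shape:
        raise ValidationError("doses and viability must have equal length")
    if np.any(doses <= 0):
        raise ValidationError("doses must be positive")
    if np.unique(doses).size < 4:
        raise ValidationError("need >= 4 distinct doses")
    if not np.all(np.isfinite(viability)):
        raise ValidationError("viability values must be finite")
    model_set = tuple(model_set or MODEL_SET)
    unknown = set(model_set) - set(MODEL_SET)
    if unknown:
        raise ValidationError(f"unknown model ids: {sorted(unknown)}")

    max_dose = float(doses.max())
    aa = activity_area(doses, viability)

    if np.ptp(viability) < 1e-9:
        # No dose dependence at all: the midpoint is unidentifiable, report
        # the flat curve with a right-censored IC50.
        flat = DoseResponseFit("4P", float(viability.mean()), float(viability.mean()),
                               math.inf, 1.0, 0.0, aa, True, viability.size, max_dose)
        return flat, {"4P": flat}

    fits: dict[str, DoseResponseFit] = {}
    for model_id in model_set:
        res = _fit_one_model(model_id, doses, viability)
        if res is None:
            continue
        fits[model_id] = DoseResponseFit(
            model_id, res["bottom"], res["top"], res["ic50"], res["hill"],
            res["residual_se"], aa, True, viability.size, max_dose,
        )
    if not fits:
        raise FitFailureError("no dose-response model converged")
    best = min(fits.values(), key=lambda f: f.residual_se)
    return best, fits


def activity_area(doses, viability_pct, method: str = "mean") -> float:
    """Inhibition summary over the tested dose range, in [0, 1].

    ``method="mean"`` (default, CCLE-style normalized AA): the mean over all
    measurements of max(0, 1 - viability/100). ``method="trapezoid"``
    integrates the same inhibition over log10 dose and normalizes by the
    spanned range.
    """
    doses = np.asarray(doses, dtype=float)
    v = np.asarray(viability_pct, dtype=float)
    if doses.shape != v.shape:
        raise ValidationError("doses and viability must have equal length")
    inhibition = np.maximum(0.0, 1.0 - v / 100.0)
    if method == "mean":
        return float(inhibition.mean())
    if method == "trapezoid":
        order = np.argsort(doses)
        d, y = np.log10(doses[order]), inhibition[order]
        span = d[-1] - d[0]
        if span <= 0:
            raise ValidationError("trapezoid AA needs >= 2 distinct doses")
        return float(np.trapezoid(y, d) / span)
    raise ValidationError(f"unknown AA method {method!r}")


def screen_differential_drugs(
    sensitivity: pd.DataFrame,
    phenotypes: pd.Series,
    metric: str = "activity_area",
    alpha: float = 0.05,
) -> list[DrugScreenResult]:
    """Welch-t screen for drugs with phenotype-differential sensitivity.

    ``sensitivity`` is cell lines x drugs (one metric per cell); ``phenotypes``
    maps cell line -> CS/M or NS/E. Drugs are returned ordered by p-value;
    the ``more_sensitive`` phenotype is the group with the larger mean when
    the metric is an activity area (higher = more sensitive) and the smaller
    mean for an IC50-type metric (``metric`` containing "ic50").
    """
    phenotypes = phenotypes.reindex(sensitivity.index)
    csm_ids = phenotypes.index[phenotypes == CSM]
    nse_ids = phenotypes.index[phenotypes == NSE]
    higher_is_sensitive = "ic50" not in metric.lower()
    results: list[DrugScreenResult] = []
    for drug in sensitivity.columns:
        a = sensitivity.loc[csm_ids, drug].dropna()
        b = sensitivity.loc[nse_ids, drug].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"drug {drug!r}: fewer than 2 values per phenotype; skipped")
            continue
        t, p = welch_t_test(a, b)
        diff = a.mean() - b.mean()
        if higher_is_sensitive:
            more = CSM if diff > 0 else NSE
        else:
            more = CSM if diff < 0 else NSE
        results.append(DrugScreenResult(
            drug=drug, metric=metric, mean_csm=float(a.mean()),
            mean_nse=float(b.mean()), n_csm=len(a), n_nse=len(b),
            t_statistic=t, p_value=p, more_sensitive=more,
        ))
    results.sort(key=lambda r: (r.p_value, r.drug))
    return results
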