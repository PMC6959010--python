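"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the textbook definitions and stays
independent of the code paths it checks.
"""

import itertools
import math

import numpy as np
from scipy import stats


def pearson_r(x, y):
    """Textbook Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def welch_t(a, b):
    """Welch t statistic and two-sided p from the definition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def complete_linkage(points):
    """Naive agglomerative complete linkage on Euclidean distances.

    Returns the merge history as a list of (frozenset_a, frozenset_b, height)
    and a function partition(k) giving the flat clustering as a set of
    frozensets of point indices.
    """
    points = np.asarray(points, float)
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)

    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    snapshots = {n: {frozenset([i]) for i in range(n)}}
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            height = max(d[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or height < best[0]:
                best = (height, i, j)
        height, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((clusters[i], clusters[j], height))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
        snapshots[len(clusters)] = set(clusters)

    def partition(k):
        return snapshots[k]

    return merges, partition


def logrank_chi2(times, events, group_mask):
    """Two-group log-rank chi-square from the hypergeometric definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group_mask = np.asarray(group_mask, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group_mask).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & group_mask).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    p = stats.chi2.sf(chi2, 1)
    return chi2, p


def fit_4pl_grid_polish(doses, viability, fix_top=None, fix_bottom=None,
                        fix_hill=None):
    """Grid search over (log10 IC50, hill) + Nelder-Mead polish of one model.

    For fixed (ic50, hill) the logistic is linear in (bottom, top), so the
    grid stage solves a constrained linear least-squares exactly.
    """
    doses = np.asarray(doses, float)
    v = np.asarray(viability, float)
    log_d = np.log10(doses)

    def rss_linear(log_ic50, hill):
        f = 1.0 / (1.0 + 10.0 ** (hill * (log_d - log_ic50)))  # fraction 'top'
        if fix_top is None and fix_bottom is None:
            A = np.column_stack([1.0 - f, f])
            coef, *_ = np.linalg.lstsq(A, v, rcond=None)
            bottom, top = coef
        elif fix_top is not None:
            resid_target = v - fix_top * f
            A = (1.0 - f)[:, None]
            coef, *_ = np.linalg.lstsq(A, resid_target, rcond=None)
            bottom, top = coef[0], fix_top
        else:
            resid_target = v - fix_bottom * (1.0 - f)
            A = f[:, None]
            coef, *_ = np.linalg.lstsq(A, resid_target, rcond=None)
            bottom, top = fix_bottom, coef[0]
        pred = bottom + (top - bottom) * f
        return ((pred - v) ** 2).sum(), bottom, top

    hills = [fix_hill] if fix_hill is not None else np.geomspace(0.1, 10, 25)
    ic_grid = np.linspace(log_d.min() - 3, log_d.max() + 3, 80)
    best = None
    for h in hills:
        for li in ic_grid:
            rss, bottom, top = rss_linear(li, h)
            if best is None or rss < best[0]:
                best = (rss, li, h, bottom, top)
    _, li, h, bottom, top = best

    from scipy.optimize import minimize

    def objective(theta):
        li_, h_ = theta
        if h_ <= 0:
            return np.inf
        return rss_linear(li_, h_)[0]

    if fix_hill is None:
        sol = minimize(objective, [li, h], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        li, h = sol.x
    else:
        sol = minimize(lambda t: rss_linear(t[0], fix_hill)[0], [li],
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        li, h = sol.x[0], fix_hill
    rss, bottom, top = rss_linear(li, h)
    n_free = 1 + (fix_hill is None) + (fix_top is None) + (fix_bottom is None)
    residual_se = math.sqrt(rss / (len(v) - n_free))
    return {"bottom": bottom, "top": top, "ic50": 10.0**li, "hill": h,
            "residual_se": residual_se}
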