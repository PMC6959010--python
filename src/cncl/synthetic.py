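"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be simulated here: two-group expression
matrices with a planted directional signature, paired pre/post cohorts with
phenotype switching, four-parameter-logistic viability curves, and two-group
exponential survival with proportional hazards. All generators are
deterministic under a fixed seed.

The expression model is additive Gaussian on the log2 scale (the convention
for RMA-normalized microarray data). Signature genes of each arm share a
standard-normal latent factor per sample, weighted by ``within_arm_corr``,
which reproduces the strong within-arm inter-gene correlation real
stemness/EMT signatures show without specifying a full covariance matrix.
Probe-level physics, batch effects and RNA-seq overdispersion are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix
from .labels import CSM, NSE

__all__ = [
    "ExpressionSimConfig",
    "DoseResponseSimConfig",
    "SurvivalSimConfig",
    "generate_expression",
    "generate_paired_switch",
    "generate_dose_response",
    "generate_survival",
    "four_pl",
]


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the two-group expression simulation.

    ``log2_effect`` is the expected log2 difference (CS/M minus NS/E) for
    up-arm signature genes; down-arm genes get the negated effect.
    ``within_arm_corr`` in [0, 1] weights a shared per-sample latent factor so
    same-arm signature genes co-vary (pairwise correlation ~ weight squared).
    """

    n_genes: int = 1000
    n_signature_up: int = 8
    n_signature_down: int = 7
    n_csm_samples: int = 20
    n_nse_samples: int = 20
    log2_effect: float = 3.0
    noise_sd: float = 0.5
    within_arm_corr: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_signature_up", "n_signature_down",
                     "n_csm_samples", "n_nse_samples"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.n_signature_up + self.n_signature_down > self.n_genes:
            raise ValidationError("signature larger than gene universe")
        if self.log2_effect < 0:
            raise ValidationError("log2_effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not 0.0 <= self.within_arm_corr <= 1.0:
            raise ValidationError("within_arm_corr must be in [0, 1]")


@dataclass(frozen=True)
class DoseResponseSimConfig:
    """Four-parameter-logistic viability simulation (percent scale)."""

    doses: Sequence[float] = (0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 50.0)
    bottom: float = 0.0
    top: float = 100.0
    ic50: float = 1.0
    hill: float = 1.0
    noise_sd: float = 5.0
    replicates: int = 4
    seed: int = 0

    def validate(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if doses.size == 0 or np.any(doses <= 0):
            raise ValidationError("doses must be positive")
        if np.any(np.diff(doses) <= 0):
            raise ValidationError("doses must be strictly increasing")
        if self.bottom >= self.top:
            raise ValidationError("bottom must be below top")
        if self.ic50 <= 0:
            raise ValidationError("ic50 must be positive")
        if self.hill <= 0:
            raise ValidationError("hill must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be a positive integer")


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Two-group exponential survival with proportional hazards.

    Group 1 (CS/M-like) has hazard ``baseline_rate * hazard_ratio``; censoring
    is independent exponential with rate ``censor_rate``.
    """

    n_per_group: int = 100
    hazard_ratio: float = 2.0
    baseline_rate: float = 0.1
    censor_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be a positive integer")
        for name in ("hazard_ratio", "baseline_rate", "censor_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


def four_pl(dose, bottom, top, ic50, hill):
    """Four-parameter logistic viability: bottom + (top-bottom)/(1+(d/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _draw_samples(cfg: ExpressionSimConfig, baselines: np.ndarray,
                  group: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an n_genes x n block for one phenotype group."""
    shift = np.zeros(cfg.n_genes)
    half = cfg.log2_effect / 2.0
    sign = 1.0 if group == CSM else -1.0
    up = slice(0, cfg.n_signature_up)
    down = slice(cfg.n_signature_up, cfg.n_signature_up + cfg.n_signature_down)
    shift[up] = sign * half
    shift[down] = -sign * half

    w = cfg.within_arm_corr
    eps = rng.normal(0.0, 1.0, size=(cfg.n_genes, n))
    latent_up = rng.normal(0.0, 1.0, size=n)
    latent_down = rng.normal(0.0, 1.0, size=n)
    noise = eps.copy()
    resid = np.sqrt(1.0 - w * w)
    noise[up] = resid * eps[up] + w * latent_up[None, :]
    noise[down] = resid * eps[down] + w * latent_down[None, :]
    return baselines[:, None] + shift[:, None] + cfg.noise_sd * noise


def generate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Simulate a two-group log2 expression matrix with a planted signature.

    Returns
    -------
    matrix
        :class:`~cncl.io.ExpressionMatrix`, genes x samples, log2 scale.
    labels
        Per-sample phenotype label (``"CS/M"`` / ``"NS/E"``).
    truth
        DataFrame indexed by planted gene id with a ``direction`` column
        (``"up"`` = elevated in CS/M, ``"down"`` = elevated in NS/E).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baselines = rng.normal(8.0, 1.0, size=config.n_genes)

    csm = _draw_samples(config, baselines, CSM, config.n_csm_samples, rng)
    nse = _draw_samples(config, baselines, NSE, config.n_nse_samples, rng)
    values = np.hstack([csm, nse])
    samples = [f"CSM_{i:03d}" for i in range(1, config.n_csm_samples + 1)] + \
              [f"NSE_{i:03d}" for i in range(1, config.n_nse_samples + 1)]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    labels = pd.Series([CSM] * config.n_csm_samples + [NSE] * config.n_nse_samples,
                       index=samples, name="phenotype")
    n_up, n_down = config.n_signature_up, config.n_signature_down
    truth = pd.DataFrame(
        {"direction": ["up"] * n_up + ["down"] * n_down},
        index=pd.Index(genes[: n_up + n_down], name="feature_id"),
    )
    return matrix, labels, truth


def generate_paired_switch(
    config: ExpressionSimConfig,
    switch_fraction: float,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series]:
    """Simulate a paired pre/post-treatment cohort with phenotype switching.

    Each pre-treatment sample keeps its group from :func:`generate_expression`;
    post-treatment, a ``switch_fraction`` share of samples (chosen at random)
    is redrawn from the *opposite* group's generative model, the rest redrawn
    from their own. Pre and post matrices share sample ids; the returned
    boolean Series flags the switched samples.
    """
    config.validate()
    if not 0.0 <= switch_fraction <= 1.0:
        raise ValidationError("switch_fraction must be in [0, 1]")
    pre, labels, _ = generate_expression(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    baselines_rng = np.random.default_rng(config.seed)
    baselines = baselines_rng.normal(8.0, 1.0, size=config.n_genes)

    n = len(labels)
    n_switch = int(round(switch_fraction * n))
    switched_idx = rng.choice(n, size=n_switch, replace=False)
    switched = np.zeros(n, dtype=bool)
    switched[switched_idx] = True

    opposite = {CSM: NSE, NSE: CSM}
    post_cols = []
    for i, sample in enumerate(labels.index):
        group = opposite[labels.iloc[i]] if switched[i] else labels.iloc[i]
        col = _draw_samples(config, baselines, group, 1, rng)[:, 0]
        post_cols.append(col)
    post_values = np.column_stack(post_cols)
    post = ExpressionMatrix(pd.DataFrame(post_values, index=pre.feature_ids,
                                         columns=pre.sample_ids))
    flag = pd.Series(switched, index=labels.index, name="switched")
    return pre, post, flag


def generate_dose_response(config: DoseResponseSimConfig) -> pd.DataFrame:
    """Simulate a replicated dose-viability table from a 4PL curve.

    Gaussian noise (percent-viability scale) is truncated to [-10, 130] to
    mimic out-of-range assay readings. Columns: dose_uM, replicate,
    viability_pct.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.doses, dtype=float)
    clean = four_pl(doses, config.bottom, config.top, config.ic50, config.hill)
    rows = []
    for rep in range(1, config.replicates + 1):
        noisy = clean + rng.normal(0.0, config.noise_sd, size=doses.size) \
            if config.noise_sd > 0 else clean.copy()
        noisy = np.clip(noisy, -10.0, 130.0)
        for d, v in zip(doses, noisy):
            rows.append({"dose_uM": d, "replicate": rep, "viability_pct": v})
    return pd.DataFrame(rows)


def generate_survival(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate two-group exponential survival.

    Columns: sample_id, time, event (1 = death observed, 0 = censored),
    group (``"CS/M"`` with hazard ``baseline_rate * hazard_ratio``, ``"NS/E"``
    with ``baseline_rate``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    rows = []
    for group, rate in ((CSM, config.baseline_rate * config.hazard_ratio),
                        (NSE, config.baseline_rate)):
        event_t = rng.exponential(1.0 / rate, size=n)
        censor_t = rng.exponential(1.0 / config.censor_rate, size=n)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        tag = "CSM" if group == CSM else "NSE"
        for i in range(n):
            rows.append({"sample_id": f"{tag}_{i + 1:03d}", "time": time[i],
                         "event": event[i], "group": group})
    return pd.DataFrame(rows)
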