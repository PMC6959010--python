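"""Continuous stemness score from median-centroid Pearson correlations.

Two reference centroids are built from a labeled cohort: per-gene z-score
standardization across all samples, then the per-gene median within the CS/M
group and within the NS/E group. Each test sample's standardized signature
vector is Pearson-correlated with both centroids, giving CS/M(r) and NS/E(r);
the stemness score is their difference

    SS = Delta(r) = CS/M(r) - NS/E(r),

bounded in [-2, 2], where negative values indicate a more epithelial (NS/E)
phenotype. A categorical call is made from a cutoff (default 0) with an
optional intermediary band; cohort-specific cutoffs can come from the
survival module's multiple-cutoff log-rank scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingGenesError, ValidationError
from .io import ExpressionMatrix
from .labels import CSM, INTERMEDIARY, NSE
from .classify import standardize_genes
from .signature import SignatureGeneList

__all__ = [
    "CentroidPair",
    "StemnessScore",
    "build_centroids",
    "score_sample",
    "score_matrix",
    "call_from_score",
    "trace_plasticity",
]


@dataclass
class CentroidPair:
    """Per-gene median standardized expression of each reference group."""

    csm_median: pd.Series
    nse_median: pd.Series
    source: dict | None = None

    def __post_init__(self) -> None:
        if not self.csm_median.index.equals(self.nse_median.index):
            raise ValidationError("centroid gene sets differ")
        if not (np.isfinite(self.csm_median).all() and np.isfinite(self.nse_median).all()):
            raise ValidationError("centroids must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.csm_median.index)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"csm_median": self.csm_median,
                      "nse_median": self.nse_median}) \
            .to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "CentroidPair":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(df["csm_median"], df["nse_median"])


@dataclass(frozen=True)
class StemnessScore:
    """Per-sample correlation pair and their difference Delta(r)."""

    sample_id: str
    csm_r: float
    nse_r: float
    delta_r: float
    call: str

    def __post_init__(self) -> None:
        assert -2.0 - 1e-9 <= self.delta_r <= 2.0 + 1e-9, "delta_r out of [-2, 2]"


def build_centroids(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    signature: SignatureGeneList,
    center_only: bool = False,
) -> CentroidPair:
    """Median centroids of the standardized signature submatrix per group.

    Standardization is a per-gene z-score across *all* samples by default
    (``center_only=True`` subtracts the mean without scaling).
    """
    missing = set(signature.genes) - set(matrix.feature_ids)
    if missing:
        raise MissingGenesError(missing)
    labels = labels.reindex(matrix.sample_ids)
    csm_ids = labels.index[labels == CSM]
    nse_ids = labels.index[labels == NSE]
    if len(csm_ids) == 0 or len(nse_ids) == 0:
        raise ValidationError("both reference groups must be non-empty")
    z = standardize_genes(matrix.values.loc[signature.genes], center_only=center_only)
    return CentroidPair(
        csm_median=z[csm_ids].median(axis=1),
        nse_median=z[nse_ids].median(axis=1),
        source={"n_csm": len(csm_ids), "n_nse": len(nse_ids)},
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def score_sample(
    sample: pd.Series,
    centroids: CentroidPair,
    cutoff: float = 0.0,
    band_halfwidth: float = 0.0,
    sample_id: str = "",
) -> StemnessScore:
    """Score one sample's standardized signature vector against the centroids.

    ``sample`` must cover every centroid gene. CS/M(r) and NS/E(r) are Pearson
    correlations across genes; ``delta_r = csm_r - nse_r``.
    """
    genes = centroids.genes
    if len(genes) < 3:
        raise ValidationError("need >= 3 signature genes for a correlation")
    missing = set(genes) - set(sample.index)
    if missing:
        raise MissingGenesError(missing)
    x = sample.reindex(genes).to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample vector: correlation undefined")
    c_csm = centroids.csm_median.to_numpy(dtype=float)
    c_nse = centroids.nse_median.to_numpy(dtype=float)
    if np.ptp(c_csm) == 0 or np.ptp(c_nse) == 0:
        raise ValidationError("constant centroid: rebuild references")
    csm_r = _pearson(x, c_csm)
    nse_r = _pearson(x, c_nse)
    delta = csm_r - nse_r
    call = call_from_score(delta, cutoff=cutoff, band_halfwidth=band_halfwidth)
    return StemnessScore(sample_id or str(sample.name), csm_r, nse_r, delta, call)


def score_matrix(
    matrix: ExpressionMatrix,
    centroids: CentroidPair,
    cutoff: float = 0.0,
    band_halfwidth: float = 0.0,
    center_only: bool = False,
) -> pd.DataFrame:
    """Score every sample of a cohort; standardizes the cohort's own genes.

    Returns a DataFrame indexed by sample id with columns csm_r, nse_r,
    delta_r, call.
    """
    missing = set(centroids.genes) - set(matrix.feature_ids)
    if missing:
        raise MissingGenesError(missing)
    z = standardize_genes(matrix.values.loc[centroids.genes], center_only=center_only)
    rows = []
    for sample_id in z.columns:
        s = score_sample(z[sample_id], centroids, cutoff, band_halfwidth,
                         sample_id=sample_id)
        rows.append({"sample_id": s.sample_id, "csm_r": s.csm_r,
                     "nse_r": s.nse_r, "delta_r": s.delta_r, "call": s.call})
    return pd.DataFrame(rows).set_index("sample_id")


def call_from_score(delta_r: float, cutoff: float = 0.0,
                    band_halfwidth: float = 0.0) -> str:
    """Categorical call from Delta(r).

    ``delta_r > cutoff + band`` -> CS/M; ``delta_r <= cutoff - band`` -> NS/E;
    anything inside the band -> I. With a zero band the boundary value itself
    is NS/E (ties go to the epithelial side, since only strictly positive
    scores indicate a stem-like phenotype relative to the cutoff).
    """
    if band_halfwidth < 0:
        raise ValidationError("band_halfwidth must be >= 0")
    if delta_r > cutoff + band_halfwidth:
        return CSM
    if delta_r <= cutoff - band_halfwidth:
        return NSE
    return INTERMEDIARY


def trace_plasticity(
    pre_scores: pd.DataFrame,
    post_scores: pd.DataFrame,
    pairing: dict[str, str] | None = None,
    ignore_intermediary: bool = True,
) -> pd.DataFrame:
    """Trace phenotype switching between paired pre/post-treatment scores.

    ``pairing`` maps each pre sample id to its post sample id (identity if
    omitted). A pair *switched* when the pre and post calls are distinct
    non-intermediary labels; pairs touching an I call are never counted as
    switches when ``ignore_intermediary`` (the default).

    Returns one row per pair: pre_call, post_call, switched, delta_of_delta_r.
    """
    if pairing is None:
        pairing = {s: s for s in pre_scores.index}
    missing_pre = set(pairing) - set(pre_scores.index)
    missing_post = set(pairing.values()) - set(post_scores.index)
    if missing_pre or missing_post:
        raise ValidationError(
            f"unmatched pairs: pre={sorted(missing_pre)} post={sorted(missing_post)}"
        )
    rows = []
    for pre_id, post_id in pairing.items():
        pre_call = pre_scores.loc[pre_id, "call"]
        post_call = post_scores.loc[post_id, "call"]
        if ignore_intermediary and INTERMEDIARY in (pre_call, post_call):
            switched = False
        else:
            switched = pre_call != post_call
        rows.append({
            "pre_id": pre_id, "post_id": post_id,
            "pre_call": pre_call, "post_call": post_call,
            "switched": switched,
            "delta_of_delta_r": post_scores.loc[post_id, "delta_r"]
            - pre_scores.loc[pre_id, "delta_r"],
        })
    return pd.DataFrame(rows).set_index("pre_id")
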