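"""Derivation of a directional stemness/EMT signature from two labeled cohorts.

The pipeline mirrors how robust two-phenotype gene lists are built from
independent cell-line panels: rank differentially expressed genes per dataset
by Welch t-test (p < 0.05, top 200), intersect the two lists keeping only
direction-concordant genes, apply hard fold-change (>= 3-fold) and p-value
(< 2e-4) filters in both datasets, and finally require strong within-arm
inter-gene correlation. The canonical outcome on real breast-cancer panels is
a 15-gene list with 8 genes up- and 7 down-regulated in stem-like/mesenchymal
(CS/M) cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, EmptySignatureError, ValidationError
from .io import ExpressionMatrix
from .labels import CSM, NSE

__all__ = [
    "DerivationParams",
    "SignatureGeneList",
    "welch_t_test",
    "rank_de_genes",
    "derive_signature",
    "rank_sum_combine",
]

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class DerivationParams:
    """Filter thresholds of the signature-derivation pipeline.

    ``min_fold`` is on the linear scale (3 means 3-fold in either direction);
    ``min_intercorr`` thresholds the mean absolute pairwise Pearson r of a
    candidate against the other same-direction candidates.
    """

    top_n: int = 200
    initial_p: float = 0.05
    min_fold: float = 3.0
    max_p: float = 2e-4
    min_intercorr: float = 0.5
    order_by: str = "p"  # or "fold"

    def validate(self) -> None:
        if not (0 < self.max_p <= self.initial_p <= 1):
            raise ValidationError("need 0 < max_p <= initial_p <= 1")
        if self.min_fold < 1:
            raise ValidationError("min_fold must be >= 1")
        if not 0.0 <= self.min_intercorr <= 1.0:
            raise ValidationError("min_intercorr must be in [0, 1]")
        if self.top_n < 0:
            raise ValidationError("top_n must be >= 0")
        if self.order_by not in ("p", "fold"):
            raise ValidationError("order_by must be 'p' or 'fold'")


@dataclass
class SignatureGeneList:
    """A directional gene signature with per-dataset evidence.

    ``table`` is indexed by feature id with columns ``direction`` ("up" =
    elevated in CS/M, "down" = elevated in NS/E), ``fold_a``, ``p_a``,
    ``fold_b``, ``p_b``. ``provenance`` records dataset ids and the filter
    parameters used.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("signature entries must be unique")
        bad = set(self.table["direction"]) - {"up", "down"}
        if bad:
            raise ValidationError(f"unknown directions: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def up_genes(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "up"])

    @property
    def down_genes(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "down"])

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path) -> "SignatureGeneList":
        table = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(table)

    @classmethod
    def from_directions(cls, directions: Mapping[str, str]) -> "SignatureGeneList":
        """Build a bare signature from a feature -> {"up","down"} mapping."""
        table = pd.DataFrame({"direction": pd.Series(dict(directions))})
        table.index.name = "feature_id"
        return cls(table)


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Degenerate conventions: both groups constant with equal means -> (0, 1);
    constant with unequal means -> p is the smallest positive float.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), _TINY_P
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def rank_de_genes(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    top_n: int = 200,
    initial_p: float = 0.05,
    order_by: str = "p",
) -> pd.DataFrame:
    """Rank differentially expressed genes between CS/M and NS/E groups.

    Per gene: Welch t-test of CS/M vs NS/E samples on log2 values; genes with
    p < ``initial_p`` are ordered (p ascending by default, or |fold|
    descending) and truncated to ``top_n``. Fold change is the anti-logged
    group-mean difference ``2**|mean_csm - mean_nse|`` with the sign carried
    by ``direction``.

    Returns a DataFrame indexed by feature id with columns ``direction``,
    ``fold``, ``p``, ``t``.
    """
    labels = labels.reindex(matrix.sample_ids)
    csm_ids = labels.index[labels == CSM]
    nse_ids = labels.index[labels == NSE]
    if len(csm_ids) < 2 or len(nse_ids) < 2:
        raise ValidationError("each phenotype group needs >= 2 samples")
    if top_n > matrix.n_features:
        raise ValidationError("top_n exceeds feature count")

    vals = matrix.values
    a = vals[csm_ids].to_numpy()
    b = vals[nse_ids].to_numpy()
    # vectorized Welch across genes, with the degenerate-variance convention
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    const = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    p = np.where(const & (diff == 0), 1.0, p)
    p = np.where(const & (diff != 0), _TINY_P, p)
    t = np.where(const, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)

    out = pd.DataFrame(
        {
            "direction": np.where(diff >= 0, "up", "down"),
            "fold": np.power(2.0, np.abs(diff)),
            "p": p,
            "t": t,
        },
        index=vals.index,
    )
    out = out[out["p"] < initial_p]
    if order_by == "p":
        out = out.sort_values(["p", "fold"], ascending=[True, False],
                              kind="mergesort")
    else:
        out = out.sort_values(["fold", "p"], ascending=[False, True],
                              kind="mergesort")
    return out.iloc[:top_n]


def _mean_abs_intercorr(vals: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Mean |Pearson r| of each gene against the other listed genes."""
    if len(genes) == 1:
        return pd.Series(1.0, index=genes)  # vacuous: no partners to disagree with
    corr = np.corrcoef(vals.loc[genes].to_numpy())
    np.fill_diagonal(corr, np.nan)
    mean_abs = np.nanmean(np.abs(corr), axis=1)
    return pd.Series(mean_abs, index=genes)


def derive_signature(
    dataset_a: ExpressionMatrix,
    labels_a: pd.Series,
    dataset_b: ExpressionMatrix,
    labels_b: pd.Series,
    params: DerivationParams | None = None,
    dataset_ids: tuple[str, str] = ("dataset_a", "dataset_b"),
) -> SignatureGeneList:
    """Derive the directional signature shared by two labeled cohorts.

    Pipeline: top-``top_n`` DE genes per dataset -> intersect features with
    concordant direction -> keep genes with fold >= ``min_fold`` and
    p < ``max_p`` in *both* datasets -> keep genes whose mean absolute
    pairwise correlation with the other retained same-direction genes is
    >= ``min_intercorr`` in both datasets.
    """
    params = params or DerivationParams()
    params.validate()
    de_a = rank_de_genes(dataset_a, labels_a, params.top_n, params.initial_p,
                         params.order_by)
    de_b = rank_de_genes(dataset_b, labels_b, params.top_n, params.initial_p,
                         params.order_by)

    shared = de_a.index.intersection(de_b.index)
    concordant = [g for g in shared
                  if de_a.loc[g, "direction"] == de_b.loc[g, "direction"]]
    if not concordant:
        raise EmptySignatureError(
            "no direction-concordant genes shared by the two top lists"
        )

    sub_a, sub_b = de_a.loc[concordant], de_b.loc[concordant]
    passing = (
        (sub_a["fold"] >= params.min_fold) & (sub_a["p"] < params.max_p)
        & (sub_b["fold"] >= params.min_fold) & (sub_b["p"] < params.max_p)
    )
    candidates = sub_a.index[passing].tolist()
    if not candidates:
        raise EmptySignatureError("no gene passed the fold/p filters in both datasets")

    kept: list[str] = []
    for direction in ("up", "down"):
        arm = [g for g in candidates if sub_a.loc[g, "direction"] == direction]
        if not arm:
            continue
        corr_a = _mean_abs_intercorr(dataset_a.values, arm)
        corr_b = _mean_abs_intercorr(dataset_b.values, arm)
        kept.extend(g for g in arm
                    if corr_a[g] >= params.min_intercorr
                    and corr_b[g] >= params.min_intercorr)
    if not kept:
        raise EmptySignatureError("no gene passed the inter-gene correlation filter")

    kept = [g for g in candidates if g in set(kept)]  # stable original order
    table = pd.DataFrame(
        {
            "direction": sub_a.loc[kept, "direction"],
            "fold_a": sub_a.loc[kept, "fold"],
            "p_a": sub_a.loc[kept, "p"],
            "fold_b": sub_b.loc[kept, "fold"],
            "p_b": sub_b.loc[kept, "p"],
        }
    )
    table.index.name = "feature_id"
    provenance = {
        "dataset_ids": dataset_ids,
        "params": params,
        "n_top_a": len(de_a),
        "n_top_b": len(de_b),
        "n_concordant": len(concordant),
        "n_fold_p_pass": len(candidates),
    }
    return SignatureGeneList(table, provenance)


def rank_sum_combine(
    ranking_a: Mapping[str, int],
    ranking_b: Mapping[str, int],
) -> pd.DataFrame:
    """Combine two rankings of the same items by summing their rank numbers.

    Used to find gene sets commonly enriched in two independent analyses:
    each item's score is ``rank_a + rank_b`` and the output is sorted by that
    ranksum ascending, ties broken lexicographically by name.
    """
    names_a, names_b = set(ranking_a), set(ranking_b)
    if names_a != names_b:
        diff = sorted(names_a.symmetric_difference(names_b))
        raise ValidationError(f"rankings cover different name sets: {diff}")
    rows = sorted(
        ((name, ranking_a[name] + ranking_b[name]) for name in names_a),
        key=lambda kv: (kv[1], kv[0]),
    )
    return pd.DataFrame(rows, columns=["name", "ranksum"]).set_index("name")
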