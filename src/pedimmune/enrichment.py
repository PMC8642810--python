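"""Single-sample GSEA immune-signature scoring.

Each sample is scored independently against each gene set by a
rank-weighted running sum: genes are sorted by expression (descending),
and the enrichment score is the accumulated difference between the
weighted fraction of set genes encountered and the fraction of non-set
genes encountered, summed over every position in the ranking.  A
positive score means the set's genes sit toward the top of the sample's
expression ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .normalize import NormalizedMatrix


@dataclass
class EnrichmentConfig:
    """ssGSEA parameters.

    alpha is the rank-weight exponent (0 gives unweighted Kolmogorov-
    Smirnov-style walks); 0.75 is the GenePattern ssGSEAProjection
    default.  Ties in expression are broken by input gene order (stable).
    """

    alpha: float = 0.75
    normalize_scores: bool = False
    tie_policy: str = "stable-input-order"

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class SignatureScores:
    """Samples x signatures enrichment-score table."""

    sample_ids: list
    signature_names: list
    scores: np.ndarray  # samples x signatures

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.sample_ids, columns=self.signature_names
        )

    def column(self, name: str) -> pd.Series:
        return self.to_frame()[name]


def ssgsea_scores(
    expr: NormalizedMatrix | pd.DataFrame,
    sets: GeneSetCollection,
    cfg: EnrichmentConfig | None = None,
) -> SignatureScores:
    """Score every sample against every gene set.

    Genes are ranked on ``log2_fpkm`` (any monotone transform of FPKM
    gives identical ranks, hence identical scores).  Sets are intersected
    with the matrix's genes; empty sets are dropped with a warning; a set
    covering every gene is an error because the out-of-set walk is
    undefined.
    """
    cfg = cfg or EnrichmentConfig()
    if isinstance(expr, NormalizedMatrix):
        values = expr.log2_fpkm
        gene_ids = list(expr.gene_ids)
        sample_ids = list(expr.sample_ids)
    else:
        values = expr.to_numpy(dtype=float)
        gene_ids = list(expr.index)
        sample_ids = list(expr.columns)
    n_genes, n_samples = values.shape
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    memberships = []
    kept_names = []
    for name, genes in sets:
        member = np.zeros(n_genes, dtype=bool)
        for g in genes:
            i = gene_pos.get(g)
            if i is not None:
                member[i] = True
        m = int(member.sum())
        if m == 0:
            warnings.warn(f"gene set {name!r} shares no genes with the matrix; dropped")
            continue
        if m == n_genes:
            raise ValueError(f"gene set {name!r} covers every gene in the matrix")
        memberships.append(member)
        kept_names.append(name)
    if not memberships:
        raise ValueError("no gene set overlaps the expression matrix")
    member_mat = np.stack(memberships, axis=1)  # genes x sets

    scores = np.empty((n_samples, len(kept_names)))
    ranks = np.arange(n_genes, 0, -1, dtype=float)  # G, G-1, ..., 1 down the list
    weights = ranks**cfg.alpha
    for j in range(n_samples):
        # stable sort on descending expression; ties keep input gene order
        order = np.argsort(-values[:, j], kind="stable")
        member_sorted = member_mat[order]  # genes(sorted) x sets
        in_weight = np.where(member_sorted, weights[:, None], 0.0)
        cum_in = np.cumsum(in_weight, axis=0)
        denom_in = cum_in[-1]  # total weight per set
        m = member_sorted.sum(axis=0)
        cum_out = np.cumsum(~member_sorted, axis=0)
        p_in = cum_in / denom_in
        p_out = cum_out / (n_genes - m)
        scores[j] = (p_in - p_out).sum(axis=0)

    if cfg.normalize_scores:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return SignatureScores(
        sample_ids=sample_ids, signature_names=kept_names, scores=scores
    )


def _group_apply(scores: SignatureScores, groups: dict, fn) -> pd.DataFrame:
    df = scores.to_frame()
    missing = [s for s in df.index if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    labels = pd.Series({s: groups[s] for s in df.index})
    out = df.groupby(labels).agg(fn)
    empty = out.index[out.isna().all(axis=1)]
    if len(empty):
        warnings.warn(f"empty groups excluded: {list(empty)}")
        out = out.drop(index=empty)
    return out


def positive_fraction(scores: SignatureScores, groups: dict) -> pd.DataFrame:
    """Percentage of samples per group with a strictly positive score.

    This is the heat-map statistic summarizing how often each immune cell
    subtype is called present in each cancer type.
    """
    return _group_apply(scores, groups, lambda col: 100.0 * np.mean(col > 0))


def group_median_scores(scores: SignatureScores, groups: dict) -> pd.DataFrame:
    """Median enrichment score per group per signature."""
    return _group_apply(scores, groups, "median")
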