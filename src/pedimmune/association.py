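"""Checkpoint-gene vs CD8+ infiltrate association.

Within each cancer type, the expression of each immune-checkpoint gene
(log2 FPKM) is correlated with the per-sample CD8+ T cell enrichment
score by Spearman rank correlation; p-values are Benjamini-Hochberg
adjusted across genes within the type, and a (type, gene) pair is called
significant iff rho > 0.3 and q < 0.05, both strict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix

RHO_THRESHOLD = 0.3
Q_THRESHOLD = 0.05


def spearman(x, y):
    """Spearman rank correlation with the t-approximation p-value.

    Pearson correlation of mid-ranks; p from
    t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def checkpoint_association(
    expr: NormalizedMatrix,
    cd8_scores: pd.Series,
    checkpoint_genes,
    groups: dict | None = None,
) -> pd.DataFrame:
    """Per-(cancer type, gene) Spearman association with CD8 infiltrate.

    Types with fewer than 4 samples are excluded with a warning; genes
    absent from the matrix are skipped with a warning.  BH adjustment is
    applied within each cancer type across its genes.
    """
    groups = groups if groups is not None else expr.sample_groups
    log2 = pd.DataFrame(expr.log2_fpkm, index=expr.gene_ids, columns=expr.sample_ids)
    genes = []
    for g in checkpoint_genes:
        if g in log2.index:
            genes.append(g)
        else:
            warnings.warn(f"checkpoint gene {g!r} absent from the matrix; skipped")
    if not genes:
        raise ValueError("no checkpoint gene present in the matrix")
    labels = pd.Series({s: groups[s] for s in expr.sample_ids})

    records = []
    for cancer_type, samples in labels.groupby(labels).groups.items():
        samples = list(samples)
        if len(samples) < 4:
            warnings.warn(
                f"cancer type {cancer_type!r} has {len(samples)} samples (< 4); excluded"
            )
            continue
        cd8 = cd8_scores.loc[samples].to_numpy(dtype=float)
        rows = []
        for g in genes:
            x = log2.loc[g, samples].to_numpy(dtype=float)
            try:
                rho, p = spearman(x, cd8)
            except ValueError:
                warnings.warn(f"gene {g!r} constant in {cancer_type!r}; excluded")
                continue
            rows.append({"cancer_type": cancer_type, "gene_id": g, "spearman_rho": rho, "p_value": p})
        if not rows:
            continue
        sub = pd.DataFrame(rows)
        sub["bh_q"] = bh_adjust(sub["p_value"])
        sub["significant"] = (sub["spearman_rho"] > RHO_THRESHOLD) & (
            sub["bh_q"] < Q_THRESHOLD
        )
        records.append(sub)
    if not records:
        raise ValueError("no cancer type with enough samples")
    return pd.concat(records, ignore_index=True)
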