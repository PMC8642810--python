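"""Between-sample normalization: TMM scaling factors and FPKM.

The trimmed mean of M-values (TMM) corrects for composition bias between
libraries: a few very highly expressed genes in one sample depress the
apparent expression of everything else when dividing by total counts.
The factor for sample j against a reference r is a precision-weighted
mean of per-gene log-ratios, after trimming the most extreme log-ratios
(M) and the most extreme average abundances (A).  Counts are then
converted to FPKM using the TMM-scaled (effective) library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import CountMatrix


@dataclass
class NormalizedMatrix:
    """TMM-normalized FPKM expression, genes x samples."""

    gene_ids: list
    sample_ids: list
    tmm_factors: np.ndarray
    fpkm: np.ndarray
    log2_fpkm: np.ndarray
    sample_groups: dict

    def to_frame(self, log: bool = False):
        import pandas as pd

        values = self.log2_fpkm if log else self.fpkm
        return pd.DataFrame(values, index=self.gene_ids, columns=self.sample_ids)


def _choose_reference(counts: np.ndarray) -> int:
    """Sample whose upper-quartile count proportion is closest to the mean."""
    props = counts / counts.sum(axis=0, keepdims=True)
    q75 = np.percentile(props, 75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def _rank_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping values whose rank lies inside the trim bounds.

    Uses mid-ranks; with n values, the lowest and highest floor(n*trim)
    ranks are discarded on each side.
    """
    n = len(values)
    r = rankdata(values)
    lo = np.floor(n * trim) + 1
    hi = n + 1 - lo
    return (r >= lo) & (r <= hi)


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: int | None = None,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factor per sample.

    For each sample j against the reference r, over genes with positive
    counts in both:

        M_g = log2((x_gj/N_j) / (x_gr/N_r))
        A_g = 0.5 * log2((x_gj/N_j) * (x_gr/N_r))

    Genes in the extreme ``trim_m`` tails of M and ``trim_a`` tails of A
    are discarded; the factor is 2 to the precision-weighted mean of the
    surviving M with weights

        w_g = 1 / ((N_j - x_gj)/(N_j x_gj) + (N_r - x_gr)/(N_r x_gr))

    Factors are rescaled by their geometric mean so they multiply to one.

    Parameters
    ----------
    counts : CountMatrix or ndarray (genes x samples)
    trim_m, trim_a : float
        Two-sided trim fractions for the log-ratio and abundance.
    reference : int, optional
        Force a reference column; by default the sample whose 75th
        percentile of count proportions is closest to the cohort mean.
    """
    x = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    x = x.astype(float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    N = x.sum(axis=0)
    if np.any(N <= 0):
        raise ValueError("every sample needs a positive total count")
    ref = _choose_reference(x) if reference is None else int(reference)
    xr, Nr = x[:, ref], N[ref]

    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        xj, Nj = x[:, j], N[j]
        both = (xj > 0) & (xr > 0)
        if not np.any(both):
            raise ValueError(
                f"sample {j} shares no co-expressed genes with the reference"
            )
        pj, pr = xj[both] / Nj, xr[both] / Nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        keep = _rank_keep(M, trim_m) & _rank_keep(A, trim_a)
        if not np.any(keep):
            raise ValueError(
                f"all genes trimmed for sample {j}; use smaller trim fractions"
            )
        w = 1.0 / (
            (Nj - xj[both][keep]) / (Nj * xj[both][keep])
            + (Nr - xr[both][keep]) / (Nr * xr[both][keep])
        )
        log_factors[j] = np.average(M[keep], weights=w)

    factors = 2.0 ** (log_factors - log_factors.mean())
    return factors


def fpkm(counts: CountMatrix, factors: np.ndarray | None = None) -> NormalizedMatrix:
    """Fragments per kilobase per million, on TMM-effective library sizes.

    fpkm_gj = x_gj * 1e9 / (L_g * N_j * f_j); log2 uses pseudocount 1.
    """
    if factors is None:
        factors = tmm_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (len(counts.sample_ids),) or np.any(factors <= 0):
        raise ValueError("need one positive TMM factor per sample")
    N = counts.library_sizes.astype(float)
    if np.any(N <= 0):
        raise ValueError("zero library size")
    eff = N * factors
    values = counts.counts * 1e9 / (counts.gene_lengths_bp[:, None] * eff[None, :])
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        tmm_factors=factors,
        fpkm=values,
        log2_fpkm=np.log2(values + 1.0),
        sample_groups=dict(counts.sample_groups),
    )
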