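"""Tumor-specific antigen screening.

Within each cancer type, genes are compared against the normal-tissue
panel (excluding the immune-privileged germline tissues, testis and
ovary) with a negative-binomial exact test on library-size-equalized
counts, and a candidate antigen must satisfy all four criteria:

1. differential-expression p-value <= 1e-5 (vs normals minus testis/ovary);
2. log2 fold change >= 4 (i.e. >= 16-fold over those normals);
3. median FPKM < 1 in every vital organ (heart, brain);
4. median FPKM >= 5 in the tumor type.

Candidates are annotated by membership in the screened categories
(cell-surface proteins, transcription factors, tumor germline antigens).
Tumor germline antigens (PRAME-like genes expressed in tumors and
testis/ovary but silent in somatic tissues) survive the screen precisely
because testis and ovary are excluded from the comparator.

The DE engine is deliberately minimal and fully enumerable: a moment
dispersion estimator plus an exact conditional test on group count sums.
Externally computed DE tables may be passed to :func:`screen_candidates`
to bypass it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneSetCollection
from .normalize import NormalizedMatrix


@dataclass
class DEConfig:
    """Screen thresholds and comparator composition."""

    dispersion_mode: str = "common"
    logfc_prior_count: float = 0.5
    p_threshold: float = 1e-5
    logfc_threshold: float = 4.0
    vital_fpkm_max: float = 1.0
    tumor_fpkm_min: float = 5.0
    excluded_normals: frozenset = frozenset({"testis", "ovary"})
    vital_organs: frozenset = frozenset({"heart", "brain", "cerebrum", "cerebellum"})

    def __post_init__(self):
        if self.dispersion_mode not in ("common", "per_gene"):
            raise ValueError(f"unknown dispersion mode {self.dispersion_mode!r}")
        for name in ("p_threshold", "logfc_threshold", "vital_fpkm_max", "tumor_fpkm_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.excluded_normals = frozenset(self.excluded_normals)
        self.vital_organs = frozenset(self.vital_organs)
        if self.excluded_normals & self.vital_organs:
            raise ValueError("excluded_normals and vital_organs must be disjoint")


def _scale_to_common(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Round counts rescaled to the geometric-mean effective library size."""
    common = np.exp(np.mean(np.log(lib_sizes)))
    return np.rint(counts * (common / lib_sizes)[None, :])


def estimate_dispersion(
    counts,
    groups=None,
    mode: str = "common",
    lib_sizes=None,
):
    """Moment estimator of the negative-binomial dispersion.

    On counts rescaled to a common library size, the per-gene estimator is
    phi_g = max(0, (s_g^2 - xbar_g) / xbar_g^2) with s^2 the within-group
    pooled sample variance.  ``mode="common"`` returns the median of
    phi_g over genes with xbar_g > 1; ``"per_gene"`` returns the vector.

    Parameters
    ----------
    counts : ndarray (genes x samples) or CountMatrix
    groups : array-like of labels per sample, optional
        Variances are pooled within groups (each needs >= 2 samples).
    lib_sizes : array-like, optional
        Effective library sizes; defaults to column sums.
    """
    x = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    x = x.astype(float)
    if lib_sizes is None:
        lib_sizes = x.sum(axis=0)
    y = x * (np.exp(np.mean(np.log(lib_sizes))) / np.asarray(lib_sizes, float))[None, :]
    if groups is None:
        groups = np.zeros(y.shape[1], dtype=int)
    groups = np.asarray(groups)
    ss = np.zeros(y.shape[0])
    dof = 0
    for g in np.unique(groups):
        cols = y[:, groups == g]
        if cols.shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        ss += cols.var(axis=1, ddof=1) * (cols.shape[1] - 1)
        dof += cols.shape[1] - 1
    s2 = ss / dof
    xbar = y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(xbar > 0, (s2 - xbar) / xbar**2, 0.0)
    phi = np.maximum(phi, 0.0)
    if mode == "per_gene":
        return phi
    informative = xbar > 1
    if not np.any(informative):
        raise ValueError("no gene with mean scaled count > 1")
    return float(np.median(phi[informative]))


_TIE_TOL = 1e-10  # relative tolerance when comparing split probabilities
_ENUM_CAP = 16384  # full enumeration below this total


def _split_logpmf_fn(total: int, n_a: int, n_b: int, phi: float):
    """Log-pmf of the conditional split a | a + b = total, and its log-normalizer.

    For phi > 0 both group sums are NB with the same success parameter
    q = 1/(1 + phi*mu), so the conditional distribution is the ratio of
    negative-binomial coefficients with sizes r_a = n_a/phi, r_b = n_b/phi
    and normalizer C(total + r_a + r_b - 1, total) (NB Vandermonde);
    phi = 0 gives the binomial.  Returns (f, logZ) with the *unnormalized*
    log mass f(a) such that p(a) = exp(f(a) - logZ); f is concave in a.
    """
    from scipy.special import gammaln

    if phi <= 0:
        pi_a = n_a / (n_a + n_b)
        la, lb = np.log(pi_a), np.log1p(-pi_a)

        def f(a):
            a = np.asarray(a, dtype=float)
            return (
                -gammaln(a + 1.0)
                - gammaln(total - a + 1.0)
                + a * la
                + (total - a) * lb
            )

        logZ = -gammaln(total + 1.0)
        return f, logZ

    r_a, r_b = n_a / phi, n_b / phi

    def f(a):
        a = np.asarray(a, dtype=float)
        return (
            gammaln(a + r_a)
            - gammaln(a + 1.0)
            + gammaln(total - a + r_b)
            - gammaln(total - a + 1.0)
        )

    logZ = (
        gammaln(total + r_a + r_b)
        - gammaln(r_a + r_b)
        - gammaln(total + 1.0)
        + gammaln(r_a)
        + gammaln(r_b)
    )
    return f, logZ


def _interval_logsum(f, lo: int, hi: int, chunk: int = 1 << 21) -> float:
    """log sum_{a=lo..hi} exp(f(a)), chunked; -inf on an empty interval."""
    if hi < lo:
        return -np.inf
    pieces = []
    for start in range(lo, hi + 1, chunk):
        a = np.arange(start, min(start + chunk, hi + 1))
        pieces.append(f(a))
    v = np.concatenate(pieces)
    m = v.max()
    return float(m + np.log(np.exp(v - m).sum()))


def _exact_p(total: int, n_a: int, n_b: int, s_a: int, phi: float) -> float:
    """Two-sided exact conditional p for the split (s_a, total - s_a).

    Group sums are NB with mean n*mu and dispersion phi/n under the null
    (mu = total / (n_a + n_b) per library); conditioning on the total, the
    p-value sums the probabilities of all splits no more likely than the
    observed one.  phi = 0 reduces to the exact binomial test.

    Small totals are fully enumerated; large totals exploit the
    log-concavity of the split distribution: the set of splits strictly
    more likely than the observed one is a contiguous window around the
    mode, located by bisection, and whichever of the window or its
    complement is shorter is summed directly.
    """
    if total == 0:
        return 1.0
    f, logZ = _split_logpmf_fn(total, n_a, n_b, phi)

    if total <= _ENUM_CAP:
        logp = f(np.arange(total + 1))
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
        obs = p[s_a]
        return float(min(p[p <= obs * (1.0 + _TIE_TOL)].sum(), 1.0))

    if phi > 0 and min(n_a, n_b) / phi < 1.0:
        # NB size below 1: the split log-mass need not be concave
        # (U-shaped or mixed), so enumerate everything in chunks
        thr = float(f(s_a)) + _TIE_TOL
        acc = -np.inf
        chunk = 1 << 21
        for start in range(0, total + 1, chunk):
            a = np.arange(start, min(start + chunk, total + 1))
            v = f(a)
            v = v[v <= thr]
            if v.size:
                m = max(acc, v.max())
                acc = m + np.log(np.exp(acc - m) + np.exp(v - m).sum())
        return float(min(np.exp(acc - logZ), 1.0)) if acc > -np.inf else 0.0

    # mode by integer ternary search on the concave log mass
    lo, hi = 0, total
    while hi - lo > 2:
        m1 = lo + (hi - lo) // 3
        m2 = hi - (hi - lo) // 3
        if f(m1) < f(m2):
            lo = m1 + 1
        else:
            hi = m2 - 1
    mode = lo + int(np.argmax(f(np.arange(lo, hi + 1))))
    thr = float(f(s_a)) + _TIE_TOL  # window = splits strictly more likely

    if f(mode) <= thr:
        return 1.0
    # left edge: smallest a with f(a) > thr (f increasing on [0, mode])
    lo, hi = 0, mode
    while lo < hi:
        mid = (lo + hi) // 2
        if f(mid) > thr:
            hi = mid
        else:
            lo = mid + 1
    a_left = lo
    # right edge: largest a with f(a) > thr (f decreasing on [mode, total])
    lo, hi = mode, total
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if f(mid) > thr:
            lo = mid
        else:
            hi = mid - 1
    a_right = lo

    window = a_right - a_left + 1
    if window <= (total + 1) - window:
        s = _interval_logsum(f, a_left, a_right)
        p = 1.0 - np.exp(s - logZ)
        if p >= 0.01:  # complement is accurate only when p is not tiny
            return float(min(max(p, 0.0), 1.0))
    left = _interval_logsum(f, 0, a_left - 1)
    right = _interval_logsum(f, a_right + 1, total)
    m = max(left, right)
    if m == -np.inf:
        return 0.0
    s = m + np.log(np.exp(left - m) + np.exp(right - m))
    return float(min(np.exp(s - logZ), 1.0))


def nb_exact_test(
    group_a_counts,
    group_b_counts,
    phi,
    lib_sizes_a=None,
    lib_sizes_b=None,
    prior_count: float = 0.5,
    gene_ids=None,
) -> pd.DataFrame:
    """Exact negative-binomial test per gene, group A vs group B.

    Counts are rescaled to a common effective library size and rounded so
    the conditional group-sum argument applies, then each gene's observed
    split of the total between the groups is scored by :func:`_exact_p`.
    The fold change is log2((cpm_A + prior) / (cpm_B + prior)) on
    per-million-scaled group means.

    Returns a DataFrame with ``gene_id``, ``log2_fc`` and ``p_value``.
    """
    xa = np.atleast_2d(np.asarray(group_a_counts, dtype=float))
    xb = np.atleast_2d(np.asarray(group_b_counts, dtype=float))
    if np.any(xa < 0) or np.any(xb < 0):
        raise ValueError("negative counts")
    if lib_sizes_a is None:
        lib_sizes_a = xa.sum(axis=0)
    if lib_sizes_b is None:
        lib_sizes_b = xb.sum(axis=0)
    all_libs = np.concatenate([np.asarray(lib_sizes_a, float), np.asarray(lib_sizes_b, float)])
    common = np.exp(np.mean(np.log(all_libs)))
    ya = np.rint(xa * (common / np.asarray(lib_sizes_a, float))[None, :])
    yb = np.rint(xb * (common / np.asarray(lib_sizes_b, float))[None, :])
    n_a, n_b = ya.shape[1], yb.shape[1]
    s_a = ya.sum(axis=1).astype(np.int64)
    s_b = yb.sum(axis=1).astype(np.int64)
    phi_vec = np.broadcast_to(np.asarray(phi, dtype=float), s_a.shape)

    cpm_scale = 1e6 / common
    mean_a = ya.mean(axis=1) * cpm_scale
    mean_b = yb.mean(axis=1) * cpm_scale
    log2_fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))
    log2_fc[(s_a + s_b) == 0] = 0.0

    pvals = np.array(
        [
            _exact_p(int(t), n_a, n_b, int(a), float(ph))
            for t, a, ph in zip(s_a + s_b, s_a, phi_vec)
        ]
    )
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(s_a))]
    return pd.DataFrame({"gene_id": gene_ids, "log2_fc": log2_fc, "p_value": pvals})


def differential_expression(
    counts: CountMatrix,
    tumor_type: str,
    normal_labels,
    cfg: DEConfig | None = None,
    tmm_factors=None,
) -> pd.DataFrame:
    """Tumor-vs-normal DE for one cancer type with the built-in engine.

    The comparator is every sample whose group is in ``normal_labels``
    minus ``cfg.excluded_normals``.
    """
    cfg = cfg or DEConfig()
    labels = np.array([counts.sample_groups[s] for s in counts.sample_ids])
    tumor_cols = labels == tumor_type
    normal_set = set(normal_labels) - cfg.excluded_normals
    normal_cols = np.isin(labels, sorted(normal_set))
    if tumor_cols.sum() == 0:
        raise ValueError(f"no samples of tumor type {tumor_type!r}")
    if normal_cols.sum() == 0:
        raise ValueError("no comparator normal samples after exclusions")
    lib = counts.library_sizes.astype(float)
    if tmm_factors is not None:
        lib = lib * np.asarray(tmm_factors, dtype=float)
    both = tumor_cols | normal_cols
    group = np.where(tumor_cols[both], tumor_type, "normal")
    phi = estimate_dispersion(
        counts.counts[:, both],
        groups=group,
        mode=cfg.dispersion_mode,
        lib_sizes=lib[both],
    )
    return nb_exact_test(
        counts.counts[:, tumor_cols],
        counts.counts[:, normal_cols],
        phi,
        lib_sizes_a=lib[tumor_cols],
        lib_sizes_b=lib[normal_cols],
        prior_count=cfg.logfc_prior_count,
        gene_ids=list(counts.gene_ids),
    )


def screen_candidates(
    de: pd.DataFrame,
    fpkm: NormalizedMatrix,
    tumor_type: str,
    category_lists: GeneSetCollection,
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """Apply the four-criterion screen to one cancer type's DE table.

    Returns the full per-gene evidence table: the four criterion values
    and booleans, a BH-adjusted q column (reported for transparency; the
    screen itself thresholds the unadjusted p),
    the assigned category, and the final ``candidate`` flag.  A gene is a
    candidate iff all four criteria hold *and* it belongs to one of the
    screened categories.
    """
    cfg = cfg or DEConfig()
    labels = np.array([fpkm.sample_groups[s] for s in fpkm.sample_ids])
    present = set(labels)
    # only organs the panel actually profiles are evaluated; heart and brain
    # (or the configured equivalent) must be present
    required = cfg.vital_organs & {"heart", "brain"} or cfg.vital_organs
    truly_missing = [v for v in required if v not in present]
    if truly_missing:
        raise ValueError(f"vital organ(s) missing from the normal panel: {truly_missing}")
    vital_present = sorted(cfg.vital_organs & present)

    fdf = pd.DataFrame(fpkm.fpkm, index=fpkm.gene_ids, columns=fpkm.sample_ids)
    tumor_median = fdf.loc[:, labels == tumor_type].median(axis=1)
    vital_max = pd.concat(
        [fdf.loc[:, labels == v].median(axis=1) for v in vital_present], axis=1
    ).max(axis=1)

    out = de.set_index("gene_id").copy()
    out["bh_q"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["tumor_median_fpkm"] = tumor_median.reindex(out.index)
    out["vital_max_median_fpkm"] = vital_max.reindex(out.index)
    out["pass_p"] = out["p_value"] <= cfg.p_threshold
    out["pass_logfc"] = out["log2_fc"] >= cfg.logfc_threshold
    out["pass_vital"] = out["vital_max_median_fpkm"] < cfg.vital_fpkm_max
    out["pass_tumor"] = out["tumor_median_fpkm"] >= cfg.tumor_fpkm_min

    category = pd.Series("", index=out.index, dtype=object)
    for name, genes in category_lists:
        hits = category.index.intersection(genes)
        category.loc[hits] = np.where(
            category.loc[hits] == "", name, category.loc[hits] + "+" + name
        )
    out["category"] = category
    out["cancer_type"] = tumor_type
    out["candidate"] = (
        out["pass_p"]
        & out["pass_logfc"]
        & out["pass_vital"]
        & out["pass_tumor"]
        & (out["category"] != "")
    )
    return out.reset_index()


def run_antigen_screen(
    counts: CountMatrix,
    fpkm: NormalizedMatrix,
    tumor_types,
    normal_labels,
    category_lists: GeneSetCollection,
    cfg: DEConfig | None = None,
    tmm_factors=None,
) -> pd.DataFrame:
    """Full screen over several cancer types; concatenated evidence tables."""
    cfg = cfg or DEConfig()
    tables = []
    for tumor_type in tumor_types:
        de = differential_expression(
            counts, tumor_type, normal_labels, cfg, tmm_factors=tmm_factors
        )
        tables.append(screen_candidates(de, fpkm, tumor_type, category_lists, cfg))
    return pd.concat(tables, ignore_index=True)
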