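"""Optimized Kaplan-Meier stratification of a continuous score.

Given a per-sample continuous score (e.g. an immune-signature enrichment
score) and right-censored survival, the optimizer scans every admissible
cutoff, splits the cohort into low/high groups at each, and keeps the
cutoff maximizing the two-group log-rank statistic.  Because the cutoff
is chosen to maximize separation, the nominal log-rank p at the optimum
is anti-conservative; significance is therefore assessed by a permutation
test: scores are shuffled against the fixed (time, event) pairs, the
full cutoff scan is repeated in each permutation, and the permutation p
is the add-one-corrected fraction of permutations whose best (smallest)
nominal p beats the observed one.

The log-rank machinery is vectorized over cutoffs and permutations so a
full permutation scan costs a handful of array operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .io import SurvivalTable


@dataclass
class KmcutConfig:
    """Cutoff-scan admissibility bounds and permutation-test settings."""

    min_group_fraction: float = 0.10
    min_group_size: int = 5
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.min_group_fraction < 0.5:
            raise ValueError("min_group_fraction must be in (0, 0.5)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class KmcutResult:
    cutoff: float
    chi_square: float
    nominal_p: float
    permutation_p: float
    group_labels: dict  # sample_id -> "low" | "high"
    n_cutoffs_scanned: int


@dataclass
class KmEstimate:
    """Product-limit survival curve; right-continuous with S(0) = 1."""

    event_times: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return s if s.ndim else float(s)


def km_estimator(times, events) -> KmEstimate:
    """Kaplan-Meier product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one observation")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, starts)
    n_at_risk = t.size - starts
    has_event = d > 0
    ev_times = t[starts][has_event]
    surv = np.cumprod(1.0 - d[has_event] / n_at_risk[has_event])
    return KmEstimate(event_times=ev_times, survival=surv)


# ---------------------------------------------------------------------------
# Vectorized log-rank over a grid of group assignments
# ---------------------------------------------------------------------------

def _risk_sets(times, events):
    """Sort by time and precompute risk-set blocks shared by all groupings."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, starts)
    n_at_risk = (t.size - starts).astype(float)
    keep = d > 0
    return order, e, starts, d[keep].astype(float), n_at_risk[keep], keep


def _logrank_grid(e_sorted, starts, d, n_at_risk, keep, G_sorted):
    """Chi-square per column of the membership matrix ``G_sorted``.

    ``G_sorted`` is (n_samples x K) boolean, rows in time-sorted order;
    column k marks membership of group 1 under grouping k.  Returns the
    (K,) array of log-rank chi-square statistics.
    """
    Gf = G_sorted.astype(float)
    rev = np.cumsum(Gf[::-1], axis=0)[::-1]
    n1 = rev[starts][keep]  # at risk in group 1, per event-time block
    d1 = np.add.reduceat(Gf * e_sorted[:, None], starts, axis=0)[keep]
    frac = n1 / n_at_risk[:, None]
    U = (d1 - d[:, None] * frac).sum(axis=0)
    # hypergeometric variance term; blocks with a single subject at risk drop
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = (
            d[:, None]
            * frac
            * (1.0 - frac)
            * ((n_at_risk[:, None] - d[:, None]) / (n_at_risk[:, None] - 1.0))
        )
    v_terms[n_at_risk == 1] = 0.0
    V = v_terms.sum(axis=0)
    chi2 = np.zeros_like(U)
    ok = V > 0
    chi2[ok] = U[ok] ** 2 / V[ok]
    return chi2


def logrank_test(times, events, groups):
    """Two-group log-rank test.

    Parameters
    ----------
    times, events : array-like
        Right-censored survival data; ``events`` is 1 for death/event.
    groups : array-like of {0, 1} or booleans
        Group membership per sample.

    Returns
    -------
    (chi_square, nominal_p)
        The statistic U^2/V and its upper-tail chi-square(1 df) p-value.
        A degenerate comparison (V = 0) returns (0, 1).
    """
    g = np.asarray(groups).astype(bool)
    e = np.asarray(events, dtype=int)
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValueError("need at least one event")
    order, e_sorted, starts, d, n_at_risk, keep = _risk_sets(times, events)
    chi2 = _logrank_grid(e_sorted, starts, d, n_at_risk, keep, g[order][:, None])
    stat = float(chi2[0])
    p = float(chi2_dist.sf(stat, 1)) if stat > 0 else 1.0
    return stat, p


def _align_score(score, surv: SurvivalTable) -> np.ndarray:
    if isinstance(score, pd.Series):
        missing = [s for s in surv.sample_ids if s not in score.index]
        if missing:
            raise ValueError(f"samples without a score: {missing}")
        return score.loc[surv.sample_ids].to_numpy(dtype=float)
    if isinstance(score, dict):
        return _align_score(pd.Series(score), surv)
    arr = np.asarray(score, dtype=float)
    if arr.shape != (len(surv.sample_ids),):
        raise ValueError("score length does not match the survival table")
    return arr


def kmopt(score, surv: SurvivalTable, cfg: KmcutConfig | None = None) -> KmcutResult:
    """Optimal-cutoff Kaplan-Meier stratification with a permutation test.

    Candidate cutoffs are midpoints between consecutive distinct score
    values for which both resulting groups satisfy the admissibility
    bounds.  The returned cutoff maximizes the log-rank chi-square (ties
    broken toward the smallest cutoff).  ``permutation_p`` is
    (1 + #{permutations whose best nominal p <= observed best p}) / (B+1).
    """
    cfg = cfg or KmcutConfig()
    x = _align_score(score, surv)
    n = x.size
    min_size = max(cfg.min_group_size, math.ceil(cfg.min_group_fraction * n))
    if n < 2 * min_size:
        raise ValueError(f"need at least {2 * min_size} samples")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError("score is constant; no cutoff exists")
    if surv.event.sum() == 0:
        raise ValueError("need at least one event")

    # admissible midpoints: low group = score <= midpoint
    counts_le = np.searchsorted(np.sort(x), distinct, side="right")
    low_n = counts_le[:-1]
    admissible = (low_n >= min_size) & (n - low_n >= min_size)
    if not np.any(admissible):
        raise ValueError("no admissible cutoff under the group-size bounds")
    cutoffs = ((distinct[:-1] + distinct[1:]) / 2.0)[admissible]
    C = cutoffs.size

    order, e_sorted, starts, d, n_at_risk, keep = _risk_sets(surv.time, surv.event)
    G = x[order][:, None] > cutoffs[None, :]  # time-sorted rows

    chi2_obs = _logrank_grid(e_sorted, starts, d, n_at_risk, keep, G)
    best = int(np.argmax(chi2_obs))  # ties -> first = smallest cutoff
    best_chi2 = float(chi2_obs[best])
    nominal_p = float(chi2_dist.sf(best_chi2, 1)) if best_chi2 > 0 else 1.0

    rng = np.random.default_rng(cfg.seed)
    B = cfg.n_permutations
    # permuting scores against fixed (time, event) = permuting G's rows
    n_exceed = 0
    max_cols = max(C, 4_000_000 // max(n, 1))
    chunk = max(1, max_cols // C)
    b = 0
    while b < B:
        nb = min(chunk, B - b)
        perms = np.stack([rng.permutation(n) for _ in range(nb)])
        big = np.concatenate([G[perm] for perm in perms], axis=1)
        chi2_perm = _logrank_grid(e_sorted, starts, d, n_at_risk, keep, big)
        maxima = chi2_perm.reshape(nb, C).max(axis=1)
        n_exceed += int(np.sum(maxima >= best_chi2))
        b += nb
    permutation_p = (1.0 + n_exceed) / (B + 1.0)

    cutoff = float(cutoffs[best])
    labels = {
        s: ("high" if xi > cutoff else "low") for s, xi in zip(surv.sample_ids, x)
    }
    return KmcutResult(
        cutoff=cutoff,
        chi_square=best_chi2,
        nominal_p=nominal_p,
        permutation_p=permutation_p,
        group_labels=labels,
        n_cutoffs_scanned=C,
    )


def kmopt_table(scores, surv: SurvivalTable, cfg: KmcutConfig | None = None):
    """Run :func:`kmopt` per signature and BH-adjust permutation p across
    signatures.

    ``scores`` is a :class:`~pedimmune.enrichment.SignatureScores` or a
    DataFrame (samples x signatures).  Returns a DataFrame with one row
    per signature plus a ``bh_q`` column, and a dict of per-signature
    group labels.
    """
    from statsmodels.stats.multitest import multipletests

    df = scores if isinstance(scores, pd.DataFrame) else scores.to_frame()
    rows, labels = [], {}
    for name in df.columns:
        res = kmopt(df[name], surv, cfg)
        rows.append(
            {
                "signature": name,
                "cutoff": res.cutoff,
                "chi_square": res.chi_square,
                "nominal_p": res.nominal_p,
                "permutation_p": res.permutation_p,
                "n_cutoffs_scanned": res.n_cutoffs_scanned,
            }
        )
        labels[name] = res.group_labels
    out = pd.DataFrame(rows).set_index("signature")
    out["bh_q"] = multipletests(out["permutation_p"], method="fdr_bh")[1]
    return out, labels
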