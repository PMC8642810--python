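"""Synthetic cohort generator with exported ground truth.

Emulates the statistical structure every pipeline stage assumes, so the
whole analysis is verifiable without restricted patient data:

* negative-binomial gene counts with a latent per-sample immune
  infiltration factor scaling an immune gene set in tumors;
* planted tumor-type-specific antigen genes, silent across the normal
  panel (a tumor-germline subset is co-expressed in testis, exercising
  the testis/ovary exclusion of the antigen screen);
* a normal-tissue panel including heart, brain, testis and ovary;
* exponential survival whose hazard decreases with the immune factor
  (high immune score protective), with censoring calibrated to a target
  rate;
* Zipf rank-size TCR repertoires with planted expanded clones (forced to
  satisfy the joint cpm/fraction expansion rule) and public clones
  shared across patients but absent from the healthy-donor database.

Baseline expression is parameterized on the FPKM scale and internally
rescaled so that realized FPKM after TMM normalization tracks the
configured values; this makes the antigen-screen thresholds (FPKM < 1 in
vital organs, >= 5 in tumor) directly plantable.

Everything is driven by one integer seed through a single PCG64
generator per operation, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CloneTable, CountMatrix, GeneSetCollection, ReferenceCdr3Set, SurvivalTable

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Cohort structure and effect sizes.

    Defaults model a scaled-down pediatric solid-tumor cohort: three
    cancer types of 20 tumors each, an 8-tissue normal panel with three
    samples per tissue, 32-fold planted antigens, a protective immune
    hazard ratio, and 50-clone Zipf repertoires.
    """

    n_genes: int = 2000
    tumor_types: dict = field(default_factory=lambda: {"OS": 20, "EWS": 20, "NBL": 20})
    normal_panel: dict = field(
        default_factory=lambda: {
            "heart": 3,
            "brain": 3,
            "testis": 3,
            "ovary": 3,
            "lung": 3,
            "liver": 3,
            "kidney": 3,
            "muscle": 3,
        }
    )
    immune_factor_sd: float = 1.0
    immune_geneset_size: int = 100
    n_antigens_per_type: int = 5
    n_tumor_germline_per_type: int = 2  # subset of the antigens, testis-co-expressed
    antigen_fold_change: float = 32.0
    antigen_baseline_fpkm: float = 0.4
    antigen_gene_length_bp: int = 10_000  # long transcripts: keeps the planted
    # per-million abundance well clear of the fold-change prior at < 1 FPKM
    baseline_log_fpkm_mean: float = 3.0  # natural-log scale of the log-normal
    baseline_log_fpkm_sd: float = 1.2
    mean_depth: float = 3e6
    depth_spread_fold: float = 3.0  # max/min ratio of per-sample depths
    nb_dispersion: float = 0.2
    # survival
    baseline_hazard: float = 0.05
    survival_beta: float = 1.0
    censoring_rate: float = 0.2
    # TCR
    clones_per_sample: int = 50
    zipf_exponent: float = 1.0
    zipf_top_count: int = 200
    n_expanded_clones: int = 5
    expanded_fraction: float = 0.05
    n_public_clones: int = 10
    public_clone_count: int = 5
    healthy_db_size: int = 2000
    healthy_overlap_fraction: float = 0.1
    total_sample_reads: int = 30_000_000
    seed: int = 0

    def __post_init__(self):
        required = {"heart", "brain", "testis", "ovary"}
        missing = required - set(self.normal_panel)
        if missing:
            raise ValueError(f"normal panel must include {sorted(missing)}")
        if len(self.tumor_types) < 2:
            raise ValueError("need at least two tumor types")
        if self.antigen_fold_change <= 1:
            raise ValueError("antigen fold change must exceed 1")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must be in [0, 1)")
        if self.n_tumor_germline_per_type > self.n_antigens_per_type:
            raise ValueError("tumor-germline subset larger than antigen count")
        if not 0 < self.expanded_fraction < 1:
            raise ValueError("expanded fraction must be in (0, 1)")


@dataclass
class CohortTruth:
    """Planted ground truth exported with each simulated cohort."""

    immune_factors: dict = field(default_factory=dict)  # sample -> latent factor
    immune_genes: list = field(default_factory=list)
    antigen_genes: dict = field(default_factory=dict)  # type -> [gene ids]
    tumor_germline_genes: dict = field(default_factory=dict)  # type -> [gene ids]
    expanded_clones: list = field(default_factory=list)  # (sample, cdr3)
    public_clones: list = field(default_factory=list)
    survival_beta: float = 0.0


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2) counts; Poisson when phi = 0."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    r = 1.0 / phi
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_expression(cfg: SimulationConfig, seed: int | None = None):
    """Generate counts for tumors plus the normal panel.

    Returns (CountMatrix, CohortTruth).  Mean counts are
    mu_gj = baseline_fpkm_g * (L_g/1e3) * (depth_j/1e6) * lift_gj with
    lift = exp(immune_factor_j) for immune genes in tumors, the antigen
    fold change for planted genes in their type (and testis for the
    tumor-germline subset), 1 otherwise; baselines are rescaled so
    realized FPKM approximates the configured baseline scale.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    G = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(G)]
    lengths = rng.integers(500, 5001, size=G)

    truth = CohortTruth(survival_beta=cfg.survival_beta)
    pool = rng.permutation(G)
    k = cfg.immune_geneset_size
    truth.immune_genes = [gene_ids[i] for i in pool[:k]]
    cursor = k
    for t in cfg.tumor_types:
        idx = pool[cursor : cursor + cfg.n_antigens_per_type]
        cursor += cfg.n_antigens_per_type
        truth.antigen_genes[t] = [gene_ids[i] for i in idx]
        truth.tumor_germline_genes[t] = [
            gene_ids[i] for i in idx[: cfg.n_tumor_germline_per_type]
        ]
        lengths[idx] = cfg.antigen_gene_length_bp

    baseline = rng.lognormal(cfg.baseline_log_fpkm_mean, cfg.baseline_log_fpkm_sd, size=G)
    # rescale so sum(b * L/1e3) = 1e6: realized FPKM ~ configured baseline
    baseline *= 1e6 / np.sum(baseline * lengths / 1e3)
    for t in cfg.tumor_types:
        baseline[[gene_ids.index(g) for g in truth.antigen_genes[t]]] = (
            cfg.antigen_baseline_fpkm
        )

    sample_ids, groups = [], {}
    for t, n in cfg.tumor_types.items():
        for i in range(n):
            s = f"{t}_{i:03d}"
            sample_ids.append(s)
            groups[s] = t
    for tissue, n in cfg.normal_panel.items():
        for i in range(n):
            s = f"N_{tissue}_{i:02d}"
            sample_ids.append(s)
            groups[s] = tissue

    immune_idx = pool[:k]
    antigen_idx = {t: None for t in cfg.tumor_types}
    gcursor = k
    for t in cfg.tumor_types:
        antigen_idx[t] = pool[gcursor : gcursor + cfg.n_antigens_per_type]
        gcursor += cfg.n_antigens_per_type

    half = np.log(cfg.depth_spread_fold) / 2
    depths = cfg.mean_depth * np.exp(
        rng.uniform(-half, half, size=len(sample_ids))
    )
    counts = np.zeros((G, len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        lift = np.ones(G)
        group = groups[s]
        if group in cfg.tumor_types:
            factor = rng.normal(0.0, cfg.immune_factor_sd)
            truth.immune_factors[s] = float(factor)
            lift[immune_idx] = np.exp(factor)
            lift[antigen_idx[group]] = cfg.antigen_fold_change
        elif group == "testis":
            for t in cfg.tumor_types:
                tg = antigen_idx[t][: cfg.n_tumor_germline_per_type]
                lift[tg] = cfg.antigen_fold_change
        mu = baseline * (lengths / 1e3) * (depths[j] / 1e6) * lift
        counts[:, j] = _nb_draw(rng, mu, cfg.nb_dispersion)

    cm = CountMatrix(
        gene_ids=gene_ids,
        gene_lengths_bp=lengths,
        sample_ids=sample_ids,
        counts=counts,
        sample_groups=groups,
    )
    return cm, truth


def simulate_survival(
    immune_factors: dict, cfg: SimulationConfig, seed: int | None = None
) -> SurvivalTable:
    """Exponential survival with hazard h0 * exp(-beta * immune factor).

    Positive beta makes a high immune factor protective.  Censoring is
    independent exponential with its rate chosen (by bisection on the
    per-sample censoring probability lambda_c / (lambda_c + lambda_e))
    to hit the configured expected censoring fraction.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    samples = list(immune_factors)
    factors = np.array([immune_factors[s] for s in samples], dtype=float)
    rate = cfg.baseline_hazard * np.exp(-cfg.survival_beta * factors)
    times_event = rng.exponential(1.0 / rate)
    if cfg.censoring_rate == 0:
        return SurvivalTable(
            sample_ids=samples, time=times_event, event=np.ones(len(samples), dtype=int)
        )

    def mean_censor_prob(lam_c):
        return float(np.mean(lam_c / (lam_c + rate)))

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if mean_censor_prob(mid) < cfg.censoring_rate:
            lo = mid
        else:
            hi = mid
    lam_c = np.sqrt(lo * hi)
    times_censor = rng.exponential(1.0 / lam_c, size=len(samples))
    time = np.minimum(times_event, times_censor)
    event = (times_event <= times_censor).astype(int)
    return SurvivalTable(sample_ids=samples, time=time, event=event)


def _random_cdr3(rng: np.random.Generator, taken: set) -> str:
    """A fresh CDR3: length clipped-normal around 14 within [6, 25]."""
    while True:
        length = int(np.clip(np.rint(rng.normal(14.0, 2.2)), 6, 25))
        seq = "".join(rng.choice(_AA, size=length))
        if seq not in taken:
            taken.add(seq)
            return seq


def simulate_repertoires(cfg: SimulationConfig, seed: int | None = None):
    """Zipf repertoires with planted expanded and public clones.

    Background clone counts follow the rank-size law
    count(rank) = max(1, round(top_count * rank^-exponent)), identical
    across samples, with a fixed per-sample sequencing depth; the pooled
    cpm distribution therefore has its top 1/clones_per_sample mass tied
    at the maximum, so no background clone strictly exceeds the pooled
    99th percentile.  Planted expanded clones get counts forced above
    both expansion criteria; public clones are injected into two
    patients each at low abundance and withheld from the healthy
    database; a configurable fraction of background clones is mirrored
    into the healthy database.

    Returns (clone tables, healthy ReferenceCdr3Set, CohortTruth,
    patient_of map).
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    if 1.0 / cfg.clones_per_sample <= 0.01:
        raise ValueError(
            "clones_per_sample too large: the top Zipf rank must hold > 1% of "
            "pooled clones for exact planted recovery"
        )
    n_samples = sum(cfg.tumor_types.values())
    sample_ids = [
        f"{t}_{i:03d}" for t, n in cfg.tumor_types.items() for i in range(n)
    ]
    patient_of = {s: f"P_{s}" for s in sample_ids}

    ranks = np.arange(1, cfg.clones_per_sample + 1)
    zipf_counts = np.maximum(
        1, np.rint(cfg.zipf_top_count * ranks ** (-cfg.zipf_exponent))
    ).astype(int)
    background_total = int(zipf_counts.sum())

    taken: set = set()
    tables = {}
    for s in sample_ids:
        clones = {}
        for c in zipf_counts:
            clones[_random_cdr3(rng, taken)] = int(c)
        tables[s] = clones

    truth = CohortTruth(survival_beta=cfg.survival_beta)

    # public clones: same sequence in two distinct patients, low count
    for _ in range(cfg.n_public_clones):
        seq = _random_cdr3(rng, taken)
        pair = rng.choice(n_samples, size=2, replace=False)
        for j in pair:
            tables[sample_ids[j]][seq] = cfg.public_clone_count
        truth.public_clones.append(seq)

    # expanded clones: force both criteria with margin
    max_bg_cpm = 1e6 * zipf_counts.max() / cfg.total_sample_reads
    host_samples = rng.choice(n_samples, size=cfg.n_expanded_clones, replace=False)
    f = cfg.expanded_fraction
    for j in host_samples:
        s = sample_ids[j]
        rest = sum(tables[s].values())
        count = max(
            int(np.ceil(2.0 * zipf_counts.max())),
            int(np.ceil(f * rest / (1.0 - f))) + 1,
        )
        seq = _random_cdr3(rng, taken)
        tables[s][seq] = count
        truth.expanded_clones.append((s, seq))

    # feasibility: planted cpm above the pooled percentile and fraction rule
    for s, seq in truth.expanded_clones:
        total = sum(tables[s].values())
        if tables[s][seq] / total <= f or (
            1e6 * tables[s][seq] / cfg.total_sample_reads <= max_bg_cpm
        ):
            raise ValueError("infeasible expansion planting under this config")

    # healthy database: fresh sequences plus a slice of the background
    db = {_random_cdr3(rng, taken) for _ in range(cfg.healthy_db_size)}
    background_seqs = [
        c
        for s in sample_ids
        for c in tables[s]
        if c not in set(truth.public_clones)
        and (s, c) not in set(truth.expanded_clones)
    ]
    n_overlap = int(round(cfg.healthy_overlap_fraction * len(background_seqs)))
    if n_overlap:
        db.update(rng.choice(background_seqs, size=n_overlap, replace=False))

    clone_tables = [
        CloneTable(
            sample_id=s, clones=tables[s], total_sample_reads=cfg.total_sample_reads
        )
        for s in sample_ids
    ]
    healthy = ReferenceCdr3Set(name="healthy_db", sequences=db)
    return clone_tables, healthy, truth, patient_of


def immune_signature_collection(truth: CohortTruth, n_sets: int = 4, seed: int = 0):
    """Split the planted immune gene set into disjoint named signatures.

    Gives ssGSEA several signatures that all track the latent immune
    factor, mimicking a panel of immune cell-type signatures.
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.immune_genes)
    rng.shuffle(genes)
    chunks = np.array_split(np.array(genes), n_sets)
    return GeneSetCollection(
        sets={f"immune_sig_{i+1}": list(c) for i, c in enumerate(chunks) if len(c)}
    )


def antigen_category_collection(
    truth: CohortTruth, all_gene_ids, n_decoys: int = 30, seed: int = 0
) -> GeneSetCollection:
    """Category lists for the antigen screen: planted genes plus decoys.

    The tumor-germline subset goes to the ``tumor_germline`` category;
    remaining planted antigens alternate between ``surface`` and
    ``transcription_factor``; decoy genes (never planted) pad each list
    so the screen has negatives to reject.
    """
    rng = np.random.default_rng(seed)
    planted = {g for genes in truth.antigen_genes.values() for g in genes}
    germline = {g for genes in truth.tumor_germline_genes.values() for g in genes}
    surface, tf = [], []
    for t, genes in truth.antigen_genes.items():
        rest = [g for g in genes if g not in germline]
        surface.extend(rest[::2])
        tf.extend(rest[1::2])
    decoy_pool = [g for g in all_gene_ids if g not in planted]
    decoys = list(rng.choice(decoy_pool, size=min(n_decoys, len(decoy_pool)), replace=False))
    third = max(1, len(decoys) // 3)
    return GeneSetCollection(
        sets={
            "surface": surface + decoys[:third],
            "transcription_factor": tf + decoys[third : 2 * third],
            "tumor_germline": sorted(germline) + decoys[2 * third :],
        }
    )
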