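import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedimmune import GeneSetCollection
from pedimmune.antigen import (
    DEConfig,
    _exact_p,
    estimate_dispersion,
    nb_exact_test,
    screen_candidates,
)
from pedimmune.normalize import NormalizedMatrix


def exact_p_oracle(total, n_a, n_b, s_a, phi):
    """Direct transcription of the conditional two-sided definition.

    Uses scipy's pmf (not log-pmf) and a per-split comparison loop, so it
    shares no code path with the implementation.
    """
    a = np.arange(total + 1)
    if phi <= 0:
        masses = stats.binom.pmf(a, total, n_a / (n_a + n_b))
    else:
        mu = total / (n_a + n_b)
        r_a, r_b = n_a / phi, n_b / phi
        q = 1.0 / (1.0 + phi * mu)
        masses = stats.nbinom.pmf(a, r_a, q) * stats.nbinom.pmf(total - a, r_b, q)
    masses = masses / masses.sum()
    obs = masses[s_a]
    total_p = 0.0
    for m in masses:
        if m <= obs * (1.0 + 1e-10):
            total_p += m
    return min(total_p, 1.0)


class TestExactTest:
    def test_binomial_enumeration_case(self):
        # phi=0, 1 vs 1 libraries, split (5,1): the four outcomes with
        # mass <= C(6,5)/64 are {0,1,5,6} -> p = 14/64
        assert _exact_p(6, 1, 1, 5, 0.0) == pytest.approx(14 / 64, abs=1e-12)

    def test_modal_symmetric_split_p_one(self):
        # equal groups, observed split at the mode -> every mass <= modal
        # mass is summed, which is all of them
        assert _exact_p(10, 3, 3, 5, 0.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.2, 1.0])
    def test_small_total_oracle_agreement(self, phi, rng):
        for _ in range(40):
            total = int(rng.integers(1, 60))
            n_a, n_b = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            s_a = int(rng.integers(0, total + 1))
            want = exact_p_oracle(total, n_a, n_b, s_a, phi)
            got = _exact_p(total, n_a, n_b, s_a, phi)
            assert abs(got - want) < 1e-12

    def test_matches_scipy_binomtest_at_phi_zero(self, rng):
        for _ in range(20):
            total = int(rng.integers(1, 200))
            n_a, n_b = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            s_a = int(rng.integers(0, total + 1))
            want = stats.binomtest(s_a, total, n_a / (n_a + n_b)).pvalue
            got = _exact_p(total, n_a, n_b, s_a, 0.0)
            assert abs(got - want) < 1e-9

    def test_zero_total_p_one_fc_zero(self):
        de = nb_exact_test(
            np.zeros((1, 3)), np.zeros((1, 4)), 0.3,
            lib_sizes_a=np.full(3, 1e6), lib_sizes_b=np.full(4, 1e6),
        )
        assert de["p_value"].iloc[0] == 1.0
        assert de["log2_fc"].iloc[0] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(np.array([[-1.0]]), np.array([[2.0]]), 0.0)

    def test_planted_difference_is_significant(self, rng):
        xa = rng.poisson(200, (1, 6))
        xb = rng.poisson(10, (1, 6))
        de = nb_exact_test(xa, xb, 0.0, lib_sizes_a=np.full(6, 1e4), lib_sizes_b=np.full(6, 1e4))
        assert de["p_value"].iloc[0] < 1e-10
        assert de["log2_fc"].iloc[0] > 3


class TestDispersion:
    def test_constant_gene_zero(self):
        x = np.tile([[5.0], [7.0]], (1, 6))
        phi = estimate_dispersion(x, mode="per_gene", lib_sizes=np.ones(6))
        assert np.all(phi == 0.0)

    def test_poisson_common_small(self, rng):
        mu = rng.lognormal(3, 1, 200)
        x = rng.poisson(np.broadcast_to(mu[:, None], (200, 10)))
        assert estimate_dispersion(x, lib_sizes=np.ones(10)) <= 0.05

    def test_nb_recovery(self, rng):
        phi, r = 0.4, 2.5
        mu = rng.lognormal(3, 1, 500)
        x = rng.negative_binomial(r, r / (r + mu[:, None] * np.ones(20)), (500, 20))
        assert 0.2 < estimate_dispersion(x, lib_sizes=np.ones(20)) < 0.6

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            estimate_dispersion(np.ones((5, 3)), groups=["a", "a", "b"])


def _fpkm_matrix(gene_ids, data, groups):
    """NormalizedMatrix straight from an FPKM table (factors = 1)."""
    sample_ids = list(groups)
    arr = np.asarray(data, dtype=float)
    return NormalizedMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        tmm_factors=np.ones(len(sample_ids)),
        fpkm=arr,
        log2_fpkm=np.log2(arr + 1.0),
        sample_groups=dict(groups),
    )


class TestScreen:
    def _setup(self):
        gene_ids = ["passes", "weak_fc", "germline", "housekeeping"]
        groups = {
            "t1": "EWS", "t2": "EWS", "t3": "EWS",
            "h1": "heart", "h2": "heart",
            "b1": "brain", "b2": "brain",
            "x1": "testis", "x2": "testis",
        }
        fpkm = [
            # tumor high, vital silent
            [8, 9, 8, 0.3, 0.3, 0.4, 0.4, 0.1, 0.1],
            [8, 9, 8, 0.3, 0.3, 0.4, 0.4, 0.1, 0.1],
            # testis-restricted among normals, tumor high
            [20, 22, 19, 0.0, 0.0, 0.0, 0.0, 30, 28],
            # everywhere
            [50, 52, 49, 48, 50, 51, 47, 50, 52],
        ]
        de = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2_fc": [4.2, 3.9, 6.0, 0.1],
                "p_value": [1e-6, 1e-6, 1e-8, 0.8],
            }
        )
        cats = GeneSetCollection(
            sets={
                "surface": ["passes", "weak_fc", "housekeeping"],
                "tumor_germline": ["germline"],
            }
        )
        return de, _fpkm_matrix(gene_ids, fpkm, groups), cats

    def test_four_criterion_calls(self):
        de, fp, cats = self._setup()
        out = screen_candidates(de, fp, "EWS", cats).set_index("gene_id")
        assert out.loc["passes", "candidate"]
        # FC 3.9 < 4 (16-fold) rejected despite everything else passing
        assert not out.loc["weak_fc", "candidate"]
        # testis expression does not disqualify: testis excluded upstream
        assert out.loc["germline", "candidate"]
        assert not out.loc["housekeeping", "candidate"]

    def test_category_required(self):
        de, fp, _ = self._setup()
        cats = GeneSetCollection(sets={"surface": ["weak_fc"]})
        out = screen_candidates(de, fp, "EWS", cats).set_index("gene_id")
        assert not out["candidate"].any()  # "passes" has no category now

    def test_missing_vital_organ_named(self):
        de, fp, cats = self._setup()
        fp.sample_groups = {
            s: ("lung" if g == "brain" else g) for s, g in fp.sample_groups.items()
        }
        with pytest.raises(ValueError, match="brain"):
            screen_candidates(de, fp, "EWS", cats)

    @pytest.mark.parametrize(
        "field,delta",
        [("p_threshold", 0.1), ("logfc_threshold", 2.0), ("tumor_fpkm_min", 2.0)],
    )
    def test_raising_thresholds_never_adds_candidates(self, field, delta):
        de, fp, cats = self._setup()
        base = screen_candidates(de, fp, "EWS", cats, DEConfig())["candidate"]
        kwargs = {field: getattr(DEConfig(), field) * (0.1 if field == "p_threshold" else 1) }
        stricter_value = {
            "p_threshold": DEConfig().p_threshold / 10,
            "logfc_threshold": DEConfig().logfc_threshold + delta,
            "tumor_fpkm_min": DEConfig().tumor_fpkm_min + delta,
        }[field]
        strict = screen_candidates(
            de, fp, "EWS", cats, DEConfig(**{field: stricter_value})
        )["candidate"]
        assert not (strict & ~base).any()
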