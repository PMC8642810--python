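import numpy as np
import pytest

from pedimmune.io import CloneTable, ReferenceCdr3Set
from pedimmune.repertoire import (
    ExpansionConfig,
    call_expansion,
    cdr3_stats,
    diversity_indices,
    normalize_clones,
    partition_overlap,
)


def _table(sample_id, clones, total=None):
    return CloneTable(sample_id=sample_id, clones=clones, total_sample_reads=total)


class TestNormalizeClones:
    def test_cpm_and_fraction(self):
        t = _table("s", {"CASSA": 8, "CASSW": 2}, total=1_000_000)
        df = normalize_clones(t)
        assert np.allclose(df["cpm"], [8.0, 2.0])
        assert np.allclose(df["fraction"], [0.8, 0.2])

    def test_single_clone_fraction_one(self):
        df = normalize_clones(_table("s", {"CASSA": 5}, total=100))
        assert df["fraction"].iloc[0] == 1.0

    def test_tcr_denominator(self):
        cfg = ExpansionConfig(cpm_denominator="total_tcr_reads")
        df = normalize_clones(_table("s", {"CASSA": 3, "CASSW": 1}), cfg)
        assert np.allclose(df["cpm"], [750_000.0, 250_000.0])

    def test_missing_denominator_instructs_fallback(self):
        with pytest.raises(ValueError, match="total_tcr_reads"):
            normalize_clones(_table("s", {"CASSA": 1}))

    def test_fractions_sum_to_one(self, rng):
        clones = {f"CASS{c}": int(k) for c, k in zip("ACDEFGH", rng.integers(1, 500, 7))}
        df = normalize_clones(_table("s", clones, total=10**6))
        assert abs(df["fraction"].sum() - 1.0) < 1e-9


class TestCallExpansion:
    def test_boundary_fraction_excluded(self):
        # one clone at exactly 1% of TCR reads: strict rule excludes it
        tables = [
            _table("a", {"CASSA": 1, "CASSW": 99}, total=1000),
            _table("b", {"CASSC": 100}, total=10**9),
        ]
        calls, _, _, _ = call_expansion(tables, ExpansionConfig())
        row = calls[(calls.sample_id == "a") & (calls.cdr3_aa == "CASSA")].iloc[0]
        assert row["fraction"] == 0.01
        assert not row["expanded"]

    def test_identical_cpm_nothing_exceeds(self):
        tables = [
            _table(s, {f"CAS{c}{s}": 10 for c in "ACDEF"}, total=1000)
            for s in ("RA", "RC", "RD")
        ]
        calls, per_sample, _, thr = call_expansion(tables)
        assert thr == 10_000.0
        assert not calls["expanded"].any()
        assert not per_sample["has_expanded"].any()

    def test_sample_order_invariance(self):
        tables = [
            _table("a", {"CASSA": 500, "CASSW": 5}, total=1000),
            _table("b", {"CASSC": 2, "CASSD": 3}, total=1000),
        ]
        c1, _, _, _ = call_expansion(tables)
        c2, _, _, _ = call_expansion(tables[::-1])
        m1 = c1.set_index(["sample_id", "cdr3_aa"])["expanded"].sort_index()
        m2 = c2.set_index(["sample_id", "cdr3_aa"])["expanded"].sort_index()
        assert m1.equals(m2)

    def test_common_count_scaling_invariance(self):
        base = [
            _table("a", {"CASSA": 400, "CASSW": 5}, total=1000),
            _table("b", {"CASSC": 2, "CASSD": 9}, total=1000),
        ]
        scaled = [
            _table(t.sample_id, {c: 7 * k for c, k in t.clones.items()},
                   total=7 * t.total_sample_reads)
            for t in base
        ]
        c1, _, _, _ = call_expansion(base)
        c2, _, _, _ = call_expansion(scaled)
        assert list(c1["expanded"]) == list(c2["expanded"])

    def test_per_group_patient_counted_once(self):
        tables = [
            _table("p1_t1", {"CASSA": 900, "CASSW": 1}, total=1000),
            _table("p1_t2", {"CASSC": 901, "CASSD": 1}, total=1000),
            _table("p2_t1", {"CASSE": 1, "CASSF": 2}, total=1000),
        ]
        _, _, per_group, _ = call_expansion(
            tables,
            patient_of={"p1_t1": "p1", "p1_t2": "p1", "p2_t1": "p2"},
            group_of={s: "OS" for s in ("p1_t1", "p1_t2", "p2_t1")},
        )
        assert per_group.loc["OS", "n_patients"] == 2
        assert per_group.loc["OS", "n_expanded"] == 1
        assert np.isclose(per_group.loc["OS", "pct_expanded"], 50.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            call_expansion([])


class TestPartitionOverlap:
    def test_three_patient_example(self):
        tables = [
            _table("s1", {"AAAA": 1, "YYYY": 1}),
            _table("s2", {"YYYY": 2}),
            _table("s3", {"CCCC": 1}),
        ]
        patient_of = {"s1": "p1", "s2": "p2", "s3": "p3"}
        refs = [ReferenceCdr3Set(name="db", sequences={"CCCC"})]
        per_cdr3, summary = partition_overlap(tables, patient_of, refs)
        cat = per_cdr3.set_index("cdr3_aa")["category"]
        assert cat["AAAA"] == "private"
        assert cat["YYYY"] == "multi_tumor_private"
        assert cat["CCCC"] == "reference_shared"
        assert np.allclose(summary["percentage"], [100 / 3] * 3)

    def test_empty_reference_all_shared_are_public(self):
        tables = [_table("s1", {"AAAA": 1}), _table("s2", {"AAAA": 1})]
        per_cdr3, _ = partition_overlap(tables, {"s1": "p1", "s2": "p2"}, [])
        assert per_cdr3["category"].tolist() == ["multi_tumor_private"]

    def test_same_patient_two_samples_stays_private(self):
        tables = [_table("s1", {"AAAA": 1}), _table("s2", {"AAAA": 1})]
        per_cdr3, _ = partition_overlap(tables, {"s1": "p1", "s2": "p1"}, [])
        assert per_cdr3["category"].tolist() == ["private"]

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        tables = []
        for i in range(6):
            clones = {
                "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 10)): 1
                for _ in range(20)
            }
            tables.append(_table(f"s{i}", clones))
        refs = [ReferenceCdr3Set(name="db", sequences=set(list(tables[0].clones)[:5]))]
        per_cdr3, summary = partition_overlap(
            tables, {f"s{i}": f"p{i}" for i in range(6)}, refs
        )
        distinct = set().union(*(t.clones for t in tables))
        assert summary["count"].sum() == len(distinct)
        assert len(per_cdr3) == len(distinct)

    def test_unmapped_sample_rejected(self):
        with pytest.raises(ValueError):
            partition_overlap([_table("s1", {"AAAA": 1})], {}, [])


class TestCdr3Stats:
    def test_median_length(self):
        tables = [
            _table("s", {"A" * 12: 1, "C" * 14: 1, "D" * 16: 1000})
        ]
        st = cdr3_stats(tables)
        assert st["median_length"] == 14.0
        # read count does not weight the distribution
        assert st["length_distribution"].loc[16] == 1

    def test_per_group_median_unique_counts(self):
        tables = [
            _table("s1", {f"AAA{c}": 1 for c in "CDE"}),
            _table("s2", {f"AAA{c}": 1 for c in "CDEFG"}),
        ]
        st = cdr3_stats(tables, group_of={"s1": "OS", "s2": "OS"})
        assert st["group_medians"].loc["OS"] == 4.0

    def test_diversity_monoclonal(self):
        d = diversity_indices(_table("s", {"AAAA": 100}))
        assert d["shannon"] == 0.0
        assert d["clonality"] == 1.0
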