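"""Filter-cascade correctness: MAF, call rates, exact HWE, BY-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from broodscan.datamodel import MISSING, GenotypeDataset
from broodscan.qc_filter import (
    QcConfig,
    QcError,
    by_fdr_filter,
    hwe_exact_test,
    minor_allele_frequency,
    run_qc,
)
from conftest import make_random_dataset
from oracles import by_stepup_oracle, hwe_exact_oracle


def dataset_from_counts(count_matrix, missing=None) -> GenotypeDataset:
    """Build a biallelic dataset from a tracked-allele count matrix (0/1/2)."""
    counts = np.asarray(count_matrix)
    n_s, n_l = counts.shape
    calls = np.empty((n_s, n_l, 2), dtype=np.int16)
    calls[:, :, 0] = np.where(counts >= 1, 0, 1)
    calls[:, :, 1] = np.where(counts == 2, 0, 1)
    if missing is not None:
        calls[np.asarray(missing, dtype=bool)] = MISSING
    ds = GenotypeDataset(
        [f"s{i}" for i in range(n_s)],
        [f"L{j}" for j in range(n_l)],
        calls,
        allele_names=[["A", "G"]] * n_l,
    )
    meta = pd.DataFrame(
        {"brood_year": 2000, "broodline": "A", "generation": 0},
        index=pd.Index(ds.sample_ids, name="sample_id"),
    )
    ds.attach_metadata(meta)
    return ds


class TestMaf:
    def test_one_het_in_ten(self):
        ds = dataset_from_counts(np.array([[2]] * 9 + [[1]]))
        assert minor_allele_frequency(ds, "L0") == pytest.approx(0.05)

    def test_monomorphic_is_zero(self):
        ds = dataset_from_counts(np.full((8, 1), 2))
        assert minor_allele_frequency(ds, "L0") == 0.0

    def test_matches_counting_oracle(self, rng):
        ds = make_random_dataset(100, 30, rng, missing_rate=0.2, with_meta=False)
        for j in range(30):
            calls = [tuple(c) for c, m in zip(ds.calls[:, j], ds.missing_mask()[:, j]) if not m]
            alleles = [a for c in calls for a in c]
            p = alleles.count(0) / len(alleles)
            assert minor_allele_frequency(ds, j) == pytest.approx(min(p, 1 - p), abs=1e-15)

    def test_all_missing_raises(self):
        ds = dataset_from_counts(np.array([[2, 2]]), missing=[[True, False]])
        with pytest.raises(QcError, match="missing"):
            minor_allele_frequency(ds, "L0")


class TestHweExact:
    def test_two_homozygotes(self):
        # full enumeration: configurations het in {0, 2} with probs 1/3, 2/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_all_heterozygotes_extreme(self):
        assert hwe_exact_test(0, 100, 0) < 1e-10

    def test_modal_configuration(self):
        assert hwe_exact_test(25, 50, 25) >= 0.5

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(40, 0, 0) == 1.0

    def test_exhaustive_enumeration_all_triples_to_n10(self):
        """Exact match with the rational-arithmetic enumeration oracle, n <= 10."""
        for n in range(1, 11):
            for n_hom1 in range(n + 1):
                for n_het in range(n - n_hom1 + 1):
                    n_hom2 = n - n_hom1 - n_het
                    got = hwe_exact_test(n_hom1, n_het, n_hom2)
                    want = float(hwe_exact_oracle(n_hom1, n_het, n_hom2))
                    assert got == pytest.approx(want, abs=1e-12), (n_hom1, n_het, n_hom2)


class TestByFdr:
    def test_single_test(self):
        keep, thr = by_fdr_filter([0.005], alpha=0.01)
        assert not keep[0] and thr == pytest.approx(0.005)

    def test_all_ones_none_rejected(self):
        keep, thr = by_fdr_filter(np.ones(50), alpha=0.01)
        assert keep.all() and np.isnan(thr)

    def test_empty(self):
        keep, thr = by_fdr_filter([], alpha=0.01)
        assert keep.size == 0

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_stepup_property_any_pvector(self, pvals):
        """For arbitrary p-vectors the rejection set equals the naive step-up
        and the reported threshold is the largest rejected raw p."""
        keep, thr = by_fdr_filter(pvals, alpha=0.05, method="BY")
        np.testing.assert_array_equal(~keep, by_stepup_oracle(pvals, 0.05, "BY"))
        if (~keep).any():
            assert thr == max(p for p, k in zip(pvals, keep) if not k)
        else:
            assert np.isnan(thr)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_hwe_property_valid_pvalue(self, a, h, b):
        """HWE exact p is a valid probability and symmetric in the homozygotes."""
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_exact_test(b, h, a), abs=1e-12)

    @pytest.mark.parametrize("method", ["BY", "BH"])
    def test_matches_naive_stepup_oracle(self, rng, method):
        for _ in range(50):
            m = int(rng.integers(1, 500))
            p = rng.random(m) ** rng.uniform(0.5, 4)
            keep, _ = by_fdr_filter(p, alpha=0.05, method=method)
            np.testing.assert_array_equal(~keep, by_stepup_oracle(p, 0.05, method))


class TestCascade:
    def build_crafted(self):
        """One violation per stage, plus clean loci that must survive.

        Layout (40 samples, 7 loci):
        - L0: MAF 1/80 -> removed at stage 1
        - L1, L3: exactly HWE-proportioned at p=0.5 (clean)
        - L2: missing only for sample 0 -> survives stage 3
        - L4: missing for samples 1-14 -> call rate 25/39 < 0.8 after s0
          removal -> stage 3
        - L5: all heterozygotes -> extreme HWE violation -> stage 4
        - L6: MAF exactly 0.05 with minor copies concentrated in sample 0
          (order-sensitivity witness; see test_stage_order_matters)
        - sample 0: called at 3 of 7 loci -> removed at stage 2
        """
        n_s = 40
        hw_perfect = np.array([0] * 10 + [1] * 20 + [2] * 10)  # exact HWE at p=0.5
        counts = np.tile(hw_perfect[:, None], (1, 7))
        counts[:, 0] = 2
        counts[0, 0] = 1            # MAF 1/80 < 0.05
        counts[:, 5] = 1            # all het
        counts[:, 6] = 2
        counts[0, 6] = 0            # 2 minor copies in s0 ...
        counts[1, 6] = 1            # ... plus one in s1
        counts[2, 6] = 1            # ... and s2: MAF = 4/80 = 0.05 exactly
        missing = np.zeros((n_s, 7), dtype=bool)
        missing[0, 1:5] = True      # sample 0 call rate 3/7 < 0.75
        missing[1:15, 4] = True     # L4: 25/39 < 0.8 once s0 is gone
        return dataset_from_counts(counts, missing)

    def test_intended_removals_and_telescoping(self):
        ds = self.build_crafted()
        filtered, report = run_qc(ds, QcConfig())
        removed = report.removed.set_index("id")
        assert removed.loc["L0", "stage"] == "maf"
        assert removed.loc["s0", "stage"] == "sample_call_rate"
        assert removed.loc["L4", "stage"] == "locus_call_rate"
        assert removed.loc["L5", "stage"] == "hwe"
        assert set(filtered.locus_ids) == {"L1", "L2", "L3", "L6"}
        assert "s0" not in filtered.sample_ids
        assert len(removed) == 4
        for st in report.stages:  # telescoping: input = removed + surviving
            assert st["n_in"] == st["n_removed"] + st["n_out"]
        # survivors chain across same-entity stages
        assert report.stages[0]["n_out"] == report.stages[2]["n_in"]
        assert report.stages[2]["n_out"] == report.stages[3]["n_in"]

    def test_stage_order_matters(self):
        """Permuting the cascade (sample call rate before MAF) changes survivors.

        L6 has pooled MAF exactly 0.05 (kept, boundary inclusive) but its
        minor copies sit mostly in the low-call-rate sample 0; removing
        samples first drops its MAF to 2/78 and the MAF stage then removes
        it. The enforced order therefore keeps L6, the permuted one does not.
        """
        ds = self.build_crafted()
        filtered, _ = run_qc(ds, QcConfig())
        assert "L6" in filtered.locus_ids
        # permuted cascade: sample call rate on the raw matrix first
        rate = ds.called_mask().mean(axis=1)
        ds2 = ds.subset(samples=rate >= 0.75)
        filtered2, _ = run_qc(ds2, QcConfig())
        assert "L6" not in filtered2.locus_ids
        assert set(filtered2.locus_ids) != set(filtered.locus_ids)

    def test_boundary_values_kept(self):
        """Exactly-at-threshold entities survive (removal is strict 'less than')."""
        # locus with MAF exactly 0.05: 1 minor allele in 10 diploids
        counts = np.full((10, 2), 2)
        counts[0, 0] = 1
        ds = dataset_from_counts(counts)
        filtered, _ = run_qc(ds, QcConfig(hwe_alpha=0.0001))
        assert "L0" in filtered.locus_ids

    def test_empty_survivors_raises_with_stage_name(self):
        counts = np.full((6, 3), 2)  # all monomorphic -> MAF 0 < 0.05
        ds = dataset_from_counts(counts)
        with pytest.raises(QcError, match="maf"):
            run_qc(ds, QcConfig())

    def test_hwe_conforming_data_low_removal(self, rng):
        """On HWE-conforming data stage 4 removes (almost) nothing: BY is conservative."""
        ds = make_random_dataset(300, 800, rng)
        _, report = run_qc(ds, QcConfig())
        hwe_stage = [s for s in report.stages if s["stage"] == "hwe"][0]
        assert hwe_stage["n_removed"] <= 0.005 * hwe_stage["n_in"]
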