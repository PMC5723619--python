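"""Allele frequencies, genotypic distances, principal coordinates."""

import numpy as np
import pandas as pd
import pytest

from broodscan.datamodel import MISSING, GenotypeDataset
from broodscan.popstruct import (
    PopStructError,
    genotypic_distance_matrix,
    group_allele_frequencies,
    principal_coordinates,
    run_pcoa,
)
from conftest import make_random_dataset
from oracles import genotypic_distance_oracle


def dataset_from_pairs(pairs_by_sample, n_alleles=4):
    """Dataset from explicit per-sample lists of allele pairs (None = missing)."""
    n_s = len(pairs_by_sample)
    n_l = len(pairs_by_sample[0])
    calls = np.full((n_s, n_l, 2), MISSING, dtype=np.int16)
    for i, row in enumerate(pairs_by_sample):
        for j, pair in enumerate(row):
            if pair is not None:
                calls[i, j] = pair
    names = [[chr(ord("A") + k) for k in range(n_alleles)]] * n_l
    return GenotypeDataset(
        [f"s{i}" for i in range(n_s)], [f"L{j}" for j in range(n_l)], calls,
        allele_names=names,
    )


class TestGroupFrequencies:
    def test_simple_count(self):
        ds = dataset_from_pairs([[(0, 0)], [(0, 1)]])
        meta = pd.DataFrame({"brood_year": [2000, 2000], "broodline": ["A", "A"],
                             "generation": [0, 0]},
                            index=pd.Index(["s0", "s1"], name="sample_id"))
        ds.attach_metadata(meta)
        ft = group_allele_frequencies(ds)
        assert ft.freq[0, 0] == pytest.approx(0.75)  # 3 of 4 allele copies
        assert ft.size[0, 0] == 2

    def test_all_missing_group_flagged(self):
        ds = dataset_from_pairs([[(0, 0), None], [(0, 1), None]])
        meta = pd.DataFrame({"brood_year": [2000, 2000], "broodline": ["A", "A"],
                             "generation": [0, 0]},
                            index=pd.Index(["s0", "s1"], name="sample_id"))
        ds.attach_metadata(meta)
        ft = group_allele_frequencies(ds)
        assert np.isnan(ft.freq[0, 1]) and ft.size[0, 1] == 0

    def test_matches_counting_oracle(self, rng):
        ds = make_random_dataset(50, 200, rng, missing_rate=0.1)
        ft = group_allele_frequencies(ds)
        meta = ds.sample_meta
        for g, key in enumerate(ft.group_keys):
            mask = [(b, gen) == key for b, gen in zip(meta["broodline"], meta["generation"])]
            for j in rng.choice(200, 20, replace=False):
                copies, n = 0, 0
                for i in np.flatnonzero(mask):
                    a, b = ds.calls[i, j]
                    if a != MISSING:
                        n += 1
                        copies += int(a == 0) + int(b == 0)
                if n:
                    assert ft.freq[g, j] == pytest.approx(copies / (2 * n), abs=1e-15)


class TestGenotypicDistance:
    @pytest.mark.parametrize("g1,g2,want", [
        ((0, 0), (1, 1), 4.0),   # AA vs BB
        ((0, 0), (0, 1), 1.0),   # AA vs AB
        ((0, 1), (2, 3), 2.0),   # AB vs CD
        ((0, 0), (1, 2), 3.0),   # AA vs BC
        ((0, 1), (0, 1), 0.0),   # AB vs AB
        ((0, 1), (0, 2), 1.0),   # AB vs AC
    ])
    def test_single_locus_table(self, g1, g2, want):
        ds = dataset_from_pairs([[g1], [g2]])
        d2 = genotypic_distance_matrix(ds)
        assert d2[0, 1] == pytest.approx(want)

    def test_identical_samples_zero(self):
        ds = dataset_from_pairs([[(0, 1), (1, 1)], [(0, 1), (1, 1)]])
        d2 = genotypic_distance_matrix(ds)
        assert d2[0, 1] == 0.0
        assert np.all(np.diag(d2) == 0.0)

    def test_symmetry_and_oracle(self, rng):
        ds = make_random_dataset(15, 40, rng, missing_rate=0.2, with_meta=False)
        d2 = genotypic_distance_matrix(ds)
        np.testing.assert_allclose(d2, d2.T, atol=1e-12)
        for _ in range(30):
            i, j = rng.choice(15, 2, replace=False)
            rows = []
            for k in (i, j):
                rows.append([None if ds.calls[k, l, 0] == MISSING else tuple(ds.calls[k, l])
                             for l in range(40)])
            want = genotypic_distance_oracle(rows[0], rows[1], 40)
            assert d2[i, j] == pytest.approx(want, rel=1e-12)

    def test_missingness_rescaling(self):
        """A pair sharing half the loci is scaled up to the full locus count."""
        ds = dataset_from_pairs([
            [(0, 0), (0, 0)],
            [(1, 1), None],
        ])
        d2 = genotypic_distance_matrix(ds)
        assert d2[0, 1] == pytest.approx(4.0 * 2 / 1)

    def test_disjoint_pair_raises(self):
        ds = dataset_from_pairs([
            [(0, 0), None],
            [None, (1, 1)],
        ])
        with pytest.raises(PopStructError, match="share no called locus"):
            genotypic_distance_matrix(ds)


class TestPrincipalCoordinates:
    def test_recovers_euclidean_configuration(self):
        """Unit-square corners: embedded distances reproduce the inputs."""
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        res = principal_coordinates(d2, n_axes=2)
        emb = res.coordinates
        d2_emb = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
        np.testing.assert_allclose(d2_emb, d2, atol=1e-9)

    def test_identical_samples_identical_coordinates(self):
        pts = np.array([[0.0, 0], [0, 0], [3, 4]])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        res = principal_coordinates(d2, n_axes=1)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_axis_order_and_explained(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(20, 3)) * np.array([5.0, 2.0, 0.5])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        res = principal_coordinates(d2, n_axes=3)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.explained.sum() <= 1.0 + 1e-12

    def test_permutation_invariance_up_to_sign(self, rng):
        ds = make_random_dataset(25, 60, rng, with_meta=False)
        d2 = genotypic_distance_matrix(ds)
        res = principal_coordinates(d2, n_axes=2)
        perm = rng.permutation(25)
        res_p = principal_coordinates(d2[np.ix_(perm, perm)], n_axes=2)
        for k in range(2):
            a, b = res.coordinates[perm, k], res_p.coordinates[:, k]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_excess_axes_truncated_with_warning(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        with pytest.warns(UserWarning, match="truncating"):
            res = principal_coordinates(d2, n_axes=3)
        assert res.coordinates.shape[1] == 1

    def test_cross_check_against_skbio(self, rng):
        """Independent route: scikit-bio's PCoA gives the same embedding geometry."""
        skbio = pytest.importorskip("skbio")
        ds = make_random_dataset(20, 80, rng, with_meta=False)
        d2 = genotypic_distance_matrix(ds)
        ours = principal_coordinates(d2, n_axes=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(np.sqrt(d2)), number_of_dimensions=3
        )
        for k in range(3):
            a = ours.coordinates[:, k]
            b = theirs.samples.values[:, k]
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)
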