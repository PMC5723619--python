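"""Group allele frequencies, individual genetic distances, and principal
coordinates.

The distance is the codominant-genotypic squared distance of Smouse &
Peakall: per locus, half the squared Euclidean distance between the two
individuals' allele-count vectors (AA-AA 0, AA-AB 1, AB-AB 0, AB-AC 1,
AB-CD 2, AA-BC 3, AA-BB 4). Missing data are handled by pairwise deletion
with rescaling to the full locus count, so sparsely genotyped pairs remain
comparable to complete ones. Principal coordinates are the classical
Gower-centred eigendecomposition of the squared-distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .datamodel import GenotypeDataset


class PopStructError(ValueError):
    pass


@dataclass
class FrequencyTable:
    """Tracked-allele frequency and diploid sample size per group per locus.

    ``freq`` is NaN where a group has no called diploids at a locus.
    """

    group_keys: list          # e.g. [(broodline, generation), ...] sorted
    locus_ids: list[str]
    freq: np.ndarray          # (n_groups, n_loci)
    size: np.ndarray          # (n_groups, n_loci) called diploid counts
    het: np.ndarray           # (n_groups, n_loci) observed heterozygote freq
    n_group_samples: np.ndarray  # (n_groups,) samples per group

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, key in enumerate(self.group_keys):
            rows.append(pd.DataFrame({
                "group": [key] * len(self.locus_ids),
                "locus_id": self.locus_ids,
                "freq": self.freq[g],
                "n": self.size[g],
            }))
        return pd.concat(rows, ignore_index=True)


def group_allele_frequencies(dataset: GenotypeDataset,
                             by=("broodline", "generation")) -> FrequencyTable:
    """Tracked-allele (index 0) frequencies per metadata group.

    frequency = tracked-allele copies / (2 x non-missing diploids); groups
    with no called diploid at a locus are flagged NaN.
    """
    called = dataset.called_mask()
    a0 = dataset.allele_counts(0) * called
    het = (dataset.allele_counts(0) == 1) & called
    keys, freqs, sizes, hets, counts = [], [], [], [], []
    for key, mask in dataset.groups(by=by):
        n_called = called[mask].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = a0[mask].sum(axis=0) / (2.0 * n_called)
            h = het[mask].sum(axis=0) / n_called
        f[n_called == 0] = np.nan
        h[n_called == 0] = np.nan
        keys.append(key)
        freqs.append(f)
        sizes.append(n_called)
        hets.append(h)
        counts.append(int(mask.sum()))
    return FrequencyTable(
        group_keys=keys,
        locus_ids=list(dataset.locus_ids),
        freq=np.array(freqs),
        size=np.array(sizes),
        het=np.array(hets),
        n_group_samples=np.array(counts),
    )


# ---------------------------------------------------------------------------
# genotypic distance
# ---------------------------------------------------------------------------

def genotypic_distance_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Pairwise codominant-genotypic squared distances between samples.

    Per shared-called locus the contribution is half the squared Euclidean
    distance between allele-count vectors; each pair's sum is rescaled by
    (total loci / shared-called loci) so missingness does not shrink
    distances. Raises if any pair shares no called locus.
    """
    if dataset.n_samples < 2:
        raise PopStructError("need at least 2 samples for a distance matrix")
    n_alleles = max(len(a) for a in dataset.allele_names)
    n_alleles = max(n_alleles, int(dataset.calls.max()) + 1, 2)
    called = dataset.called_mask().astype(float)
    n_loci = dataset.n_loci

    # stack per-allele count matrices: C_k[i, j] = copies of allele k
    d2 = np.zeros((dataset.n_samples, dataset.n_samples))
    for k in range(n_alleles):
        ck = dataset.allele_counts(k).astype(float) * called
        sq = ck * ck
        # sum over shared loci of (c_i - c_j)^2, via masked expansion
        d2 += (sq @ called.T) + (called @ sq.T) - 2.0 * (ck @ ck.T)
    d2 *= 0.5
    shared = called @ called.T
    off = ~np.eye(dataset.n_samples, dtype=bool)
    if np.any(shared[off] == 0):
        i, j = np.argwhere((shared == 0) & off)[0]
        raise PopStructError(
            f"samples {dataset.sample_ids[i]!r} and {dataset.sample_ids[j]!r} "
            "share no called locus"
        )
    np.fill_diagonal(shared, 1.0)  # avoid 0/0 on the diagonal
    d2 = d2 * (n_loci / shared)
    np.fill_diagonal(d2, 0.0)
    return (d2 + d2.T) / 2.0  # enforce exact symmetry


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray          # (n_samples, n_axes)
    eigenvalues: np.ndarray          # all eigenvalues, decreasing (may be negative)
    explained: np.ndarray            # per-retained-axis fraction of positive variation

    def to_frame(self, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"axis{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        if meta is not None and len(meta):
            df = df.join(meta)
        return df


def principal_coordinates(d_squared: np.ndarray, n_axes: int = 2,
                          sample_ids=None) -> OrdinationResult:
    """Classical PCoA of a squared-distance matrix.

    Gower double-centering of -D²/2, symmetric eigendecomposition,
    coordinates = eigenvectors scaled by sqrt(eigenvalue). Negative
    eigenvalues (possible for non-Euclidean inputs) are reported but never
    used for coordinates. Axis signs are fixed by making the
    largest-magnitude loading on each axis positive.
    """
    d2 = np.asarray(d_squared, dtype=float)
    n = d2.shape[0]
    if d2.shape != (n, n) or not np.allclose(d2, d2.T, atol=1e-8):
        raise PopStructError("distance matrix must be square and symmetric")
    if np.any(np.diag(d2) > 1e-8) or np.any(d2 < -1e-12):
        raise PopStructError("distance matrix must be nonnegative with zero diagonal")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10, 1e-10 * abs(vals[0]))
    rank = int(pos.sum())
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but only {rank} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = rank
    coords = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    for k in range(coords.shape[1]):  # reproducible axis orientation
        imax = np.argmax(np.abs(coords[:, k]))
        if coords[imax, k] < 0:
            coords[:, k] = -coords[:, k]
    total = vals[pos].sum()
    explained = vals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return OrdinationResult(
        sample_ids=list(sample_ids),
        coordinates=coords,
        eigenvalues=vals,
        explained=explained,
    )


def run_pcoa(dataset: GenotypeDataset, n_axes: int = 2) -> OrdinationResult:
    """Distance matrix + PCoA in one call (the Figure-2 style analysis)."""
    d2 = genotypic_distance_matrix(dataset)
    return principal_coordinates(d2, n_axes=n_axes, sample_ids=dataset.sample_ids)
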