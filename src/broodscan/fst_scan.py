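"""FST-heterozygosity outlier scan among generations within a broodline.

Year classes of one broodline are treated as populations; per locus the
multi-group Weir-Cockerham (1984) theta and the expected heterozygosity He
are computed, and compared to a neutral envelope built by simulating
neutral biallelic loci under multi-generation drift. The drift effective
size is calibrated so the simulated mean FST matches the neutral mean FST
of the data (estimated iteratively, trimming loci outside a provisional
envelope, in the spirit of the fdist/Lositan "neutral mean FST" step).
Unlike the island-model null of those tools, the null here is temporal
drift matched to the study design, since the "populations" are successive
generations of a single line rather than demes.

Directional (upper-tail) outliers are designated by Benjamini-Hochberg on
He-conditioned empirical p-values; balancing-selection (lower-tail) signals
are reported separately and never fed to consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import GenotypeDataset
from .popstruct import group_allele_frequencies


class FstScanError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Weir-Cockerham estimator
# ---------------------------------------------------------------------------

def wc_fst_he_many(n, p, h):
    """Vectorised Weir-Cockerham theta and He across groups, per locus.

    Parameters are (n_groups, n_loci) arrays: called diploid counts ``n``,
    tracked-allele frequencies ``p``, observed heterozygote frequencies
    ``h``. Groups with fewer than 2 called diploids at a locus are excluded
    from that locus; loci with fewer than 2 eligible groups are unscannable
    (NaN). Returns (theta, he, scannable).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    ok = (n >= 2) & ~np.isnan(p)
    nm = np.where(ok, n, 0.0)
    pm = np.where(ok, p, 0.0)
    hm = np.where(ok, h, 0.0)
    r = ok.sum(axis=0).astype(float)
    s1 = nm.sum(axis=0)                     # sum n_i
    s2 = (nm * nm).sum(axis=0)              # sum n_i^2
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = s1 / r
        nc = (s1 - s2 / s1) / (r - 1.0)
        pbar = (nm * pm).sum(axis=0) / s1
        s2var = (nm * (pm - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (nm * hm).sum(axis=0) / s1
        a = (nbar / nc) * (
            s2var - (pbar * (1 - pbar) - (r - 1) / r * s2var - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2var - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom
    he = 2.0 * pbar * (1.0 - pbar)
    scannable = (r >= 2) & np.isfinite(theta)
    theta = np.where(scannable, theta, np.nan)
    he = np.where(r >= 1, he, np.nan)
    return theta, he, scannable


def wc_fst_he(groups):
    """Weir-Cockerham (theta, He) for one locus from per-group genotype counts.

    ``groups`` is a sequence of (n_hom_tracked, n_het, n_hom_other) count
    triples, one per population (here: per generation). Groups with fewer
    than 2 diploids are ignored; fewer than 2 eligible groups raises.
    """
    tri = [(int(x), int(y), int(z)) for x, y, z in groups]
    n = np.array([[sum(t)] for t in tri], dtype=float)
    eligible = n[:, 0] >= 2
    if eligible.sum() < 2:
        raise FstScanError("need >= 2 groups with >= 2 called diploids")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.array([[(2 * a + ab) / (2 * s) if (s := a + ab + b) else np.nan]
                      for a, ab, b in tri])
        h = np.array([[ab / s if (s := a + ab + b) else np.nan] for a, ab, b in tri])
    theta, he, scannable = wc_fst_he_many(n, p, h)
    if not scannable[0]:
        raise FstScanError("locus unscannable (monomorphic across groups)")
    return float(theta[0]), float(he[0])


# ---------------------------------------------------------------------------
# neutral simulation and envelope
# ---------------------------------------------------------------------------

@dataclass
class NeutralEnvelope:
    """He-conditioned FST quantile band from simulated neutral loci."""

    bin_edges: np.ndarray      # (n_bins + 1,) He edges (equal-count bins)
    bin_centers: np.ndarray    # (n_bins,) mean simulated He per bin
    lo: np.ndarray             # (n_bins,) lower FST quantile per bin
    hi: np.ndarray             # (n_bins,) upper FST quantile per bin
    sim_fst_by_bin: list       # sorted simulated FST arrays per bin
    ci: float
    neutral_mean_fst: float
    ne_calibrated: float
    n_sims: int

    def bounds(self, he) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (lo, hi) envelope at the given He values."""
        he = np.asarray(he, dtype=float)
        return (np.interp(he, self.bin_centers, self.lo),
                np.interp(he, self.bin_centers, self.hi))

    def bin_of(self, he) -> np.ndarray:
        """Equal-count bin index for each He (nearest-bin beyond the range)."""
        idx = np.digitize(np.asarray(he, dtype=float), self.bin_edges[1:-1], right=False)
        return np.clip(idx, 0, len(self.bin_centers) - 1)


def simulate_neutral_loci(n_loci: int, ne: float, group_sizes, generations, rng,
                          founder_low: float = 0.02, founder_high: float = 0.98):
    """Simulate neutral biallelic loci drifting across the observed year classes.

    Founder frequencies are Uniform(founder_low, founder_high) so simulated
    He spans the observed range; each group g with size ``group_sizes[g]``
    is sampled (HWE multinomial) at the frequency of generation
    ``generations[g]``. Returns (fst, he) arrays of length ``n_loci``.
    """
    gens = np.asarray(generations, dtype=int)
    sizes = np.asarray(group_sizes, dtype=int)
    two_ne = max(int(round(2 * ne)), 4)
    p = rng.uniform(founder_low, founder_high, size=n_loci)
    freq_at = {0: p.copy()}
    cur = p
    for t in range(1, int(gens.max()) + 1):
        cur = rng.binomial(two_ne, cur) / float(two_ne)
        freq_at[t] = cur.copy()
    n_mat = np.empty((len(sizes), n_loci))
    p_mat = np.empty((len(sizes), n_loci))
    h_mat = np.empty((len(sizes), n_loci))
    for g, (sz, gen) in enumerate(zip(sizes, gens)):
        f = freq_at[int(gen)]
        pv = np.stack([f * f, 2 * f * (1 - f), (1 - f) ** 2], axis=-1)
        counts = rng.multinomial(int(sz), pv)     # (n_loci, 3)
        n_mat[g] = sz
        p_mat[g] = (2 * counts[:, 0] + counts[:, 1]) / (2.0 * sz)
        h_mat[g] = counts[:, 1] / float(sz)
    fst, he, scannable = wc_fst_he_many(n_mat, p_mat, h_mat)
    return fst[scannable], he[scannable]


def _trimmed_mean(fst, he, ci: float, n_bins: int) -> float:
    """Mean FST of loci inside their own per-He-bin central-ci quantile band.

    Applying the identical trim to simulated and observed loci keeps the
    envelope calibration unbiased: an envelope-trimmed observed mean must be
    matched against an equally trimmed simulated mean.
    """
    edges, _, lo, hi = _bin_envelope(fst, he, ci, n_bins)
    idx = np.digitize(he, edges[1:-1])
    inside = (fst >= lo[idx]) & (fst <= hi[idx])
    return float(fst[inside].mean())


def _calibrate_ne(target_fst: float, group_sizes, generations, rng,
                  trim_ci: float | None = None, n_bins: int = 20,
                  n_calib: int = 6000, n_iter: int = 14) -> float:
    """Bisection on log2(Ne) so simulated mean WC FST matches ``target_fst``.

    Calibration uses the same estimator and group structure as the scan,
    with common random numbers across evaluations. When ``trim_ci`` is set,
    the simulated statistic is the per-He-bin trimmed mean, mirroring a
    trimmed observed target.
    """
    target = max(float(target_fst), 1e-5)
    seed = int(rng.integers(0, 2**31 - 1))
    lo, hi = np.log2(4.0), np.log2(5e5)  # Ne in [4, 500000]

    def mean_fst(log_ne: float) -> float:
        r = np.random.default_rng(seed)
        fst, he = simulate_neutral_loci(n_calib, 2.0 ** log_ne, group_sizes,
                                        generations, r)
        if trim_ci is not None:
            return _trimmed_mean(fst, he, trim_ci, n_bins)
        return float(np.nanmean(fst))

    if mean_fst(lo) < target:
        return 2.0 ** lo
    if mean_fst(hi) > target:
        return 2.0 ** hi
    for _ in range(n_iter):
        mid = (lo + hi) / 2.0
        if mean_fst(mid) > target:
            lo = mid
        else:
            hi = mid
    return 2.0 ** ((lo + hi) / 2.0)


def neutral_envelope(observed_fst, observed_he, group_sizes, generations,
                     n_sims: int = 50000, ci: float = 0.95, rng=None,
                     n_bins: int = 20, max_calibration_iter: int = 10) -> NeutralEnvelope:
    """Build the He-conditioned neutral FST envelope.

    1. estimate the neutral mean FST iteratively: start from the mean of all
       scannable loci, build a provisional envelope from a reduced
       simulation, drop loci outside it, recompute until stable;
    2. simulate ``n_sims`` neutral loci at the calibrated drift size;
    3. bin the simulated loci by He (equal-count), take per-bin FST
       quantiles at (1-ci)/2 and 1-(1-ci)/2, interpolate between bin centers.
    """
    if rng is None:
        rng = np.random.default_rng()
    fst = np.asarray(observed_fst, dtype=float)
    he = np.asarray(observed_he, dtype=float)
    ok = np.isfinite(fst) & np.isfinite(he)
    fst, he = fst[ok], he[ok]
    if fst.size < 100:
        raise FstScanError(f"too few scannable loci to calibrate ({fst.size} < 100)")
    if n_sims < 1000:
        raise FstScanError("n_sims must be >= 1000")

    mean_fst = max(float(fst.mean()), 1e-5)
    ne = _calibrate_ne(mean_fst, group_sizes, generations, rng)
    n_prov = max(min(n_sims // 5, 10000), 2000)
    for _ in range(max_calibration_iter):
        sim_fst, sim_he = simulate_neutral_loci(n_prov, ne, group_sizes, generations, rng)
        env = _bin_envelope(sim_fst, sim_he, ci, n_bins)
        lo_b, hi_b = (np.interp(he, env[1], env[2]), np.interp(he, env[1], env[3]))
        inside = (fst >= lo_b) & (fst <= hi_b)
        if inside.sum() < 100:
            break
        # trimmed observed mean is matched against an equally trimmed
        # simulated mean, otherwise the trim biases Ne upward
        new_mean = max(float(fst[inside].mean()), 1e-5)
        ne_new = _calibrate_ne(new_mean, group_sizes, generations, rng, trim_ci=ci,
                               n_bins=n_bins)
        mean_fst = new_mean
        if abs(np.log(ne_new) - np.log(ne)) < 0.02:
            ne = ne_new
            break
        ne = ne_new
    sim_fst, sim_he = simulate_neutral_loci(n_sims, ne, group_sizes, generations, rng)
    edges, centers, lo_q, hi_q = _bin_envelope(sim_fst, sim_he, ci, n_bins)
    order = np.digitize(sim_he, edges[1:-1])
    pools = [np.sort(sim_fst[order == b]) for b in range(len(centers))]
    return NeutralEnvelope(
        bin_edges=edges, bin_centers=centers, lo=lo_q, hi=hi_q,
        sim_fst_by_bin=pools, ci=ci, neutral_mean_fst=mean_fst,
        ne_calibrated=float(ne), n_sims=int(n_sims),
    )


def _bin_envelope(sim_fst, sim_he, ci, n_bins):
    """Equal-count He bins with per-bin FST quantiles."""
    qs = [(1 - ci) / 2.0, 1 - (1 - ci) / 2.0]
    edges = np.quantile(sim_he, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) - 1 < 2:
        raise FstScanError("degenerate He distribution in simulation")
    idx = np.digitize(sim_he, edges[1:-1])
    centers = np.empty(len(edges) - 1)
    lo_q = np.empty(len(edges) - 1)
    hi_q = np.empty(len(edges) - 1)
    for b in range(len(edges) - 1):
        sel = idx == b
        centers[b] = sim_he[sel].mean()
        lo_q[b], hi_q[b] = np.quantile(sim_fst[sel], qs)
    return edges, centers, lo_q, hi_q


# ---------------------------------------------------------------------------
# outlier designation
# ---------------------------------------------------------------------------

@dataclass
class FstScanResult:
    broodline: str
    table: pd.DataFrame       # locus_id, fst, he, env_lo, env_hi, p, q, outlier,
                              # above_envelope, p_low, balancing, scannable
    neutral_mean_fst: float
    n_sims: int
    ci: float
    fdr: float
    ne_calibrated: float

    @property
    def outliers(self) -> list[str]:
        t = self.table
        return t.loc[t["outlier"].fillna(False), "locus_id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def fst_outliers(locus_ids, fst, he, envelope: NeutralEnvelope, fdr: float = 0.1,
                 broodline: str = "?") -> FstScanResult:
    """Designate directional outliers from He-conditioned empirical p-values.

    p = fraction of bin-matched simulated loci with FST >= observed (0 when
    the observed value exceeds every simulated one); Benjamini-Hochberg at
    level ``fdr`` flags outliers. Loci above the envelope's upper quantile
    are additionally marked for plotting; the lower (balancing) tail is
    reported separately.
    """
    fst = np.asarray(fst, dtype=float)
    he = np.asarray(he, dtype=float)
    scannable = np.isfinite(fst) & np.isfinite(he)
    n = fst.shape[0]
    p_hi = np.full(n, np.nan)
    p_lo = np.full(n, np.nan)
    env_lo = np.full(n, np.nan)
    env_hi = np.full(n, np.nan)
    sidx = np.flatnonzero(scannable)
    if sidx.size:
        lo_b, hi_b = envelope.bounds(he[sidx])
        env_lo[sidx], env_hi[sidx] = lo_b, hi_b
        bins = envelope.bin_of(he[sidx])
        for k, (j, b) in enumerate(zip(sidx, bins)):
            pool = envelope.sim_fst_by_bin[b]
            m = pool.size
            ge = m - np.searchsorted(pool, fst[j], side="left")
            p_hi[j] = ge / m
            le = np.searchsorted(pool, fst[j], side="right")
            p_lo[j] = le / m
    outlier = np.zeros(n, dtype=bool)
    q = np.full(n, np.nan)
    if sidx.size:
        rej, qvals, _, _ = multipletests(p_hi[sidx], alpha=fdr, method="fdr_bh")
        outlier[sidx] = rej
        q[sidx] = qvals
    balancing = np.zeros(n, dtype=bool)
    if sidx.size:
        rej_lo, _, _, _ = multipletests(p_lo[sidx], alpha=fdr, method="fdr_bh")
        balancing[sidx] = rej_lo
    table = pd.DataFrame({
        "locus_id": list(locus_ids),
        "fst": fst,
        "he": he,
        "env_lo": env_lo,
        "env_hi": env_hi,
        "p": p_hi,
        "q": q,
        "outlier": pd.array([bool(o) if s else pd.NA for o, s in zip(outlier, scannable)],
                            dtype="boolean"),
        "above_envelope": fst > env_hi,
        "p_low": p_lo,
        "balancing": balancing,
        "scannable": scannable,
    })
    return FstScanResult(
        broodline=broodline, table=table,
        neutral_mean_fst=envelope.neutral_mean_fst,
        n_sims=envelope.n_sims, ci=envelope.ci, fdr=fdr,
        ne_calibrated=envelope.ne_calibrated,
    )


def run_fst_scan(dataset: GenotypeDataset, broodline: str, n_sims: int = 50000,
                 ci: float = 0.95, fdr: float = 0.1, min_group_size: int = 8,
                 rng=None) -> FstScanResult:
    """Full FST-He outlier scan for one broodline.

    Year classes with fewer than ``min_group_size`` samples are excluded
    (mirroring the exclusion of an N=7 year class); remaining generations
    are the populations of the Weir-Cockerham estimator.
    """
    if rng is None:
        rng = np.random.default_rng()
    meta = dataset.require_metadata()
    if broodline not in set(meta["broodline"]):
        raise FstScanError(f"broodline {broodline!r} not present in metadata")
    freqtab = group_allele_frequencies(dataset)
    rows = [i for i, key in enumerate(freqtab.group_keys)
            if key[0] == broodline and freqtab.n_group_samples[i] >= min_group_size]
    if len(rows) < 2:
        raise FstScanError(
            f"broodline {broodline!r}: fewer than 2 year classes with >= "
            f"{min_group_size} samples"
        )
    gens = [int(freqtab.group_keys[i][1]) for i in rows]
    n = freqtab.size[rows]
    p = freqtab.freq[rows]
    h = freqtab.het[rows]
    fst, he, scannable = wc_fst_he_many(n, p, h)
    group_sizes = [int(round(np.nanmean(n[g]))) for g in range(len(rows))]
    env = neutral_envelope(fst[scannable], he[scannable], group_sizes, gens,
                           n_sims=n_sims, ci=ci, rng=rng)
    result = fst_outliers(freqtab.locus_ids, fst, he, env, fdr=fdr, broodline=broodline)
    return result
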