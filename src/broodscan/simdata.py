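"""Synthetic multi-generation broodline simulator with known truth.

Emulates the study design the scans are built for: three reproductively
isolated broodlines on a 3-year generation interval, four generations each
(one generation of broodline A missing), ~5,392 pre-ascertained biallelic
SNPs with founder MAF >= 0.05, Wright-Fisher drift at small effective
broodstock size, a small fraction of loci under shared directional
selection, and beta-distributed per-sample/per-locus missingness.

Genotypes are Hardy-Weinberg draws from the generation's allele frequency;
selection acts deterministically on the expected frequency before binomial
sampling (standard WF-with-selection). Loci are unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset
from .io_formats import BROODLINE_FOUNDING_YEARS


class SimConfigError(ValueError):
    pass


#: default per-broodline, per-generation broodstock sample sizes, patterned on
#: the study's year-class counts (~664 genotyped fish over 11 year classes;
#: broodline C the best-sampled, one N=7 year class in B, A missing 2003)
DEFAULT_SAMPLE_SIZES = {
    "A": [55, 0, 30, 45],
    "B": [50, 40, 7, 55],
    "C": [100, 92, 90, 100],
}


@dataclass
class SimConfig:
    """Parameters of one simulated reintroduction study.

    Attributes
    ----------
    n_broodlines : int
        Number of isolated broodlines (labelled A, B, C, ...).
    n_generations : int
        Generations per broodline, including any masked (unsampled) ones.
    n_loci : int
        Biallelic SNP count.
    n_selected : int
        Loci under shared directional selection (same sign of s in every
        broodline).
    s : float
        Additive selection coefficient on the tracked allele at selected loci.
    Ne : int
        Effective broodstock size per generation (drift intensity).
    founder_divergence : int
        Drift generations separating each broodline's founder pool from the
        common source pool; creates the broodline cluster separation.
    sample_sizes : dict[str, list[int]]
        Per-broodline, per-generation diploid sample counts; 0 masks a
        generation (broodline A's 2003 year class by default).
    missing_rate_sample, missing_rate_locus : (float, float)
        Beta(a, b) parameters for per-sample and per-locus missingness rates.
    maf_min : float
        Lower bound of the source-pool minor allele frequency (SNP panel
        ascertainment).
    migration_rate : float
        Per-generation fraction of gametes drawn from the previous calendar
        year's neighbouring broodline (jack gene flow); 0 = full isolation.
    source_infusion : float
        Per-generation fraction of gametes drawn from the unchanged source
        pool (hatchery supplementation); 0 by default.
    """

    n_broodlines: int = 3
    n_generations: int = 4
    n_loci: int = 5392
    n_selected: int = 50
    s: float = 0.5
    Ne: int = 100
    founder_divergence: int = 3
    sample_sizes: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SAMPLE_SIZES.items()})
    missing_rate_sample: tuple = (2.0, 38.0)   # mean 5% per sample
    missing_rate_locus: tuple = (1.0, 39.0)    # mean 2.5% per locus
    maf_min: float = 0.05
    migration_rate: float = 0.0
    source_infusion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise SimConfigError("s must be >= 0 (sign convention: tracked allele favoured)")
        if not (0 < self.maf_min < 0.5):
            raise SimConfigError("maf_min must lie in (0, 0.5)")
        if self.Ne < 2:
            raise SimConfigError("Ne must be >= 2")
        if self.n_selected > self.n_loci:
            raise SimConfigError("n_selected exceeds n_loci")
        labels = self.broodline_labels()
        if set(self.sample_sizes) != set(labels):
            raise SimConfigError(
                f"sample_sizes keys {sorted(self.sample_sizes)} do not match "
                f"broodlines {labels}"
            )
        for b in labels:
            sizes = self.sample_sizes[b]
            if len(sizes) != self.n_generations:
                raise SimConfigError(
                    f"sample_sizes[{b!r}] has {len(sizes)} entries, expected "
                    f"{self.n_generations}"
                )
            if any(n < 0 for n in sizes):
                raise SimConfigError("sample sizes must be >= 0")

    def broodline_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_broodlines)]


@dataclass
class SimulatedStudy:
    """A simulated dataset plus its generating truth."""

    dataset: GenotypeDataset
    truth: pd.DataFrame  # index locus_id: label (neutral|selected), s
    trajectories: dict   # broodline -> (n_generations, n_loci) frequency array
    config: SimConfig


def wright_fisher_trajectory(p0, Ne: int, s: float, n_generations: int, rng) -> np.ndarray:
    """Simulate tracked-allele frequencies over ``n_generations`` WF steps.

    Selection is gametic/additive: the post-selection expected frequency is
    p' = p(1+s) / (1+ps), then 2*Ne allele copies are drawn binomially.
    Frequencies 0 and 1 are absorbing. ``p0`` may be a scalar or an array
    (one trajectory per entry); returns shape (n_generations + 1, len(p0))
    including the founder frequency at step 0.
    """
    p = np.atleast_1d(np.asarray(p0, dtype=float)).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p0 must lie in [0, 1]")
    out = np.empty((n_generations + 1, p.shape[0]))
    out[0] = p
    for t in range(1, n_generations + 1):
        p_sel = p * (1.0 + s) / (1.0 + p * s)
        p = rng.binomial(2 * Ne, p_sel) / (2.0 * Ne)
        out[t] = p
    return out


def _wf_steps(p, Ne, s, n_steps, rng):
    """In-place multi-step WF update for a frequency vector; returns history."""
    hist = [p.copy()]
    for _ in range(n_steps):
        p_sel = p * (1.0 + s) / (1.0 + p * s)
        p = rng.binomial(2 * Ne, p_sel) / (2.0 * Ne)
        hist.append(p)
    return hist


def sample_genotypes(freqs: np.ndarray, n_samples: int, rng) -> np.ndarray:
    """Draw HWE diploid calls for ``n_samples`` at tracked-allele freqs ``freqs``.

    Returns (n_samples, n_loci, 2) allele-index pairs (0 = tracked allele).
    """
    n_loci = freqs.shape[0]
    # count of tracked allele per individual: Binomial(2, p)
    counts = rng.binomial(2, freqs[None, :], size=(n_samples, n_loci))
    calls = np.empty((n_samples, n_loci, 2), dtype=np.int16)
    calls[:, :, 0] = np.where(counts >= 1, 0, 1)
    calls[:, :, 1] = np.where(counts == 2, 0, 1)
    return calls


def simulate_study(config: SimConfig, rng=None) -> SimulatedStudy:
    """Generate a full multi-broodline study with known neutral/selected truth.

    Source-pool frequencies are Uniform(maf_min, 1 - maf_min); each broodline
    founder pool drifts ``founder_divergence`` generations from the source
    pool; generations within a broodline follow WF propagation, with the same
    selection sign at selected loci in every broodline (shared pressure).
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = cfg.broodline_labels()
    n_loci = cfg.n_loci

    source = rng.uniform(cfg.maf_min, 1.0 - cfg.maf_min, size=n_loci)
    selected = np.zeros(n_loci, dtype=bool)
    if cfg.n_selected:
        selected[rng.choice(n_loci, size=cfg.n_selected, replace=False)] = True
    s_vec = np.where(selected, cfg.s, 0.0)

    trajectories: dict[str, np.ndarray] = {}
    founders: dict[str, np.ndarray] = {}
    for b in labels:
        p = source.copy()
        for _ in range(cfg.founder_divergence):  # neutral divergence from source
            p = rng.binomial(2 * cfg.Ne, p) / (2.0 * cfg.Ne)
        founders[b] = p

    for b in labels:
        traj = np.empty((cfg.n_generations, n_loci))
        p = founders[b].copy()
        traj[0] = p
        for g in range(1, cfg.n_generations):
            p_sel = p * (1.0 + s_vec) / (1.0 + p * s_vec)
            if cfg.source_infusion > 0:
                p_sel = (1 - cfg.source_infusion) * p_sel + cfg.source_infusion * source
            if cfg.migration_rate > 0 and len(labels) > 1:
                donor = labels[(labels.index(b) - 1) % len(labels)]
                # previous calendar year = same generation index of the donor line
                donor_p = trajectories.get(donor, traj)[min(g, cfg.n_generations - 1)] \
                    if donor in trajectories else founders[donor]
                p_sel = (1 - cfg.migration_rate) * p_sel + cfg.migration_rate * donor_p
            p = rng.binomial(2 * cfg.Ne, p_sel) / (2.0 * cfg.Ne)
            traj[g] = p
        trajectories[b] = traj

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    for bi, b in enumerate(labels):
        founding_year = BROODLINE_FOUNDING_YEARS.get(b, 2000 + bi)
        for g in range(cfg.n_generations):
            n = int(cfg.sample_sizes[b][g])
            if n == 0:
                continue
            calls = sample_genotypes(trajectories[b][g], n, rng)
            blocks.append(calls)
            year = founding_year + 3 * g
            for k in range(n):
                sid = f"{b}{year}_{k + 1:03d}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "brood_year": year, "broodline": b, "generation": g}
                )
    calls = np.concatenate(blocks, axis=0)
    locus_ids = [f"Coho_{100000 + j}-{rng.integers(20, 80)}" for j in range(n_loci)]
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    dataset = GenotypeDataset(
        sample_ids,
        locus_ids,
        calls,
        allele_names=[["A", "G"] for _ in range(n_loci)],
    )
    dataset.attach_metadata(meta)
    truth = pd.DataFrame(
        {
            "label": np.where(selected, "selected", "neutral"),
            "s": s_vec,
        },
        index=pd.Index(locus_ids, name="locus_id"),
    )
    study = SimulatedStudy(dataset=dataset, truth=truth, trajectories=trajectories, config=cfg)
    return study


def apply_missingness(dataset: GenotypeDataset, config: SimConfig, rng) -> GenotypeDataset:
    """Return a copy of ``dataset`` with beta-distributed missingness applied.

    Per-sample and per-locus rates are drawn from the configured beta
    distributions; a call goes missing independently with probability
    1 - (1 - r_sample)(1 - r_locus) — emulating low-read samples and
    poorly genotyped tags.
    """
    a_s, b_s = config.missing_rate_sample
    a_l, b_l = config.missing_rate_locus
    r_sample = rng.beta(a_s, b_s, size=dataset.n_samples) if a_s > 0 else np.zeros(dataset.n_samples)
    r_locus = rng.beta(a_l, b_l, size=dataset.n_loci) if a_l > 0 else np.zeros(dataset.n_loci)
    return apply_missingness_rates(dataset, r_sample, r_locus, rng)


def apply_missingness_rates(dataset: GenotypeDataset, r_sample, r_locus, rng) -> GenotypeDataset:
    """Apply explicit per-sample / per-locus missingness rates (both in [0,1])."""
    r_sample = np.asarray(r_sample, dtype=float)
    r_locus = np.asarray(r_locus, dtype=float)
    p_miss = 1.0 - np.outer(1.0 - r_sample, 1.0 - r_locus)
    mask = rng.random(p_miss.shape) < p_miss
    calls = dataset.calls.copy()
    calls[mask] = MISSING
    out = GenotypeDataset(
        list(dataset.sample_ids),
        list(dataset.locus_ids),
        calls,
        sample_meta=dataset.sample_meta.copy(),
        allele_names=[list(a) for a in dataset.allele_names],
    )
    return out


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write GenePop + VCF + metadata TSV + truth TSV for a simulated study."""
    import os

    from .io_formats import write_genepop, write_metadata, write_vcf_genotypes

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genepop": os.path.join(outdir, "study.genepop"),
        "vcf": os.path.join(outdir, "study.vcf"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_genepop(study.dataset, paths["genepop"])
    write_vcf_genotypes(study.dataset, paths["vcf"])
    write_metadata(study.dataset.sample_meta, paths["metadata"])
    study.truth.reset_index().to_csv(paths["truth"], sep="\t", index=False)
    return paths
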