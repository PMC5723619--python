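"""Post-genotyping SNP/sample filter cascade with an audit trail.

Stage order is fixed and matters:

1. locus filters on the raw matrix — non-biallelic loci out, then minor
   allele frequency < 5% out (pooled over all samples);
2. samples with < 75% call rate over the surviving loci out;
3. loci with < 80% call rate over the surviving samples out;
4. Hardy-Weinberg exact test pooling all surviving samples as one
   population, Benjamini-Yekutieli FDR at alpha = 0.01, rejected loci out
   (guards against null alleles and paralogous sequence variants).

Boundary ties are kept: removal uses strict inequality ("less than") at
every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .datamodel import GenotypeDataset


class QcError(ValueError):
    pass


@dataclass
class QcConfig:
    maf_min: float = 0.05
    sample_call_rate_min: float = 0.75
    locus_call_rate_min: float = 0.80
    hwe_alpha: float = 0.01
    fdr_method: str = "BY"

    def __post_init__(self) -> None:
        for name in ("maf_min", "sample_call_rate_min", "locus_call_rate_min", "hwe_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise QcError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class QcReport:
    """Telescoping per-stage accounting of what was removed and why."""

    stages: list = field(default_factory=list)  # dicts: stage, entity, n_in, n_removed, n_out
    removed: pd.DataFrame | None = None         # id, stage, reason, value
    hwe_pvalues: pd.Series | None = None        # per tested locus
    hwe_threshold: float = float("nan")         # largest rejected raw p (BY effective threshold)

    def add_stage(self, stage: str, entity: str, n_in: int, n_removed: int) -> None:
        self.stages.append(
            {"stage": stage, "entity": entity, "n_in": n_in,
             "n_removed": n_removed, "n_out": n_in - n_removed}
        )

    def stage_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_tsv(self, path) -> None:
        assert self.removed is not None
        self.removed.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def minor_allele_frequency(dataset: GenotypeDataset, locus) -> float:
    """MAF of one locus pooled over all samples; requires >= 1 non-missing call."""
    j = dataset.locus_ids.index(locus) if isinstance(locus, str) else int(locus)
    calls = dataset.calls[:, j, :].ravel()
    calls = calls[calls >= 0]
    if calls.size == 0:
        raise QcError(f"locus {dataset.locus_ids[j]}: all calls missing, MAF undefined")
    p = float(np.mean(calls == 0))
    return min(p, 1.0 - p)


def _maf_vector(dataset: GenotypeDataset) -> np.ndarray:
    """Vectorised pooled MAF per locus (NaN where all-missing); biallelic view.

    Uses the tracked-allele (index 0) frequency; for a biallelic locus
    min(p, 1-p) is the MAF regardless of which allele is tracked.
    """
    called = dataset.called_mask()
    n_called = called.sum(axis=0).astype(float)
    a0 = (dataset.calls == 0).sum(axis=2) * called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = a0.sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    maf[n_called == 0] = np.nan
    return maf


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test for one biallelic locus.

    Conditions on the total sample size n and minor-allele count; the
    probability of observing h heterozygotes is proportional to
    n! / (n_hom1! h! n_hom2!) * 2**h (hypergeometric-style enumeration).
    The p-value sums the probabilities of all heterozygote configurations no
    more probable than the observed one (probability-ordering tail).
    Monomorphic loci return 1.0 (no test possible).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise QcError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise QcError("need at least one genotype")
    n_a = 2 * n_hom1 + n_het          # copies of allele 1
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    # enumerate heterozygote counts compatible with (n, n_minor): same parity
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:  # pragma: no cover - counts inconsistent with minor count
        raise QcError("observed heterozygote count incompatible with allele counts")
    p_obs = obs[0]
    # relative tolerance absorbs floating-point ties in the probability ordering
    return float(probs[probs <= p_obs * (1.0 + 1e-12)].sum().clip(0.0, 1.0))


def by_fdr_filter(p_values, alpha: float = 0.01, method: str = "BY"):
    """Benjamini-Yekutieli (or BH) step-up; returns (keep mask, effective threshold).

    The keep mask is True for tests NOT rejected; the effective threshold is
    the largest raw p-value among rejected tests (NaN when none rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), float("nan")
    if np.any((p < 0) | (p > 1)):
        raise QcError("p-values must lie in [0, 1]")
    sm_method = {"BY": "fdr_by", "BH": "fdr_bh"}[method.upper()]
    reject, _, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    threshold = float(p[reject].max()) if reject.any() else float("nan")
    return ~reject, threshold


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def _genotype_counts(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (hom tracked, het, hom other) counts over non-missing biallelic calls."""
    a0 = dataset.allele_counts(0)
    called = dataset.called_mask()
    hom1 = ((a0 == 2) & called).sum(axis=0)
    het = ((a0 == 1) & called).sum(axis=0)
    hom2 = ((a0 == 0) & called).sum(axis=0)
    return hom1, het, hom2


def run_qc(dataset: GenotypeDataset, config: QcConfig | None = None):
    """Run the full filter cascade; returns (filtered dataset, QcReport)."""
    cfg = config or QcConfig()
    report = QcReport()
    removed_rows: list[dict] = []
    ds = dataset

    # -- stage 1: locus MAF (and biallelicity) ---------------------------
    n_alleles = ds.n_observed_alleles()
    maf = _maf_vector(ds)
    drop_bi = n_alleles > 2
    drop_empty = n_alleles == 0
    with np.errstate(invalid="ignore"):
        drop_maf = (~drop_bi) & (~drop_empty) & (maf < cfg.maf_min)
    for j in np.flatnonzero(drop_bi):
        removed_rows.append({"id": ds.locus_ids[j], "stage": "maf", "entity": "locus",
                             "reason": "not biallelic", "value": int(n_alleles[j])})
    for j in np.flatnonzero(drop_empty):
        removed_rows.append({"id": ds.locus_ids[j], "stage": "maf", "entity": "locus",
                             "reason": "all calls missing", "value": 0})
    for j in np.flatnonzero(drop_maf):
        removed_rows.append({"id": ds.locus_ids[j], "stage": "maf", "entity": "locus",
                             "reason": f"MAF < {cfg.maf_min}", "value": float(maf[j])})
    keep = ~(drop_bi | drop_empty | drop_maf)
    report.add_stage("maf", "locus", ds.n_loci, int((~keep).sum()))
    ds = ds.subset(loci=keep)
    _require_nonempty(ds, "maf")

    # -- stage 2: sample call rate ---------------------------------------
    rate = ds.called_mask().mean(axis=1)
    drop_s = rate < cfg.sample_call_rate_min
    for i in np.flatnonzero(drop_s):
        removed_rows.append({"id": ds.sample_ids[i], "stage": "sample_call_rate",
                             "entity": "sample",
                             "reason": f"call rate < {cfg.sample_call_rate_min}",
                             "value": float(rate[i])})
    report.add_stage("sample_call_rate", "sample", ds.n_samples, int(drop_s.sum()))
    ds = ds.subset(samples=~drop_s)
    _require_nonempty(ds, "sample_call_rate")

    # -- stage 3: locus call rate ----------------------------------------
    rate_l = ds.called_mask().mean(axis=0)
    drop_l = rate_l < cfg.locus_call_rate_min
    for j in np.flatnonzero(drop_l):
        removed_rows.append({"id": ds.locus_ids[j], "stage": "locus_call_rate",
                             "entity": "locus",
                             "reason": f"call rate < {cfg.locus_call_rate_min}",
                             "value": float(rate_l[j])})
    report.add_stage("locus_call_rate", "locus", ds.n_loci, int(drop_l.sum()))
    ds = ds.subset(loci=~drop_l)
    _require_nonempty(ds, "locus_call_rate")

    # -- stage 4: HWE + BY-FDR -------------------------------------------
    hom1, het, hom2 = _genotype_counts(ds)
    pvals = np.array([hwe_exact_test(int(a), int(h), int(b))
                      for a, h, b in zip(hom1, het, hom2)])
    keep_mask, threshold = by_fdr_filter(pvals, alpha=cfg.hwe_alpha, method=cfg.fdr_method)
    for j in np.flatnonzero(~keep_mask):
        removed_rows.append({"id": ds.locus_ids[j], "stage": "hwe", "entity": "locus",
                             "reason": f"HWE {cfg.fdr_method}-FDR rejected "
                                       f"(alpha={cfg.hwe_alpha})",
                             "value": float(pvals[j])})
    report.add_stage("hwe", "locus", ds.n_loci, int((~keep_mask).sum()))
    report.hwe_pvalues = pd.Series(pvals, index=ds.locus_ids, name="hwe_p")
    report.hwe_threshold = threshold
    ds = ds.subset(loci=keep_mask)
    _require_nonempty(ds, "hwe")

    report.removed = pd.DataFrame(
        removed_rows, columns=["id", "stage", "entity", "reason", "value"]
    )
    return ds, report


def _require_nonempty(ds: GenotypeDataset, stage: str) -> None:
    if ds.n_loci == 0 or ds.n_samples == 0:
        raise QcError(f"QC stage {stage!r} removed every "
                      f"{'locus' if ds.n_loci == 0 else 'sample'}")
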