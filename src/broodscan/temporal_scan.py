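"""Per-locus temporal selection scan: regression slope + Q-Q deviation test.

For one broodline, each locus's tracked-allele frequency is regressed on
generation index (true spacing preserved across a missing generation). The
locus slopes are then compared to the straight line a Gaussian slope
distribution would produce on a normal Q-Q plot (Blom plotting positions,
reference line through the quartiles). The deviation of each observed slope
from its Q-Q expectation, squared and standardised by the mean squared
deviation, is referred to a chi-square distribution with 1 df; loci with
p < alpha are outliers. Because the cutoff on the deviation scale is
sqrt(chi2_0.99) times the RMS deviation, it is a data-dependent multiple of
the mean absolute deviation (about 3.2x for Gaussian deviations, larger for
heavy tails), which the result reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeDataset
from .popstruct import FrequencyTable, group_allele_frequencies


class TemporalScanError(ValueError):
    pass


@dataclass
class SlopeScanResult:
    """Per-locus slope-scan table plus scan-level deviation summary.

    ``table`` columns: locus_id, slope, scannable, rank, z (theoretical
    quantile), expected (Q-Q line), deviation, statistic, p, outlier.
    """

    broodline: str
    table: pd.DataFrame
    alpha: float
    mean_abs_deviation: float
    rms_deviation: float
    cutoff_deviation: float       # smallest |deviation| flagged
    cutoff_multiple_of_mean: float  # cutoff_deviation / mean_abs_deviation

    @property
    def outliers(self) -> list[str]:
        t = self.table
        return t.loc[t["outlier"].fillna(False), "locus_id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def slope_per_locus(freqs, generations) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope of frequency on generation index, vectorised over loci.

    ``freqs`` is (n_generations, n_loci) with NaN where a generation has no
    defined frequency; ``generations`` are the abscissa values (true
    spacing, e.g. 0, 2, 3 for a broodline missing generation 1). Returns
    (slopes, scannable) where loci with < 2 defined generations are
    unscannable (slope NaN).
    """
    y = np.asarray(freqs, dtype=float)
    x = np.asarray(generations, dtype=float)[:, None]
    ok = ~np.isnan(y)
    n = ok.sum(axis=0)
    xm = np.where(ok, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = xm.sum(axis=0) / n
        ybar = np.where(ok, y, 0.0).sum(axis=0) / n
        dx = np.where(ok, x - xbar, 0.0)
        sxx = (dx * dx).sum(axis=0)
        sxy = (dx * np.where(ok, y - ybar, 0.0)).sum(axis=0)
        slopes = sxy / sxx
    scannable = (n >= 2) & (sxx > 0)
    slopes = np.where(scannable, slopes, np.nan)
    return slopes, scannable


#: reference-line anchor quantiles for the Q-Q fit.  The fit must ignore the
#: extreme tail (the suspected outliers), but anchoring as far out as the
#: 5th/95th percentile points is needed to capture the spread of the
#: drift-induced scale mixture of slopes — an inner (quartile) anchor
#: systematically underestimates the tails and inflates the null flag rate
#: several-fold.
QQ_ANCHOR_QUANTILES = (0.05, 0.95)


def qq_expected_slopes(slopes, anchor=QQ_ANCHOR_QUANTILES) -> tuple[np.ndarray, np.ndarray]:
    """Q-Q expected value for each slope under a Gaussian reference.

    Slopes are ranked; theoretical quantiles use Blom plotting positions
    (i - 3/8)/(m + 1/4); the reference line passes through the paired
    anchor-quantile points of (theoretical, observed) — by default the
    5th/95th percentiles, so the extreme tails get no leverage on the fit.
    Returns (expected, z) aligned with the input order. Requires >= 20
    slopes and nonzero spread between the anchor quantiles.
    """
    b = np.asarray(slopes, dtype=float)
    if b.size < 20:
        raise TemporalScanError(f"need >= 20 slopes for a Q-Q fit, got {b.size}")
    if np.any(np.isnan(b)):
        raise TemporalScanError("slopes must be finite (exclude unscannable loci first)")
    m = b.size
    order = np.argsort(b, kind="stable")
    ranks = np.empty(m, dtype=np.int64)
    ranks[order] = np.arange(1, m + 1)
    z = stats.norm.ppf((ranks - 0.375) / (m + 0.25))
    q_lo, q_hi = np.quantile(b, anchor)
    z_lo, z_hi = stats.norm.ppf(anchor)
    if q_hi - q_lo <= 0:
        raise TemporalScanError("zero anchor-quantile spread: degenerate slope distribution")
    slope_line = (q_hi - q_lo) / (z_hi - z_lo)
    intercept = q_lo - slope_line * z_lo
    expected = intercept + slope_line * z
    return expected, z


def deviation_chi_square(slopes, expected, alpha: float = 0.01):
    """Chi-square outlier call from Q-Q deviations.

    d_i = |b_i - e_i|; X_i = d_i^2 / mean(d^2) ~ chi-square(1) under
    Gaussian deviations; outlier iff p_i < alpha, equivalently
    d_i >= sqrt(chi2_{1-alpha;1}) * RMS(d). Returns a dict of arrays plus
    the scan-level deviation summary.
    """
    b = np.asarray(slopes, dtype=float)
    e = np.asarray(expected, dtype=float)
    d = np.abs(b - e)
    msd = float(np.mean(d * d))
    mad = float(np.mean(d))
    if msd == 0 or mad == 0:
        raise TemporalScanError("all deviations zero: degenerate scan")
    statistic = d * d / msd
    p = stats.chi2.sf(statistic, df=1)
    outlier = p < alpha
    cutoff = float(np.sqrt(stats.chi2.ppf(1.0 - alpha, df=1) * msd))
    return {
        "deviation": d,
        "statistic": statistic,
        "p": p,
        "outlier": outlier,
        "mean_abs_deviation": mad,
        "rms_deviation": float(np.sqrt(msd)),
        "cutoff_deviation": cutoff,
        "cutoff_multiple_of_mean": cutoff / mad,
    }


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def scan_from_frequency_table(freqtab: FrequencyTable, broodline: str,
                              alpha: float = 0.01) -> SlopeScanResult:
    """Run the slope + Q-Q + chi-square scan on one broodline's frequencies."""
    rows = [i for i, key in enumerate(freqtab.group_keys) if key[0] == broodline]
    if not rows:
        raise TemporalScanError(f"broodline {broodline!r} absent from frequency table")
    gens = np.array([freqtab.group_keys[i][1] for i in rows], dtype=float)
    freqs = freqtab.freq[rows]
    slopes, scannable = slope_per_locus(freqs, gens)

    n_loci = len(freqtab.locus_ids)
    table = pd.DataFrame({
        "locus_id": freqtab.locus_ids,
        "slope": slopes,
        "scannable": scannable,
        "rank": np.full(n_loci, np.nan),
        "z": np.full(n_loci, np.nan),
        "expected": np.full(n_loci, np.nan),
        "deviation": np.full(n_loci, np.nan),
        "statistic": np.full(n_loci, np.nan),
        "p": np.full(n_loci, np.nan),
        "outlier": pd.array([pd.NA] * n_loci, dtype="boolean"),
    })
    idx = np.flatnonzero(scannable)
    if idx.size == 0:
        return SlopeScanResult(
            broodline=broodline, table=table, alpha=alpha,
            mean_abs_deviation=float("nan"), rms_deviation=float("nan"),
            cutoff_deviation=float("nan"), cutoff_multiple_of_mean=float("nan"),
        )
    b = slopes[idx]
    expected, z = qq_expected_slopes(b)
    chi = deviation_chi_square(b, expected, alpha=alpha)
    order = np.argsort(b, kind="stable")
    ranks = np.empty(b.size, dtype=float)
    ranks[order] = np.arange(1, b.size + 1)
    table.loc[idx, "rank"] = ranks
    table.loc[idx, "z"] = z
    table.loc[idx, "expected"] = expected
    table.loc[idx, "deviation"] = chi["deviation"]
    table.loc[idx, "statistic"] = chi["statistic"]
    table.loc[idx, "p"] = chi["p"]
    table.loc[idx, "outlier"] = chi["outlier"]
    return SlopeScanResult(
        broodline=broodline,
        table=table,
        alpha=alpha,
        mean_abs_deviation=chi["mean_abs_deviation"],
        rms_deviation=chi["rms_deviation"],
        cutoff_deviation=chi["cutoff_deviation"],
        cutoff_multiple_of_mean=chi["cutoff_multiple_of_mean"],
    )


def run_temporal_scan(dataset: GenotypeDataset, broodline: str,
                      alpha: float = 0.01) -> SlopeScanResult:
    """QC-filtered dataset in, per-locus slope-scan result for one broodline out.

    Year classes of the broodline are the regression points; the generation
    index (with true spacing across gaps) is the abscissa. Each broodline is
    a biological replicate: run this once per broodline and feed the results
    to the consensus stage.
    """
    meta = dataset.require_metadata()
    if broodline not in set(meta["broodline"]):
        raise TemporalScanError(f"broodline {broodline!r} not present in metadata")
    freqtab = group_allele_frequencies(dataset)
    return scan_from_frequency_table(freqtab, broodline, alpha=alpha)
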