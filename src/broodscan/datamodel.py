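"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`GenotypeDataset`: a samples × loci matrix of
unordered diploid allele-index pairs with per-sample metadata (brood year,
broodline label, generation index). Missing calls are encoded as ``-1`` in
both slots. Allele indices are 0-based per locus; the original allele labels
(VCF REF/ALT strings or GenePop codes) are retained in ``allele_names``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: metadata columns every dataset carries per sample
META_COLUMNS = ("brood_year", "broodline", "generation")


class DataModelError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass
class GenotypeDataset:
    """Samples × loci diploid genotype matrix with sample metadata.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows of ``calls``).
    locus_ids : list of str
        Unique locus identifiers (columns of ``calls``), e.g. ``Coho_64855-71``.
    calls : ndarray of shape (n_samples, n_loci, 2), integer
        Unordered pairs of 0-based allele indices; ``-1`` in both slots marks
        a missing call.
    sample_meta : DataFrame
        Indexed by sample id, with columns ``brood_year`` (int),
        ``broodline`` (str label, e.g. A/B/C) and ``generation`` (int >= 0).
        May be empty if metadata has not been attached yet.
    allele_names : list of list of str
        Per-locus allele labels aligned with allele indices.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    allele_names: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise DataModelError(
                f"calls must have shape (n_samples, n_loci, 2), got {self.calls.shape}"
            )
        if self.calls.shape[0] != len(self.sample_ids):
            raise DataModelError("calls rows do not match sample_ids")
        if self.calls.shape[1] != len(self.locus_ids):
            raise DataModelError("calls columns do not match locus_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataModelError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise DataModelError("duplicate locus ids")
        if not self.allele_names:
            n_all = int(self.calls.max(initial=1)) + 1
            names = [str(i) for i in range(max(n_all, 2))]
            self.allele_names = [list(names) for _ in self.locus_ids]
        # normalise: a call with any -1 is fully missing, pairs stored sorted
        miss = (self.calls < 0).any(axis=2)
        self.calls = np.sort(self.calls, axis=2)
        self.calls[miss] = MISSING

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def called_mask(self) -> np.ndarray:
        return ~self.missing_mask()

    # -- derived matrices -------------------------------------------------

    def allele_counts(self, allele: int = 0) -> np.ndarray:
        """Per-call count of ``allele`` (0, 1 or 2); missing calls give 0.

        Combine with :meth:`called_mask` to distinguish missing from absent.
        """
        return (self.calls == allele).sum(axis=2).astype(np.int16)

    def n_observed_alleles(self) -> np.ndarray:
        """Number of distinct alleles observed among non-missing calls, per locus."""
        out = np.zeros(self.n_loci, dtype=np.int64)
        for j in range(self.n_loci):
            vals = self.calls[:, j, :].ravel()
            out[j] = len(np.unique(vals[vals >= 0]))
        return out

    # -- subsetting -------------------------------------------------------

    def subset(self, samples=None, loci=None) -> "GenotypeDataset":
        """Return a new dataset restricted to the given sample/locus selections.

        ``samples``/``loci`` may be boolean masks, integer indices, or lists of ids.
        """
        s_idx = _resolve_index(samples, self.sample_ids)
        l_idx = _resolve_index(loci, self.locus_ids)
        meta = self.sample_meta
        new_samples = [self.sample_ids[i] for i in s_idx]
        if len(meta):
            meta = meta.loc[[s for s in new_samples if s in meta.index]]
        return GenotypeDataset(
            sample_ids=new_samples,
            locus_ids=[self.locus_ids[j] for j in l_idx],
            calls=self.calls[np.ix_(s_idx, l_idx)].copy(),
            sample_meta=meta.copy() if len(meta) else pd.DataFrame(),
            allele_names=[list(self.allele_names[j]) for j in l_idx],
        )

    # -- metadata ---------------------------------------------------------

    def attach_metadata(self, meta: pd.DataFrame) -> None:
        """Attach (replacing) per-sample metadata; every sample must be covered."""
        missing = [s for s in self.sample_ids if s not in meta.index]
        if missing:
            raise DataModelError(
                f"metadata missing for {len(missing)} samples, e.g. {missing[:3]}"
            )
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise DataModelError(f"metadata lacks required column {col!r}")
        self.sample_meta = meta.loc[self.sample_ids, list(META_COLUMNS)].copy()

    def require_metadata(self) -> pd.DataFrame:
        if len(self.sample_meta) == 0:
            raise DataModelError("dataset has no sample metadata attached")
        return self.sample_meta

    def groups(self, by=("broodline", "generation")):
        """Yield (key, boolean sample mask) per metadata group, sorted by key."""
        meta = self.require_metadata()
        keys = list(zip(*(meta[c].tolist() for c in by)))
        for key in sorted(set(keys)):
            mask = np.array([k == key for k in keys])
            yield key, mask


def _resolve_index(sel, ids) -> np.ndarray:
    if sel is None:
        return np.arange(len(ids))
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if sel.shape[0] != len(ids):
            raise DataModelError("boolean selector length mismatch")
        return np.flatnonzero(sel)
    if sel.dtype.kind in "iu":
        return sel.astype(np.int64)
    lookup = {s: i for i, s in enumerate(ids)}
    try:
        return np.array([lookup[s] for s in sel], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise DataModelError(f"unknown id {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class LocusAlignment:
    """One mapped genome position of a RAD locus tag (multi-mapping retained)."""

    locus_id: str
    chrom: str
    position: int  # 1-based leftmost aligned base
    mapq: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataModelError("alignment position must be >= 1 (1-based)")


@dataclass(frozen=True)
class GeneRecord:
    """A gene span from a GFF3 annotation, 1-based inclusive coordinates."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataModelError(f"gene {self.gene_id}: start > end")
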