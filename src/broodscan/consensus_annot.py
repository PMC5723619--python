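"""Cross-method / cross-broodline consensus of outlier calls, Venn
accounting, and nearest-gene annotation of candidates.

A "test" is one (method, broodline) pair — up to 3 methods (temporal
regression, FST-He scan, external Bayesian results) x 3 broodlines = 9
tests. Tiers: a locus significant in >= 1 test is a *candidate*;
significant in >= 2 of the 3 methods within one broodline has
*per-broodline consensus*; significant in >= 2 tests overall is *highly
significant*. Loci a method never scanned are recorded as not-tested,
distinct from not-significant, so a missing generation cannot silently
deflate consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

import numpy as np
import pandas as pd

from .datamodel import GeneRecord

SIG, NOT_SIG, NOT_TESTED = 1, 0, -1

METHODS = ("temporal", "fst", "bayes")


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusTable:
    """Locus x (method, broodline) significance matrix with candidate tiers.

    ``matrix`` holds 1 (significant), 0 (tested, not significant) or -1
    (not tested), with MultiIndex columns (method, broodline).
    """

    matrix: pd.DataFrame

    @property
    def locus_ids(self) -> list[str]:
        return list(self.matrix.index)

    def n_significant_tests(self) -> pd.Series:
        return (self.matrix == SIG).sum(axis=1)

    def candidates(self) -> list[str]:
        return self.matrix.index[self.n_significant_tests() >= 1].tolist()

    def highly_significant(self) -> list[str]:
        return self.matrix.index[self.n_significant_tests() >= 2].tolist()

    def broodline_consensus(self) -> dict[str, list[str]]:
        """Per broodline: loci significant in >= 2 of the 3 methods."""
        out: dict[str, list[str]] = {}
        broodlines = sorted({b for _, b in self.matrix.columns})
        for b in broodlines:
            cols = [c for c in self.matrix.columns if c[1] == b]
            n_sig = (self.matrix[cols] == SIG).sum(axis=1)
            out[b] = self.matrix.index[n_sig >= 2].tolist()
        return out

    def shared_across_broodlines(self, min_broodlines: int = 2) -> list[str]:
        """Loci significant (any method) in at least ``min_broodlines`` broodlines."""
        broodlines = sorted({b for _, b in self.matrix.columns})
        hits = pd.DataFrame(index=self.matrix.index)
        for b in broodlines:
            cols = [c for c in self.matrix.columns if c[1] == b]
            hits[b] = (self.matrix[cols] == SIG).any(axis=1)
        return self.matrix.index[hits.sum(axis=1) >= min_broodlines].tolist()

    def to_tsv(self, path) -> None:
        flat = self.matrix.copy()
        flat.columns = [f"{m}_{b}" for m, b in flat.columns]
        flat["n_significant_tests"] = self.n_significant_tests()
        hs = set(self.highly_significant())
        flat["tier"] = [
            "highly_significant" if i in hs else
            ("candidate" if n >= 1 else "none")
            for i, n in zip(flat.index, flat["n_significant_tests"])
        ]
        flat.index.name = "locus_id"
        flat.to_csv(path, sep="\t")


def build_consensus(results: dict) -> ConsensusTable:
    """Assemble the locus x test matrix from per-method, per-broodline results.

    ``results`` maps (method, broodline) -> DataFrame with columns
    ``locus_id`` and ``outlier`` (boolean, NA/NaN = not tested). Every input
    must cover the same locus universe; unmatched ids raise.
    """
    if len(results) < 2:
        raise ConsensusError("need result sets from >= 2 tests")
    universes = {key: set(df["locus_id"]) for key, df in results.items()}
    universe = set().union(*universes.values())
    for key, ids in universes.items():
        missing = universe - ids
        if missing:
            ex = sorted(missing)[:5]
            raise ConsensusError(
                f"test {key}: locus ids missing from its table, e.g. {ex}"
            )
    locus_ids = sorted(universe)
    cols = sorted(results.keys(), key=lambda k: (METHODS.index(k[0]), k[1]))
    mat = pd.DataFrame(NOT_TESTED, index=locus_ids,
                       columns=pd.MultiIndex.from_tuples(cols, names=["method", "broodline"]),
                       dtype=np.int8)
    for key, df in results.items():
        flags = df.set_index("locus_id")["outlier"].reindex(locus_ids)
        coded = np.full(len(locus_ids), NOT_TESTED, dtype=np.int8)
        tested = flags.notna().to_numpy()
        coded[tested] = np.where(flags[tested].to_numpy(dtype=bool), SIG, NOT_SIG)
        mat[key] = coded
    mat.index.name = "locus_id"
    return ConsensusTable(matrix=mat)


def scan_result_frame(result) -> pd.DataFrame:
    """Adapter: SlopeScanResult / FstScanResult -> (locus_id, outlier) frame."""
    t = result.table
    out = pd.DataFrame({"locus_id": t["locus_id"]})
    flags = t["outlier"]
    out["outlier"] = pd.array(
        [bool(v) if v is not pd.NA and not pd.isna(v) else pd.NA for v in flags],
        dtype="boolean",
    )
    return out


def read_external_bayes(path) -> dict[str, pd.DataFrame]:
    """Read an external Bayesian-outlier result TSV.

    Expected columns: locus_id, broodline, outlier (true/false/1/0); returns
    one (locus_id, outlier) frame per broodline. Loci absent from a
    broodline's rows are treated as not tested when the frames are aligned.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "broodline": str})
    need = {"locus_id", "broodline", "outlier"}
    if not need <= set(df.columns):
        raise ConsensusError(f"{path}: need columns {sorted(need)}")
    truthy = {"1", "true", "yes", "t"}
    df["outlier"] = [str(v).strip().lower() in truthy for v in df["outlier"]]
    return {
        b: g[["locus_id", "outlier"]].reset_index(drop=True)
        for b, g in df.groupby("broodline")
    }


def align_to_universe(frame: pd.DataFrame, locus_ids) -> pd.DataFrame:
    """Expand a (locus_id, outlier) frame to a locus universe (NA = not tested)."""
    s = frame.set_index("locus_id")["outlier"]
    s = s.reindex(locus_ids)
    return pd.DataFrame({"locus_id": list(locus_ids),
                         "outlier": pd.array(s.tolist(), dtype="boolean")})


# ---------------------------------------------------------------------------
# Venn accounting
# ---------------------------------------------------------------------------

def venn_counts(table: ConsensusTable, axis: str = "method") -> dict[str, int]:
    """Counts of flagged loci in the 7 exclusive regions of the 3-set Venn.

    ``axis`` is ``method`` or ``broodline``; a locus belongs to a set if it
    is significant in >= 1 test of that method/broodline. Keys are
    '+'-joined sorted set names; regions are exclusive, so the counts sum to
    the number of flagged loci.
    """
    if axis not in ("method", "broodline"):
        raise ConsensusError("axis must be 'method' or 'broodline'")
    level = 0 if axis == "method" else 1
    names = sorted({c[level] for c in table.matrix.columns},
                   key=(lambda m: METHODS.index(m)) if axis == "method" else None)
    membership: dict[str, set] = {}
    for name in names:
        cols = [c for c in table.matrix.columns if c[level] == name]
        sig = (table.matrix[cols] == SIG).any(axis=1)
        membership[name] = set(table.matrix.index[sig])
    counts: dict[str, int] = {}
    flagged = set().union(*membership.values()) if membership else set()
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(flagged)
            for name in combo:
                inside &= membership[name]
            for name in names:
                if name not in combo:
                    inside -= membership[name]
            counts["+".join(combo)] = len(inside)
    return counts


# ---------------------------------------------------------------------------
# nearest genes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRow:
    locus_id: str
    chrom: str
    position: int
    gene_id: str
    gene_name: str
    distance: int   # 0 if the position lies within the gene span
    rank: int       # 1..k by distance


def nearest_genes(alignments, genes, window: int = 100000, k: int = 3) -> list[AnnotationRow]:
    """Up to ``k`` nearest genes within ``window`` bases of each mapped position.

    Distance is 0 when the position falls inside the gene span, else the gap
    to the nearer span end; the window bound is inclusive. Ties break by
    (distance, gene start, gene id) for deterministic output. Multi-mapped
    loci are annotated at every retained position.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    chrom_arrays = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.start, g.gene_id))
        chrom_arrays[chrom] = (
            np.array([g.start for g in gs]),
            np.array([g.end for g in gs]),
            gs,
        )
    rows: list[AnnotationRow] = []
    for aln in alignments:
        if aln.chrom not in chrom_arrays:
            warnings.warn(
                f"locus {aln.locus_id}: chromosome {aln.chrom!r} absent from annotation",
                stacklevel=2,
            )
            continue
        starts, ends, gs = chrom_arrays[aln.chrom]
        pos = aln.position
        dist = np.where(pos < starts, starts - pos,
                        np.where(pos > ends, pos - ends, 0))
        within = np.flatnonzero(dist <= window)
        ordered = sorted(within, key=lambda i: (dist[i], gs[i].start, gs[i].gene_id))
        for rank, i in enumerate(ordered[:k], start=1):
            rows.append(AnnotationRow(
                locus_id=aln.locus_id, chrom=aln.chrom, position=pos,
                gene_id=gs[i].gene_id, gene_name=gs[i].name,
                distance=int(dist[i]), rank=rank,
            ))
    return rows


def annotation_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.locus_id, r.chrom, r.position, r.gene_id, r.gene_name, r.distance, r.rank)
         for r in rows],
        columns=["locus_id", "chrom", "position", "gene_id", "gene_name",
                 "distance", "rank"],
    )


def annotate_candidates(candidate_ids, alignments, genes,
                        window: int = 100000, k: int = 3) -> pd.DataFrame:
    """Annotate the mapped positions of candidate loci with nearby genes."""
    cand = set(candidate_ids)
    keep = [a for a in alignments if a.locus_id in cand]
    return annotation_frame(nearest_genes(keep, genes, window=window, k=k))
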