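"""Readers and writers for the external formats the pipeline touches.

GenePop and VCF carry genotypes; a sidecar tab-delimited file carries the
sample metadata neither format holds (brood year, broodline, generation);
SAM carries locus-tag genome alignments; GFF3 carries gene spans. All
coordinates are 1-based inclusive internally (SAM/GFF native).
"""

from __future__ import annotations

import os
import re
import tempfile

import numpy as np
import pandas as pd
import pysam

from .datamodel import MISSING, DataModelError, GeneRecord, GenotypeDataset, LocusAlignment


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def read_genepop(path) -> GenotypeDataset:
    """Parse a GenePop file into a :class:`GenotypeDataset`.

    Dialect: first line is a title; locus names follow, one per line or
    comma-separated on one line; ``POP``/``Pop``/``pop`` lines separate
    population blocks; each sample line is ``name , g1 g2 ...`` with 4- or
    6-digit diploid codes where ``0000``/``000000`` means missing. Allele
    codes are mapped to 0-based indices in sorted-code order; the codes are
    kept as allele names. Each population block becomes one sample group
    (recorded in the returned dataset's ``sample_meta`` as ``genepop_pop``-
    free — group structure is re-attached from the sidecar metadata file).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError(f"{path}: empty file")
    # locus names: everything between the title and the first POP line
    try:
        first_pop = next(i for i, ln in enumerate(lines) if _POP_RE.match(ln.strip()))
    except StopIteration:
        raise FormatError(f"{path}: no POP separator found") from None
    locus_lines = [ln.strip() for ln in lines[1:first_pop] if ln.strip()]
    locus_ids: list[str] = []
    for ln in locus_lines:
        locus_ids.extend(x.strip() for x in ln.split(",") if x.strip())
    if not locus_ids:
        raise FormatError(f"{path}: no locus names before first POP")

    sample_ids: list[str] = []
    raw_rows: list[list[str]] = []
    width: int | None = None
    for lineno, ln in enumerate(lines[first_pop:], start=first_pop + 1):
        stripped = ln.strip()
        if not stripped:
            continue
        if _POP_RE.match(stripped):
            continue
        if "," not in stripped:
            raise FormatError(f"{path}:{lineno}: sample line lacks ',' separator")
        name, _, geno = stripped.partition(",")
        codes = geno.split()
        if len(codes) != len(locus_ids):
            raise FormatError(
                f"{path}:{lineno}: expected {len(locus_ids)} genotypes, got {len(codes)}"
            )
        for c in codes:
            if len(c) not in (4, 6) or not c.isdigit():
                raise FormatError(
                    f"{path}:{lineno}: unknown allele-code width in {c!r} "
                    "(expected 4 or 6 digits)"
                )
            if width is None:
                width = len(c)
            elif len(c) != width:
                raise FormatError(f"{path}:{lineno}: mixed allele-code widths")
        sample_ids.append(name.strip())
        raw_rows.append(codes)

    if not sample_ids:
        raise FormatError(f"{path}: no samples")
    half = (width or 4) // 2
    n_s, n_l = len(sample_ids), len(locus_ids)
    allele_codes = np.zeros((n_s, n_l, 2), dtype=np.int32)
    for i, codes in enumerate(raw_rows):
        for j, c in enumerate(codes):
            allele_codes[i, j, 0] = int(c[:half])
            allele_codes[i, j, 1] = int(c[half:])
    # half-missing genotypes (one allele 0) are treated as missing calls
    miss = (allele_codes == 0).any(axis=2)
    calls = np.full((n_s, n_l, 2), MISSING, dtype=np.int16)
    allele_names: list[list[str]] = []
    for j in range(n_l):
        seen = np.unique(allele_codes[~miss[:, j], j, :])
        seen = seen[seen > 0]
        code_to_idx = {int(c): k for k, c in enumerate(seen)}
        allele_names.append([f"{int(c):0{half}d}" for c in seen])
        for i in range(n_s):
            if not miss[i, j]:
                calls[i, j, 0] = code_to_idx[int(allele_codes[i, j, 0])]
                calls[i, j, 1] = code_to_idx[int(allele_codes[i, j, 1])]
    # guard duplicate sample names across pops
    if len(set(sample_ids)) != len(sample_ids):
        counts: dict[str, int] = {}
        uniq = []
        for s in sample_ids:
            counts[s] = counts.get(s, 0) + 1
            uniq.append(s if counts[s] == 1 else f"{s}.{counts[s]}")
        sample_ids = uniq
    return GenotypeDataset(sample_ids, locus_ids, calls, allele_names=allele_names)


def write_genepop(dataset: GenotypeDataset, path, title: str = "broodscan export",
                  group_by=("broodline", "generation")) -> None:
    """Write a GenePop file with 4-digit allele codes (index ``i`` → ``i+1``).

    Samples are grouped into POP blocks by metadata (broodline × generation)
    when metadata is attached; otherwise a single block is written. The
    tracked allele is the first-listed (index 0) allele of each locus.
    """
    groups: list[np.ndarray]
    if len(dataset.sample_meta):
        groups = [mask for _, mask in dataset.groups(by=group_by)]
    else:
        groups = [np.ones(dataset.n_samples, dtype=bool)]
    with open(path, "w") as fh:
        fh.write(f"{title} (allele index 0 = first-listed allele)\n")
        for locus in dataset.locus_ids:
            fh.write(f"{locus}\n")
        for mask in groups:
            fh.write("POP\n")
            for i in np.flatnonzero(mask):
                codes = []
                for j in range(dataset.n_loci):
                    a, b = dataset.calls[i, j]
                    if a == MISSING:
                        codes.append("0000")
                    else:
                        codes.append(f"{a + 1:02d}{b + 1:02d}")
                fh.write(f"{dataset.sample_ids[i]} , " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path) -> GenotypeDataset:
    """Read GT calls from a VCF into a :class:`GenotypeDataset`.

    ``./.`` becomes missing; the phase separator is ignored (calls are
    unordered pairs); multiallelic records are retained with all allele
    indices (QC drops non-biallelic loci later). Locus ids come from the ID
    column, falling back to ``chrom:pos``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot open VCF: {exc}") from exc
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    allele_names: list[list[str]] = []
    rows = []
    for var in vcf:
        if var.gt_types is None:  # pragma: no cover - cyvcf2 always sets this
            raise FormatError(f"{path}: record without GT at {var.CHROM}:{var.POS}")
        locus_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        allele_names.append([var.REF] + list(var.ALT))
        g = np.array(var.genotypes, dtype=np.int64)  # (n_samples, 2 or 3)
        if g.shape[1] < 2:
            raise FormatError(f"{path}: haploid GT at {var.CHROM}:{var.POS}")
        rows.append(g[:, :2])
    vcf.close()
    if not rows:
        raise FormatError(f"{path}: no variant records")
    calls = np.stack(rows, axis=1).astype(np.int16)  # (n_samples, n_loci, 2)
    calls[calls < 0] = MISSING
    return GenotypeDataset(sample_ids, locus_ids, calls, allele_names=allele_names)


def write_vcf_genotypes(dataset: GenotypeDataset, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes.

    Loci without real genomic coordinates are written on a synthetic contig
    ``unplaced`` at consecutive positions; allele names that are not plain
    nucleotide strings are replaced by placeholder bases (A/C/G/T order).
    The tracked allele (index 0) is written as REF.
    """
    nucs = ("A", "C", "G", "T")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=unplaced>\n")
        fh.write("##broodscan_allele_convention=first-listed allele (REF) is the tracked allele\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.sample_ids) + "\n")
        for j, locus in enumerate(dataset.locus_ids):
            names = dataset.allele_names[j]
            ok = all(re.fullmatch(r"[ACGTNacgtn]+", n or "") for n in names)
            alleles = list(names) if ok and len(names) >= 2 else list(nucs[: max(2, len(names))])
            ref, alts = alleles[0], alleles[1:] or ["."]
            gts = []
            for i in range(dataset.n_samples):
                a, b = dataset.calls[i, j]
                gts.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(f"unplaced\t{j + 1}\t{locus}\t{ref}\t{','.join(alts)}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata sidecar
# ---------------------------------------------------------------------------

#: founding brood years of the three Wenatchee broodlines
BROODLINE_FOUNDING_YEARS = {"A": 2000, "B": 2001, "C": 2002}


def broodline_from_year(year: int) -> str:
    """Derive the broodline label from a brood year via the 3-year cycle.

    Coho spawn almost exclusively at age 3, so year classes form three
    reproductively isolated lineages: 2000/2003/... → A, 2001/2004/... → B,
    2002/2005/... → C.
    """
    return "ABC"[(int(year) - 2000) % 3]


def read_metadata(path) -> pd.DataFrame:
    """Read the sidecar metadata TSV (sample_id, brood_year[, broodline, generation]).

    Broodline and generation are derived from ``brood_year`` when the
    override columns are absent.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "brood_year" not in meta.columns:
        raise FormatError(f"{path}: metadata needs sample_id and brood_year columns")
    meta = meta.set_index("sample_id")
    if "broodline" not in meta.columns:
        meta["broodline"] = [broodline_from_year(y) for y in meta["brood_year"]]
    if "generation" not in meta.columns:
        # founding year per broodline: the known A/B/C years, else the
        # earliest brood year of that broodline present in the file
        founding = dict(BROODLINE_FOUNDING_YEARS)
        for b, grp in meta.groupby("broodline"):
            founding.setdefault(b, int(grp["brood_year"].min()))
        meta["generation"] = [
            (int(y) - founding[b]) // 3
            for y, b in zip(meta["brood_year"], meta["broodline"])
        ]
    meta["brood_year"] = meta["brood_year"].astype(int)
    meta["generation"] = meta["generation"].astype(int)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SAM alignments
# ---------------------------------------------------------------------------

def read_alignments(path, min_mapq: int = 10) -> list[LocusAlignment]:
    """Read locus-tag alignments from a SAM file.

    Unmapped records and records with ``mapq < min_mapq`` are dropped;
    secondary alignments are kept so multi-mapping loci retain every
    position. The locus id is the read name; the position is the 1-based
    leftmost aligned base regardless of strand.
    """
    out: list[LocusAlignment] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                out.append(
                    LocusAlignment(
                        locus_id=rec.query_name,
                        chrom=rec.reference_name,
                        position=rec.reference_start + 1,
                        mapq=rec.mapping_quality,
                        strand="-" if rec.is_reverse else "+",
                    )
                )
    except ValueError as exc:
        raise FormatError(f"{path}: SAM parse error: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path) -> list[GeneRecord]:
    """Load ``gene`` features from a GFF3 file as :class:`GeneRecord` rows.

    Gene name is taken from the ``Name`` attribute, falling back to ``ID``.
    """
    import gffutils

    with tempfile.TemporaryDirectory() as tmp:
        db = gffutils.create_db(
            str(path),
            dbfn=os.path.join(tmp, "ann.db"),
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type("gene"):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            name = feat.attributes.get("Name", [gene_id])[0]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    name=name,
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand or ".",
                )
            )
    return genes
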