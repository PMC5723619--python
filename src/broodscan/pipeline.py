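"""End-to-end orchestration: simulate -> QC -> PCoA -> scans -> consensus
-> (optional) annotation, with deterministic seeding and a run manifest.

Each stochastic stage gets its own child of the global seed (via
``numpy.random.SeedSequence.spawn``), so per-stage results are reproducible
independent of execution order changes elsewhere.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus_annot import (
    ConsensusTable,
    align_to_universe,
    annotate_candidates,
    build_consensus,
    read_external_bayes,
    scan_result_frame,
    venn_counts,
)
from .datamodel import GenotypeDataset
from .fst_scan import run_fst_scan
from .io_formats import (
    read_alignments,
    read_gene_annotation,
    read_metadata,
    read_vcf_genotypes,
    write_metadata,
    write_vcf_genotypes,
)
from .popstruct import run_pcoa
from .qc_filter import QcConfig, run_qc
from .simdata import SimConfig, SimulatedStudy, apply_missingness, simulate_study, write_study
from .temporal_scan import run_temporal_scan

log = logging.getLogger("broodscan")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``input_vcf``/``input_meta`` switch the pipeline to real data; when both
    are None a study is simulated from ``sim`` (and truth-based evaluation
    is written).
    """

    outdir: str = "run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    temporal_alpha: float = 0.01
    fst_sims: int = 50000
    fst_ci: float = 0.95
    fst_fdr: float = 0.1
    fst_min_group_size: int = 8
    pcoa_axes: int = 2
    input_vcf: str | None = None
    input_meta: str | None = None
    bayes_results: str | None = None
    sam_alignments: str | None = None
    gff_annotation: str | None = None
    annotation_window: int = 100000
    annotation_k: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        qc = QcConfig(**raw.pop("qc", {}))
        return cls(sim=sim, qc=qc, **raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def evaluate_against_truth(consensus: ConsensusTable, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-test and per-tier confusion counts against simulated truth labels."""
    truth_sel = set(truth.index[truth["label"] == "selected"])
    rows = []

    def confusion(name: str, called: set, tested: set) -> dict:
        tp = len(called & truth_sel)
        fp = len(called - truth_sel)
        fn = len((tested & truth_sel) - called)
        tn = len(tested - truth_sel - called)
        return {"test": name, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                "n_called": len(called), "n_tested": len(tested)}

    mat = consensus.matrix
    for col in mat.columns:
        tested = set(mat.index[mat[col] >= 0])
        called = set(mat.index[mat[col] == 1])
        rows.append(confusion(f"{col[0]}_{col[1]}", called, tested))
    universe = set(mat.index)
    rows.append(confusion("tier_candidate", set(consensus.candidates()), universe))
    rows.append(confusion("tier_highly_significant",
                          set(consensus.highly_significant()), universe))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written as JSON)."""
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    fh = logging.FileHandler(os.path.join(cfg.outdir, "run.log"))
    log.addHandler(fh)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
        "outputs": {},
        "timings_s": {},
    }
    root_ss = np.random.SeedSequence(cfg.seed)
    children = root_ss.spawn(8)
    stage_rng = {name: np.random.default_rng(ss) for name, ss in
                 zip(["simulate", "missingness", "fst_A", "fst_B", "fst_C",
                      "fst_extra1", "fst_extra2", "spare"], children)}

    def record(stage: str, outputs: dict, t0: float) -> None:
        manifest["stages"].append(stage)
        manifest["timings_s"][stage] = round(time.time() - t0, 3)
        for key, path in outputs.items():
            manifest["outputs"][key] = {"path": path, "sha256": _sha256(path)}
        log.info("stage %s done (%.1fs)", stage, manifest["timings_s"][stage])

    try:
        # ---- stage 1: input (simulate or load) -------------------------
        t0 = time.time()
        truth = None
        if cfg.input_vcf:
            dataset = read_vcf_genotypes(cfg.input_vcf)
            dataset.attach_metadata(read_metadata(cfg.input_meta))
            record("load", {}, t0)
        else:
            study: SimulatedStudy = simulate_study(cfg.sim, rng=stage_rng["simulate"])
            study.dataset = apply_missingness(study.dataset, cfg.sim,
                                              stage_rng["missingness"])
            paths = write_study(study, os.path.join(cfg.outdir, "simulated"))
            dataset, truth = study.dataset, study.truth
            record("simulate", paths, t0)

        # ---- stage 2: QC ----------------------------------------------
        t0 = time.time()
        filtered, report = run_qc(dataset, cfg.qc)
        qc_tsv = os.path.join(cfg.outdir, "qc_report.tsv")
        report.to_tsv(qc_tsv)
        filt_vcf = os.path.join(cfg.outdir, "filtered.vcf")
        write_vcf_genotypes(filtered, filt_vcf)
        meta_tsv = os.path.join(cfg.outdir, "filtered_meta.tsv")
        write_metadata(filtered.sample_meta, meta_tsv)
        manifest["qc_stage_table"] = report.stage_table().to_dict(orient="records")
        record("qc", {"qc_report": qc_tsv, "filtered_vcf": filt_vcf,
                      "filtered_meta": meta_tsv}, t0)

        # ---- stage 3: ordination ---------------------------------------
        t0 = time.time()
        ord_res = run_pcoa(filtered, n_axes=cfg.pcoa_axes)
        coords = ord_res.to_frame(filtered.sample_meta)
        coords_tsv = os.path.join(cfg.outdir, "pcoa_coordinates.tsv")
        coords.to_csv(coords_tsv, sep="\t")
        manifest["pcoa_explained"] = [float(x) for x in ord_res.explained]
        record("pcoa", {"pcoa_coordinates": coords_tsv}, t0)

        # ---- stage 4+5: scans per broodline ----------------------------
        broodlines = sorted(set(filtered.sample_meta["broodline"]))
        results = {}
        t0 = time.time()
        for b in broodlines:
            res = run_temporal_scan(filtered, b, alpha=cfg.temporal_alpha)
            path = os.path.join(cfg.outdir, f"temporal_{b}.tsv")
            res.to_tsv(path)
            results[("temporal", b)] = scan_result_frame(res)
            manifest.setdefault("temporal_cutoff_multiple", {})[b] = \
                res.cutoff_multiple_of_mean
            manifest["outputs"][f"temporal_{b}"] = {"path": path, "sha256": _sha256(path)}
        record("temporal_scan", {}, t0)

        t0 = time.time()
        for i, b in enumerate(broodlines):
            rng = stage_rng.get(f"fst_{b}", stage_rng[f"fst_extra{(i % 2) + 1}"])
            res = run_fst_scan(filtered, b, n_sims=cfg.fst_sims, ci=cfg.fst_ci,
                               fdr=cfg.fst_fdr,
                               min_group_size=cfg.fst_min_group_size, rng=rng)
            path = os.path.join(cfg.outdir, f"fst_{b}.tsv")
            res.to_tsv(path)
            results[("fst", b)] = scan_result_frame(res)
            manifest.setdefault("fst_neutral_mean", {})[b] = res.neutral_mean_fst
            manifest["outputs"][f"fst_{b}"] = {"path": path, "sha256": _sha256(path)}
        record("fst_scan", {}, t0)

        # ---- stage 6: consensus ----------------------------------------
        t0 = time.time()
        universe = list(filtered.locus_ids)
        if cfg.bayes_results:
            for b, frame in read_external_bayes(cfg.bayes_results).items():
                results[("bayes", b)] = align_to_universe(frame, universe)
        consensus = build_consensus(results)
        cons_tsv = os.path.join(cfg.outdir, "consensus.tsv")
        consensus.to_tsv(cons_tsv)
        venn = {"method": venn_counts(consensus, "method"),
                "broodline": venn_counts(consensus, "broodline")}
        venn_json = os.path.join(cfg.outdir, "venn_counts.json")
        with open(venn_json, "w") as fhj:
            json.dump(venn, fhj, indent=2)
        manifest["n_candidates"] = len(consensus.candidates())
        manifest["n_highly_significant"] = len(consensus.highly_significant())
        outputs = {"consensus": cons_tsv, "venn_counts": venn_json}
        if truth is not None:
            truth_on_universe = truth.loc[truth.index.intersection(universe)]
            evaluation = evaluate_against_truth(consensus, truth_on_universe)
            eval_tsv = os.path.join(cfg.outdir, "evaluation.tsv")
            evaluation.to_csv(eval_tsv, sep="\t", index=False)
            outputs["evaluation"] = eval_tsv
        record("consensus", outputs, t0)

        # ---- stage 7: annotation (optional) ----------------------------
        t0 = time.time()
        if cfg.sam_alignments and cfg.gff_annotation:
            alignments = read_alignments(cfg.sam_alignments)
            genes = read_gene_annotation(cfg.gff_annotation)
            ann = annotate_candidates(consensus.candidates(), alignments, genes,
                                      window=cfg.annotation_window,
                                      k=cfg.annotation_k)
            ann_tsv = os.path.join(cfg.outdir, "nearest_genes.tsv")
            ann.to_csv(ann_tsv, sep="\t", index=False)
            record("annotate", {"nearest_genes": ann_tsv}, t0)
        else:
            record("annotate", {}, t0)
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "input"
        manifest["error"] = str(exc)
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fhj:
            json.dump(manifest, fhj, indent=2, default=str)
        raise PipelineError(
            f"pipeline aborted after stage {manifest['failed_stage']!r}: {exc}"
        ) from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fhj:
        json.dump(manifest, fhj, indent=2, default=str)
    return manifest
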