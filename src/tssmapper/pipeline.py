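"""End-to-end orchestration: tracks -> candidates -> SVM -> TSS map -> motifs -> DB.

The core run operates entirely in memory so the same code path serves the
command-line pipeline, the test-suite and reproducibility scripts; file
artifacts are written at the end from the in-memory result.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .categorizer import UtrConfig, categorize_tss_list
from .io_formats import (CoverageTrack, GeneModel, Operon, Replicon,
                         write_tss_gff3, write_tss_table)
from .peakcalling import SalienceParams, TSSCandidate, call_candidates
from .promoter import (Motif, PromoterConfig, PromoterHit, discover_motifs,
                       extract_upstream, map_promoters, motifs_to_json)
from .proteodb import ProteinEntry, ProteoConfig, build_search_db, write_fasta_db
from .simulate import SimConfig, SimDataset, make_training_labels, simulate_dataset, write_dataset
from .tss_svm import (ScoredTSS, SvmConfig, TrainingSet, assign_confidence,
                      assign_ids, extract_feature_matrix, filter_internal_tss,
                      merge_conditions, score_candidates, scored_from_candidates,
                      train_classifier)


@dataclass
class PipelineConfig:
    salience: SalienceParams = field(default_factory=SalienceParams)
    utr: UtrConfig = field(default_factory=UtrConfig)
    promoter: PromoterConfig = field(default_factory=PromoterConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    proteo: ProteoConfig = field(default_factory=ProteoConfig)
    tss_prefix: str = "TSS"
    score_cutoff: float = 0.4
    seed: int = 0


@dataclass
class PipelineResult:
    candidates: dict[str, list[TSSCandidate]]
    features: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]
    models: dict[str, object]
    tss_list: list[ScoredTSS]
    pre_filter_tss: list[ScoredTSS]
    motifs: list[Motif]
    hits: list[PromoterHit]
    proteins: list[ProteinEntry]


def _match_labels(candidates: list[TSSCandidate], labels: pd.DataFrame,
                  condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Indices of labeled candidates and their binary labels."""
    sub = labels[labels["condition"] == condition]
    lookup = {(int(r.position), r.strand): (1 if r.label == "TSS" else 0)
              for r in sub.itertuples()}
    idx, y = [], []
    for i, c in enumerate(candidates):
        lab = lookup.get((c.position, c.strand))
        if lab is not None:
            idx.append(i)
            y.append(lab)
    return np.array(idx, dtype=int), np.array(y, dtype=int)


def run_core(replicon: Replicon, genes: list[GeneModel], operons: list[Operon],
             tracks: dict[tuple[str, str, str], CoverageTrack],
             labels: pd.DataFrame, cfg: PipelineConfig | None = None,
             *, run_promoters: bool = True, run_proteodb: bool = True) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    cfg = cfg or PipelineConfig()
    candidates: dict[str, list[TSSCandidate]] = {}
    features: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    models: dict[str, object] = {}
    scored = {}
    for cond in ("Free", "Nod"):
        cands: list[TSSCandidate] = []
        for strand in ("+", "-"):
            if (cond, "TEXplus", strand) in tracks:
                cands.extend(call_candidates(tracks, cond, strand, cfg.salience))
        candidates[cond] = cands
        X = extract_feature_matrix(cands, tracks, cond)
        features[cond] = X
        idx, y = _match_labels(cands, labels, cond)
        if len(idx) == 0:
            raise ValueError(f"no training labels match any {cond} candidate")
        svm_cfg = SvmConfig(seed=cfg.svm.seed if cfg.svm.seed else cfg.seed,
                            c_grid=cfg.svm.c_grid, gamma_decades=cfg.svm.gamma_decades,
                            cv_folds=cfg.svm.cv_folds)
        model = train_classifier(TrainingSet(X[idx], y, cond), svm_cfg)
        models[cond] = model
        scores[cond] = score_candidates(model, X)
        scored[cond] = scored_from_candidates(cands, scores[cond], X)

    tss_list = merge_conditions(scored["Free"], scored["Nod"])
    assign_ids(tss_list, prefix=cfg.tss_prefix)
    categorize_tss_list(tss_list, genes, cfg.utr)
    pre_filter = list(tss_list)
    tss_list = filter_internal_tss(tss_list)
    for t in tss_list:
        assign_confidence(t, cfg.score_cutoff)

    motifs: list[Motif] = []
    hits: list[PromoterHit] = []
    if run_promoters and tss_list:
        prom_cfg = cfg.promoter
        prom_cfg.gc_background = replicon.gc_fraction()
        windows = extract_upstream(tss_list, {replicon.id: replicon}, prom_cfg.window)
        motifs = discover_motifs([s for _, s in windows], prom_cfg)
        if motifs:
            hits = map_promoters(motifs, tss_list, {replicon.id: replicon}, prom_cfg)

    proteins: list[ProteinEntry] = []
    if run_proteodb:
        proteins = build_search_db({replicon.id: replicon}, genes, tss_list,
                                   config=cfg.proteo)
    return PipelineResult(candidates, features, scores, models, tss_list,
                          pre_filter, motifs, hits, proteins)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulated_pipeline(outdir: str | os.PathLike,
                           sim_cfg: SimConfig | None = None,
                           cfg: PipelineConfig | None = None,
                           seed: int | None = None) -> PipelineResult:
    """Simulate a dataset, run the full pipeline on it and write all artifacts.

    Reruns with the same configuration and seed reproduce byte-identical
    outputs.
    """
    cfg = cfg or PipelineConfig()
    sim_cfg = sim_cfg or SimConfig()
    if seed is not None:
        cfg.seed = seed
        from dataclasses import replace
        sim_cfg = replace(sim_cfg, seed=seed)
    sim = simulate_dataset(sim_cfg)
    labels = make_training_labels(sim)
    result = run_core(sim.replicon, sim.genes, sim.operons, sim.tracks, labels, cfg)
    write_artifacts(result, sim, outdir, cfg)
    return result


def write_artifacts(result: PipelineResult, sim: SimDataset | None,
                    outdir: str | os.PathLike, cfg: PipelineConfig) -> dict:
    os.makedirs(outdir, exist_ok=True)
    artifacts: dict[str, str] = {}

    def reg(name: str, path: str) -> str:
        artifacts[name] = path
        return path

    if sim is not None:
        paths = write_dataset(sim, os.path.join(outdir, "inputs"))
        reg("genome", paths["genome"])
        reg("input_annotation", paths["annotation"])
        reg("truth_tss", paths["truth_tss"])

    cand_rows = []
    for cond, cands in result.candidates.items():
        for c, f in zip(cands, result.features[cond]):
            cand_rows.append({
                "replicon": c.replicon_id, "position": c.position,
                "strand": c.strand, "condition": cond,
                "plus_height": c.plus_peak.height, "minus_height": c.minus_peak.height,
                "plus_salience": round(c.plus_peak.salience, 4),
                "minus_salience": round(c.minus_peak.salience, 4),
            })
    pd.DataFrame(cand_rows).to_csv(reg("candidates", os.path.join(outdir, "candidates.tsv")),
                                   sep="\t", index=False)
    write_tss_table(result.tss_list, reg("tss", os.path.join(outdir, "tss_cat.tsv")))
    with open(reg("motifs", os.path.join(outdir, "motifs.json")), "w") as fh:
        json.dump(motifs_to_json(result.motifs), fh, indent=1)
    hit_rows = [{
        "tss_id": h.tss_id, "motif_id": h.motif_id, "score": round(h.score, 4),
        "box_up": f"{h.box_up_start}-{h.box_up_end}",
        "box_down": f"{h.box_down_start}-{h.box_down_end}", "strand": h.strand,
    } for h in result.hits]
    pd.DataFrame(hit_rows).to_csv(reg("hits", os.path.join(outdir, "hits.tsv")),
                                  sep="\t", index=False)
    write_tss_gff3(result.tss_list, result.hits,
                   reg("annotation", os.path.join(outdir, "annotation.gff3")))
    write_fasta_db(result.proteins,
                   reg("searchdb", os.path.join(outdir, "searchdb.fasta")))

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "salience_m": cfg.salience.m,
            "prune_window": cfg.salience.prune_window,
            "max_pair_separation": cfg.salience.max_pair_separation,
            "utr5_max": cfg.utr.utr5_max, "utr3_max": cfg.utr.utr3_max,
            "score_cutoff": cfg.score_cutoff,
            "promoter_window": cfg.promoter.window,
        },
        "artifacts": artifacts,
        "checksums": {name: _sha256(path) for name, path in artifacts.items()
                      if os.path.isfile(path)},
        "n_tss": len(result.tss_list),
        "n_motifs": len(result.motifs),
        "n_proteins": len(result.proteins),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
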