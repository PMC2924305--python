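"""End-to-end orchestration: stages, manifest, structured logging.

``run_pipeline`` executes the analysis stages in dependency order on a set
of input files (typically produced by :mod:`peakscan.simulate` or supplied
by the user) and writes per-stage TSV/BED artifacts plus a JSON manifest
recording inputs, outputs, parameters and record counts.  Reruns with an
identical config produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotation, conservation, phenosim, significance
from .genomics import (
    Genome,
    GenomicInterval,
    read_bed,
    read_bedgraph,
    read_gene_models,
    read_wiggle,
)
from .motif import batch_best_scores, calibrate_threshold, estimate_fdr, read_meme

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("peakscan")

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths to all inputs plus the per-stage parameter blocks."""

    genome: str
    peaks: str
    genes: str
    out_dir: str
    conservation: str | None = None
    ctcf: str | None = None
    disease_matrix: str | None = None
    disease_set: str | None = None
    motifs: str | None = None  # external MEME motifs joining discovery output
    seed: int = 0
    train_fraction: float = 0.2
    window: int = 200
    discovery_widths: tuple[int, int] = (6, 20)
    n_per_width: int = 10
    n_background: int | None = None  # default: one per peak
    annotation: Mapping[str, int] = field(
        default_factory=lambda: asdict(annotation.AnnotationConfig())
    )
    domain_max_distance: int = 300_000
    n_perm: int = 999
    n_null_samples: int = 999
    run_discovery: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "discovery_widths" in data:
            data["discovery_widths"] = tuple(data["discovery_widths"])
        return cls(**data)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run all stages; returns the manifest (also written to the out dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict[str, Any] = {
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "stages": [],
    }
    state: dict[str, Any] = {}
    stages = [
        ("load_inputs", _stage_load),
        ("motif_discovery", _stage_discovery),
        ("motif_scan", _stage_scan),
        ("annotate", _stage_annotate),
        ("target_genes", _stage_ptg),
        ("conservation", _stage_conservation),
        ("phenotype_similarity", _stage_phenosim),
        ("domains", _stage_domains),
    ]
    try:
        for name, fn in stages:
            t0 = time.perf_counter()
            try:
                counts = fn(cfg, state, out)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - named-stage reporting
                raise PipelineError(name, str(exc)) from exc
            elapsed = time.perf_counter() - t0
            logger.info("stage %s done in %.2fs: %s", name, elapsed, counts)
            manifest["stages"].append(
                {"stage": name, "wall_seconds": round(elapsed, 3), "counts": counts}
            )
    except PipelineError:
        (out / "PARTIAL").write_text("pipeline aborted; see run.log\n")
        _write_manifest(manifest, out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict[str, Any], out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


# ---------------------------------------------------------------------------
# Stages


def _stage_load(cfg: RunConfig, state: dict, out: Path) -> dict[str, int]:
    for key in ("genome", "peaks", "genes"):
        if not Path(getattr(cfg, key)).exists():
            raise PipelineError("load_inputs", f"missing input: {key}")
    state["genome"] = Genome(cfg.genome)
    state["peaks"] = read_bed(cfg.peaks)
    state["genes"] = read_gene_models(cfg.genes)
    counts = {"peaks": len(state["peaks"]), "genes": len(state["genes"])}
    if cfg.conservation:
        path = Path(cfg.conservation)
        reader = read_wiggle if path.suffix in (".wig", ".wiggle") else read_bedgraph
        state["track"] = reader(path, state["genome"].chrom_lengths)
    if cfg.ctcf:
        state["ctcf"] = [p.interval for p in read_bed(cfg.ctcf)]
        counts["ctcf_sites"] = len(state["ctcf"])
    if cfg.disease_matrix:
        state["matrix"] = phenosim.DiseaseFeatureMatrix.from_tsv(cfg.disease_matrix)
        counts["diseases"] = state["matrix"].n_diseases
    return counts


def _prepare_sequence_sets(cfg: RunConfig, state: dict) -> None:
    genome, peaks = state["genome"], state["peaks"]
    train, evals = significance.split_train_eval(
        peaks, genome, cfg.train_fraction, cfg.window, seed=cfg.seed
    )
    n_bg = cfg.n_background or len(peaks)
    templates = [
        GenomicInterval(p.chrom, p.summit - cfg.window // 2, p.summit + cfg.window // 2)
        for p in peaks
        if p.summit - cfg.window // 2 >= 0
        and p.summit + cfg.window // 2 <= genome.chrom_length(p.chrom)
    ]
    bg_regions = significance.sample_genomic_background(
        genome, templates, n_bg, seed=cfg.seed + 1, exclude=[p.interval for p in peaks]
    )
    state["train"], state["eval"] = train, evals
    state["bg_genomic"] = [genome.fetch(iv) for iv in bg_regions]
    state["bg_regions"] = bg_regions
    state["bg_markov"] = significance.markov_background(
        train + evals, order=1, n=n_bg, length=cfg.window, seed=cfg.seed + 2
    )


def _stage_discovery(cfg: RunConfig, state: dict, out: Path) -> dict[str, int]:
    _prepare_sequence_sets(cfg, state)
    candidates: list[significance.MotifCandidate] = []
    if cfg.run_discovery:
        lo, hi = cfg.discovery_widths
        candidates += significance.discover_motifs(
            state["train"],
            widths=range(lo, hi + 1),
            n_per_width=cfg.n_per_width,
            seed=cfg.seed,
        )
    if cfg.motifs:
        for name, pwm in read_meme(cfg.motifs).items():
            candidates.append(significance.MotifCandidate(pwm, source="external"))
    results = significance.evaluate_candidates(
        candidates, state["train"], state["eval"], state["bg_genomic"], state["bg_markov"]
    )
    rows = [
        {
            "motif": c.pwm.name,
            "source": c.source,
            "width": c.width,
            "consensus": c.pwm.consensus,
            "p_hyper": r.p_hyper,
            "q_bh": r.q_bh,
            "fold_genomic": r.fold_genomic,
            "fold_markov": r.fold_markov,
            "auc": r.auc,
            "significant": r.significant,
        }
        for c, r in results
    ]
    _write_tsv(pd.DataFrame(rows), out / "motif_candidates.tsv")
    try:
        state["best_motif"] = significance.select_best_motif(results).pwm
    except significance.NoSignificantMotifError:
        state["best_motif"] = None
    n_sig = int(sum(r.significant for _, r in results))
    return {"candidates": len(candidates), "significant": n_sig}


def _stage_scan(cfg: RunConfig, state: dict, out: Path) -> dict[str, int]:
    pwm = state.get("best_motif")
    if pwm is None:
        (out / "scan_skipped.txt").write_text("no significant motif\n")
        return {"scanned": 0}
    pos = state["train"] + state["eval"]
    cal = calibrate_threshold(
        batch_best_scores(pwm, pos), batch_best_scores(pwm, state["bg_markov"])
    )
    scores = batch_best_scores(pwm, pos)
    hit = scores >= cal.threshold
    df = pd.DataFrame(
        {
            "sequence_index": np.arange(len(pos)),
            "best_score": scores,
            "hit": hit,
        }
    )
    _write_tsv(df, out / "scan_hits.tsv")
    state["scan"] = {
        "threshold": cal.threshold,
        "f_measure": cal.f_measure,
        "fdr": estimate_fdr(
            cal.threshold, scores, batch_best_scores(pwm, state["bg_markov"])
        ),
        "hit_fraction": float(hit.mean()),
    }
    (out / "scan_summary.json").write_text(
        json.dumps(state["scan"], indent=1, sort_keys=True)
    )
    return {"scanned": len(pos), "hits": int(hit.sum())}


def _stage_annotate(cfg: RunConfig, state: dict, out: Path) -> dict[str, int]:
    acfg = annotation.AnnotationConfig(**cfg.annotation)
    cats = annotation.classify_peaks(state["peaks"], state["genes"], acfg)
    df = pd.DataFrame(
        {"peak": [p.name for p in state["peaks"]], "category": cats}
    )
    _write_tsv(df, out / "peak_categories.tsv")
    enrich = annotation.category_enrichment(
        state["peaks"],
        state["genes"],
        acfg,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        chrom_lengths=state["genome"].chrom_lengths,
    )
    _write_tsv(enrich.reset_index(), out / "category_enrichment.tsv")
    state["categories"] = cats
    return {"classified": len(cats)}


def _stage_ptg(cfg: RunConfig, state: dict, out: Path) -> dict[str, int]:
    acfg = annotation.AnnotationConfig(**cfg.annotation)
    mapping = annotation.map_to_ptg(state["peaks"], state["genes"], acfg)
    rows = [
        {"gene": gid, "peak": p.name}
        for gid, plist in sorted(mapping.items())
        for p in plist
    ]
    _write_tsv(pd.DataFrame(rows, columns=["gene", "peak"]), out / "ptg.tsv")
    state["ptg"] = mapping
    return {"potential_target_genes": len(mapping)}


def _stage_conservation(cfg: RunConfig, state: dict, out: Path) -> dict[str, int]:
    track = state.get("track")
    if track is None:
        return {"summaries": 0}
    genome = state["genome"]
    rows = []
    peak_scores = []
    for p in state["peaks"]:
        iv = conservation.summit_window(p, 100, genome.chrom_length(p.chrom))
        s = conservation.region_mean_score(track, iv)
        peak_scores.append(s.pccs)
        rows.append(
            {
                "peak": p.name,
                "pccs": s.pccs,
                "covered_fraction": s.covered_fraction,
                "height": p.height,
            }
        )
    df = pd.DataFrame(rows)
    _write_tsv(df, out / "conservation.tsv")
    cutoffs = np.round(np.linspace(1.0, 0.0, 21), 3)
    _write_tsv(
        conservation.cumulative_curve(peak_scores, cutoffs), out / "conservation_curve.tsv"
    )
    rand_scores = [
        conservation.region_mean_score(track, iv).pccs
        for iv in state.get("bg_regions", [])
        if iv.chrom in track
    ]
    counts = {"summaries": len(rows)}
    if rand_scores:
        stat, p = conservation.compare_sets(peak_scores, rand_scores)
        (out / "conservation_test.json").write_text(
            json.dumps({"mannwhitney_u": stat, "p_two_sided": p}, indent=1)
        )
    if len(df) >= 4:
        _write_tsv(
            conservation.quartile_summary(df["pccs"], df["height"]).reset_index(),
            out / "conservation_quartiles.tsv",
        )
    return counts


def _stage_phenosim(cfg: RunConfig, state: dict, out: Path) -> dict[str, int]:
    matrix = state.get("matrix")
    if matrix is None or not cfg.disease_set:
        return {"disease_sets": 0}
    disease_set = [
        line.strip()
        for line in Path(cfg.disease_set).read_text().splitlines()
        if line.strip()
    ]
    result = phenosim.evaluate_disease_set(
        matrix, disease_set, n_samples=cfg.n_null_samples, seed=cfg.seed
    )
    ranked = phenosim.term_overrepresentation(matrix, disease_set)
    _write_tsv(ranked, out / "term_ranking.tsv")
    (out / "similarity.json").write_text(
        json.dumps(
            {
                "set_score": result.set_score,
                "null_mean": result.null_mean,
                "p_empirical": result.p_empirical,
                "n_samples": result.n_samples,
            },
            indent=1,
            sort_keys=True,
        )
    )
    return {"disease_sets": 1, "set_size": len(disease_set)}


def _stage_domains(cfg: RunConfig, state: dict, out: Path) -> dict[str, int]:
    if "ctcf" not in state:
        if cfg.ctcf:
            raise PipelineError("domains", f"missing CTCF file {cfg.ctcf}")
        return {"pairs": 0}
    dcfg = annotation.DomainSearchConfig(max_distance=cfg.domain_max_distance)
    pairs = annotation.candidate_elements(
        state["peaks"], state["genes"], state["ctcf"], dcfg
    )
    rows = [
        {
            "gene": g.gene_id,
            "peak": p.name,
            "distance": 0
            if p.interval.overlaps(g.interval)
            else int(
                max(g.interval.start - p.interval.end, p.interval.start - g.interval.end)
            ),
        }
        for g, p in pairs
    ]
    _write_tsv(pd.DataFrame(rows, columns=["gene", "peak", "distance"]), out / "domains.tsv")
    return {"pairs": len(pairs)}
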