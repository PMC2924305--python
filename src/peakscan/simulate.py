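"""Synthetic-data generators with ground-truth tables.

Every generator is deterministic under (parameters, seed); one master seed
fans out to per-generator child seeds by stable hashing of generator names,
so adding a generator never perturbs the others.  Defaults emulate the study
conditions the pipeline was built around: 200-bp peaks with a dimeric
p53-family motif planted at the observed motif-bearing rate, a conservation
track elevated under a subset of peaks, and a disease-term matrix containing
one clustered disease set whose mean pairwise similarity sits above the
random background.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CATEGORIES, AnnotationConfig, CategoryIndex
from .genomics import (
    GeneModel,
    GenomicInterval,
    Genome,
    Peak,
    ScoreTrack,
    write_bed,
    write_bedgraph,
    write_fasta,
)
from .motif import DimericPWM
from .phenosim import DiseaseFeatureMatrix

__all__ = [
    "child_seed",
    "make_genome",
    "default_dimeric_pwm",
    "make_genes",
    "plant_peaks",
    "make_ctcf_sites",
    "make_conservation_track",
    "make_disease_matrix",
    "simulate_scenario",
]

_BASES = np.array(list("ACGT"))


def child_seed(master_seed: int, name: str) -> int:
    """Stable per-generator child seed derived from a master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_genome(
    chrom_lengths: Mapping[str, int], gc_content: float = 0.41, seed: int = 0
) -> dict[str, str]:
    """I.i.d. random chromosome sequences at the requested GC content."""
    if not 0 < gc_content <= 1:
        raise ValueError("gc_content must be in (0, 1]")
    for c, L in chrom_lengths.items():
        if L < 1000:
            raise ValueError(f"chromosome {c} shorter than 1 kb")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    return {
        c: "".join(_BASES[rng.choice(4, size=L, p=p)])
        for c, L in chrom_lengths.items()
    }


def default_dimeric_pwm(background: np.ndarray | None = None) -> DimericPWM:
    """A p53-family dimeric motif: two RRRCWWGYYY half-sites, no spacer.

    The essential C (position 4) and G (position 7) of each half-site carry
    most of the information, as in the canonical p53/p63 response element.
    """
    strong = 0.85
    weak = 0.05
    R = [0.45, weak, 0.45, weak]
    C = [weak, strong, weak, weak]
    W = [0.45, weak, weak, 0.45]
    G = [weak, weak, strong, weak]
    Y = [weak, 0.45, weak, 0.45]
    half = np.array([R, R, R, C, W, W, G, Y, Y, Y])
    return DimericPWM(
        half_a=half,
        half_b=half.copy(),
        spacer_range=(0, 0),
        background=background,
        name="dimeric_consensus",
    )


def sample_motif_instance(pwm: DimericPWM, rng: np.random.Generator) -> str:
    """One motif instance sampled column-wise from the PWM (spacer uniform)."""
    spacer = int(rng.integers(pwm.spacer_range[0], pwm.spacer_range[1] + 1))
    parts = []
    for half in (pwm.half_a, pwm.half_b):
        for row in half:
            parts.append(_BASES[rng.choice(4, p=row / row.sum())])
        if half is pwm.half_a and spacer:
            parts.extend(_BASES[rng.choice(4, size=spacer)])
    return "".join(parts)


def make_genes(
    chrom_lengths: Mapping[str, int],
    n_genes: int,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (2_000, 10_000),
    n_exons_range: tuple[int, int] = (2, 5),
    max_tries: int = 10_000,
) -> list[GeneModel]:
    """Random non-overlapping stranded gene models with exon structure."""
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    tries = 0
    while len(genes) < n_genes:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place all genes without overlap")
        c = chroms[rng.choice(len(chroms), p=weights)]
        L = chrom_lengths[c]
        glen = int(rng.integers(*gene_length_range))
        if glen >= L:
            continue
        start = int(rng.integers(0, L - glen))
        if any(start < e and s < start + glen for s, e in placed[c]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        # exon boundaries: 2*n_ex sorted interior cut points
        cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2, replace=False))
        bounds = np.concatenate([[0], cuts, [glen]])
        exons = tuple(
            GenomicInterval(c, start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]), strand)
            for i in range(n_ex)
            if bounds[2 * i + 1] > bounds[2 * i]
        )
        if not exons:
            continue
        iv = GenomicInterval(c, start, start + glen, strand)
        genes.append(GeneModel(f"gene_{len(genes) + 1}", iv, exons))
        placed[c].append((start, start + glen))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def plant_peaks(
    genome: Mapping[str, str],
    n: int,
    pwm: DimericPWM | None = None,
    planting_rate: float = 0.94,
    peak_length: int = 200,
    category_mix: Mapping[str, float] | None = None,
    genes: Sequence[GeneModel] = (),
    seed: int = 0,
    height_log_mean: float = 3.9,
    height_log_sd: float = 1.0,
    cfg: AnnotationConfig = AnnotationConfig(),
    max_tries_factor: int = 500,
) -> tuple[list[Peak], pd.DataFrame, dict[str, str]]:
    """Peaks with a motif instance embedded at the summit.

    With probability ``planting_rate`` a motif instance sampled from the PWM
    replaces the genome sequence at the summit (strand uniform).  When a
    ``category_mix`` over the four genomic categories is given, peak
    positions are rejection-sampled to realise it against ``genes``.
    Returns (peaks, truth table, modified genome).
    """
    if not 0 <= planting_rate <= 1:
        raise ValueError("planting_rate must be in [0, 1]")
    pwm = pwm or default_dimeric_pwm()
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    seqs = {c: bytearray(genome[c].encode()) for c in chroms}
    weights = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    index = CategoryIndex(genes, cfg) if category_mix is not None else None
    quotas = None
    if category_mix is not None:
        mix = {c: category_mix.get(c, 0.0) for c in CATEGORIES}
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        quotas = {c: int(round(mix[c] * n)) for c in CATEGORIES}
        drift = n - sum(quotas.values())
        quotas[max(mix, key=lambda c: mix[c])] += drift
    positions: list[tuple[str, int]] = []  # (chrom, start)
    cats: list[str] = []
    tries = 0
    while len(positions) < n:
        tries += 1
        if tries > max_tries_factor * n:
            missing = [c for c in CATEGORIES if quotas and quotas[c] > 0]
            raise RuntimeError(
                f"could not place peaks for categories: {missing or 'any'}"
            )
        c = chroms[rng.choice(len(chroms), p=weights)]
        L = len(genome[c])
        if L <= peak_length:
            continue
        start = int(rng.integers(0, L - peak_length))
        summit = start + peak_length // 2
        if index is not None:
            cat = CATEGORIES[index.classify_positions(c, np.array([summit]))[0]]
            if quotas[cat] <= 0:
                continue
            quotas[cat] -= 1
        else:
            cat = ""
        positions.append((c, start))
        cats.append(cat)
    records = []
    peaks = []
    heights = rng.lognormal(mean=height_log_mean, sigma=height_log_sd, size=n)
    for i, ((c, start), cat) in enumerate(zip(positions, cats)):
        summit = start + peak_length // 2
        planted = bool(rng.random() < planting_rate)
        motif_pos = -1
        strand = "."
        if planted:
            inst = sample_motif_instance(pwm, rng)
            if rng.random() < 0.5:
                strand = "+"
            else:
                strand = "-"
                from .genomics import reverse_complement

                inst = reverse_complement(inst)
            motif_pos = summit - len(inst) // 2
            seqs[c][motif_pos : motif_pos + len(inst)] = inst.encode()
        name = f"peak_{i + 1}"
        iv = GenomicInterval(c, start, start + peak_length)
        peaks.append(Peak(iv, summit=summit, height=float(heights[i]), name=name))
        records.append(
            {
                "name": name,
                "chrom": c,
                "start": start,
                "end": start + peak_length,
                "summit": summit,
                "planted": planted,
                "motif_start": motif_pos,
                "motif_strand": strand,
                "category": cat,
            }
        )
    new_genome = {c: seqs[c].decode() for c in chroms}
    return peaks, pd.DataFrame(records), new_genome


def make_ctcf_sites(
    chrom_lengths: Mapping[str, int], n: int, seed: int = 0, site_length: int = 200
) -> list[GenomicInterval]:
    """Random CTCF site intervals, uniform across the genome."""
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        c = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, max(chrom_lengths[c] - site_length, 1)))
        out.append(GenomicInterval(c, start, start + site_length))
    return sorted(out)


def make_conservation_track(
    chrom_lengths: Mapping[str, int],
    baseline_mean: float = 0.1,
    elevated_regions: Sequence[GenomicInterval] = (),
    elevated_mean: float = 0.6,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ScoreTrack, pd.DataFrame]:
    """Beta-distributed per-base scores with elevated segments.

    ``noise_sd`` sets the per-base standard deviation (0 gives exact means).
    Returns the track and a truth table of elevated segments.
    """
    if not (0 <= baseline_mean <= 1 and 0 <= elevated_mean <= 1):
        raise ValueError("means must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arrays = {}

    def draw(mean: float, size: int) -> np.ndarray:
        if noise_sd == 0:
            return np.full(size, mean)
        max_var = mean * (1 - mean)
        var = min(noise_sd**2, 0.95 * max_var) if max_var > 0 else 0.0
        if var <= 0:
            return np.full(size, mean)
        kappa = max_var / var - 1
        a, b = mean * kappa, (1 - mean) * kappa
        return np.clip(rng.beta(a, b, size=size), 0.0, 1.0)

    for c, L in chrom_lengths.items():
        arrays[c] = draw(baseline_mean, L)
    records = []
    for iv in elevated_regions:
        arrays[iv.chrom][iv.start : iv.end] = draw(elevated_mean, iv.length())
        records.append(
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "elevated": True}
        )
    return ScoreTrack(arrays), pd.DataFrame(records)


def make_disease_matrix(
    n_diseases: int = 2033,
    n_terms: int = 500,
    cluster_size: int = 904,
    cluster_term_block: int = 12,
    background_density: float = 0.2,
    seed: int = 0,
) -> tuple[DiseaseFeatureMatrix, pd.DataFrame]:
    """Binary disease x term matrix with one clustered disease set.

    Background terms are Bernoulli(``background_density``); the cluster
    members additionally share a dense block of ``cluster_term_block``
    terms, lifting their mean pairwise similarity above the global mean by
    a margin set in closed form by the block size and density.
    """
    if cluster_size > n_diseases:
        raise ValueError("cluster_size exceeds n_diseases")
    if cluster_term_block > n_terms:
        raise ValueError("cluster_term_block exceeds n_terms")
    rng = np.random.default_rng(seed)
    w = (rng.random((n_diseases, n_terms)) < background_density).astype(float)
    members = rng.choice(n_diseases, size=cluster_size, replace=False)
    if cluster_term_block:
        w[np.ix_(members, np.arange(n_terms - cluster_term_block, n_terms))] = 1.0
    # every disease needs at least one term
    empty = np.flatnonzero(w.sum(axis=1) == 0)
    for i in empty:
        w[i, rng.integers(0, n_terms)] = 1.0
    diseases = [f"D{i + 1:05d}" for i in range(n_diseases)]
    terms = [f"term_{j + 1:04d}" for j in range(n_terms)]
    frame = pd.DataFrame(w, index=diseases, columns=terms)
    member_mask = np.zeros(n_diseases, dtype=bool)
    member_mask[members] = True
    truth = pd.DataFrame({"disease": diseases, "cluster_member": member_mask})
    return DiseaseFeatureMatrix(frame), truth


# ---------------------------------------------------------------------------
# Scenario writer


@dataclass(frozen=True)
class ScenarioParams:
    """Sizes and rates of the default synthetic scenario."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 400_000}
    )
    gc_content: float = 0.41
    n_genes: int = 40
    n_peaks: int = 300
    planting_rate: float = 0.94
    peak_length: int = 200
    n_ctcf: int = 30
    category_mix: Mapping[str, float] | None = None
    baseline_conservation: float = 0.1
    elevated_conservation: float = 0.6
    conservation_noise_sd: float = 0.1
    n_diseases: int = 2033
    n_terms: int = 500
    cluster_size: int = 904
    cluster_term_block: int = 12
    background_density: float = 0.2


def simulate_scenario(
    outdir: str | Path, seed: int = 0, params: ScenarioParams = ScenarioParams()
) -> dict[str, Path]:
    """Generate a complete input set (FASTA/BED/bedGraph/TSV) plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(
        params.chrom_lengths, params.gc_content, child_seed(seed, "genome")
    )
    genes = make_genes(params.chrom_lengths, params.n_genes, child_seed(seed, "genes"))
    pwm = default_dimeric_pwm()
    peaks, peak_truth, genome = plant_peaks(
        genome,
        params.n_peaks,
        pwm=pwm,
        planting_rate=params.planting_rate,
        peak_length=params.peak_length,
        category_mix=params.category_mix,
        genes=genes,
        seed=child_seed(seed, "peaks"),
    )
    ctcf = make_ctcf_sites(
        params.chrom_lengths, params.n_ctcf, child_seed(seed, "ctcf")
    )
    windows = [
        GenomicInterval(p.chrom, p.summit - 50, p.summit + 50) for p in peaks
    ]
    track, cons_truth = make_conservation_track(
        params.chrom_lengths,
        params.baseline_conservation,
        windows,
        params.elevated_conservation,
        params.conservation_noise_sd,
        child_seed(seed, "conservation"),
    )
    matrix, disease_truth = make_disease_matrix(
        params.n_diseases,
        params.n_terms,
        params.cluster_size,
        params.cluster_term_block,
        params.background_density,
        child_seed(seed, "diseases"),
    )
    paths = {
        "genome": outdir / "genome.fa",
        "peaks": outdir / "peaks.bed",
        "genes": outdir / "genes.bed12",
        "ctcf": outdir / "ctcf.bed",
        "conservation": outdir / "conservation.bedGraph",
        "disease_matrix": outdir / "disease_matrix.tsv",
        "peak_truth": outdir / "truth_peaks.tsv",
        "conservation_truth": outdir / "truth_conservation.tsv",
        "disease_truth": outdir / "truth_diseases.tsv",
        "motif": outdir / "planted_motif.meme",
    }
    write_fasta(genome, paths["genome"])
    write_bed(peaks, paths["peaks"])
    write_genes_bed12(genes, paths["genes"])
    with open(paths["ctcf"], "w") as fh:
        for iv in ctcf:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tctcf\n")
    write_bedgraph(track, paths["conservation"])
    matrix.to_tsv(paths["disease_matrix"])
    peak_truth.to_csv(paths["peak_truth"], sep="\t", index=False)
    cons_truth.to_csv(paths["conservation_truth"], sep="\t", index=False)
    disease_truth.to_csv(paths["disease_truth"], sep="\t", index=False)
    from .motif import write_meme

    write_meme({pwm.name: pwm}, paths["motif"])
    return paths


def write_genes_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Serialize gene models as BED12."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = sorted(g.exons, key=lambda e: e.start)
            sizes = ",".join(str(e.length()) for e in exons) + ","
            starts = ",".join(str(e.start - iv.start) for e in exons) + ","
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        g.gene_id,
                        "0",
                        iv.strand,
                        str(iv.start),
                        str(iv.end),
                        "0",
                        str(len(exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
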