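"""Genomic-category classification of peaks, target-gene mapping and the
CTCF-bounded candidate-enhancer search.

A peak summit falls into exactly one of four categories relative to a gene
set: TSS_flanking (5 kb upstream of the TSS, first exon or first intron),
intragenic (remaining introns/exons), near (5-25 kb upstream or up to 25 kb
downstream of the gene end), or intergenic (everything else).  When several
genes apply, TSS_flanking beats intragenic beats near.  Category definitions
are strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomics import GeneModel, GenomicInterval, Peak, distance, lies_between

__all__ = [
    "AnnotationConfig",
    "DomainSearchConfig",
    "CATEGORIES",
    "CategoryIndex",
    "classify_peak",
    "classify_peaks",
    "category_enrichment",
    "map_to_ptg",
    "candidate_elements",
]

CATEGORIES = ("TSS_flanking", "intragenic", "near", "intergenic")


@dataclass(frozen=True)
class AnnotationConfig:
    """Window sizes (bp) for the four-way genomic classification."""

    tss_upstream: int = 5_000
    near_upstream_max: int = 25_000
    near_downstream_max: int = 25_000
    ptg_window: int = 25_000

    def __post_init__(self) -> None:
        for f in (
            self.tss_upstream,
            self.near_upstream_max,
            self.near_downstream_max,
            self.ptg_window,
        ):
            if f <= 0:
                raise ValueError("all windows must be positive")
        if self.near_upstream_max <= self.tss_upstream:
            raise ValueError("near_upstream_max must exceed tss_upstream")


@dataclass(frozen=True)
class DomainSearchConfig:
    """Search radius for CTCF-bounded candidate regulatory elements."""

    max_distance: int = 300_000

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


def _gene_category_regions(
    gene: GeneModel, cfg: AnnotationConfig
) -> dict[str, list[tuple[int, int]]]:
    """Half-open position ranges contributed by one gene per category."""
    iv = gene.interval
    out: dict[str, list[tuple[int, int]]] = {
        "TSS_flanking": [],
        "intragenic": [],
        "near": [],
    }
    if gene.strand == "+":
        up5 = (max(0, iv.start - cfg.tss_upstream), iv.start)
        near_up = (max(0, iv.start - cfg.near_upstream_max), up5[0])
        near_down = (iv.end, iv.end + cfg.near_downstream_max)
    else:
        up5 = (iv.end, iv.end + cfg.tss_upstream)
        near_up = (up5[1], up5[1] + cfg.near_upstream_max - cfg.tss_upstream)
        near_down = (max(0, iv.start - cfg.near_downstream_max), iv.start)
    out["TSS_flanking"].append(up5)
    fe = gene.first_exon
    out["TSS_flanking"].append((fe.start, fe.end))
    fi = gene.first_intron
    if fi is not None:
        out["TSS_flanking"].append((fi.start, fi.end))
    # whole gene body; TSS_flanking takes priority inside first exon/intron
    out["intragenic"].append((iv.start, iv.end))
    for rng in (near_up, near_down):
        if rng[1] > rng[0]:
            out["near"].append(rng)
    return out


def _merge(ranges: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not ranges:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ranges = sorted(ranges)
    starts, ends = [ranges[0][0]], [ranges[0][1]]
    for s, e in ranges[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


class CategoryIndex:
    """Merged per-chromosome category regions for batch classification."""

    def __init__(self, genes: Sequence[GeneModel], cfg: AnnotationConfig):
        self.cfg = cfg
        raw: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for g in genes:
            per = _gene_category_regions(g, cfg)
            chrom = raw.setdefault(g.interval.chrom, {c: [] for c in CATEGORIES[:3]})
            for cat in CATEGORIES[:3]:
                chrom[cat].extend(per[cat])
        self._index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {
            chrom: {cat: _merge(ranges[cat]) for cat in CATEGORIES[:3]}
            for chrom, ranges in raw.items()
        }

    def classify_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Category index (into CATEGORIES) per position, priority-ordered."""
        positions = np.asarray(positions)
        out = np.full(positions.shape, 3, dtype=np.int8)  # intergenic
        per_chrom = self._index.get(chrom)
        if per_chrom is None:
            return out
        unassigned = np.ones(positions.shape, dtype=bool)
        for ci, cat in enumerate(CATEGORIES[:3]):
            starts, ends = per_chrom[cat]
            if starts.size == 0:
                continue
            idx = np.searchsorted(starts, positions, side="right") - 1
            inside = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
            hit = inside & unassigned
            out[hit] = ci
            unassigned &= ~hit
        return out


def classify_peak(
    peak: Peak, genes: Sequence[GeneModel], cfg: AnnotationConfig = AnnotationConfig()
) -> str:
    """Classify a single peak summit (see module docstring for the rule)."""
    idx = CategoryIndex(genes, cfg)
    ci = idx.classify_positions(peak.chrom, np.array([peak.summit]))[0]
    return CATEGORIES[ci]


def classify_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
    index: CategoryIndex | None = None,
) -> list[str]:
    index = index or CategoryIndex(genes, cfg)
    out = []
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(i)
    cats = np.full(len(peaks), 3, dtype=np.int8)
    for chrom, idxs in by_chrom.items():
        pos = np.array([peaks[i].summit for i in idxs])
        cats[idxs] = index.classify_positions(chrom, pos)
    return [CATEGORIES[c] for c in cats]


def category_enrichment(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
    n_perm: int = 999,
    seed: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Permutation test of category counts against random relocation.

    The null relocates each peak to a uniform position on its own chromosome
    (length preserved) and re-classifies; the empirical p per category is
    (1 + #null >= observed) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    index = CategoryIndex(genes, cfg)
    if chrom_lengths is None:
        chrom_lengths = _infer_chrom_lengths(peaks, genes)
    observed = classify_peaks(peaks, genes, cfg, index=index)
    obs_counts = np.array([observed.count(c) for c in CATEGORIES])
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    null_counts = np.zeros((n_perm, len(CATEGORIES)), dtype=np.int64)
    for chrom, plist in by_chrom.items():
        L = chrom_lengths[chrom]
        lens = np.array([p.interval.length() for p in plist])
        offs = np.array([p.summit - p.interval.start for p in plist])
        # (n_perm, n_peaks) random starts; summit offset preserved
        max_start = np.maximum(L - lens + 1, 1)
        starts = (rng.random((n_perm, len(plist))) * max_start).astype(np.int64)
        summits = np.minimum(starts + offs, L - 1)
        cats = index.classify_positions(chrom, summits.ravel()).reshape(summits.shape)
        for ci in range(len(CATEGORIES)):
            null_counts[:, ci] += (cats == ci).sum(axis=1)
    rows = []
    for ci, cat in enumerate(CATEGORIES):
        ge = int((null_counts[:, ci] >= obs_counts[ci]).sum())
        rows.append(
            {
                "category": cat,
                "observed": int(obs_counts[ci]),
                "expected_mean": float(null_counts[:, ci].mean()),
                "p_empirical": (1 + ge) / (1 + n_perm),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def _infer_chrom_lengths(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for p in peaks:
        lengths[p.chrom] = max(lengths.get(p.chrom, 0), p.interval.end)
    for g in genes:
        lengths[g.interval.chrom] = max(
            lengths.get(g.interval.chrom, 0), g.interval.end
        )
    return lengths


def map_to_ptg(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
) -> dict[str, list[Peak]]:
    """Potential-target-gene mapping: gene -> peaks within ``ptg_window``.

    A gene qualifies when at least one peak interval lies within the window
    of the gene interval (overlap counts); a peak may map to several genes.
    """
    out: dict[str, list[Peak]] = {}
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for g in genes:
        near = [
            p
            for p in by_chrom.get(g.interval.chrom, [])
            if distance(p.interval, g.interval) <= cfg.ptg_window
        ]
        if near:
            out[g.gene_id] = near
    return out


def candidate_elements(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    ctcf_sites: Sequence[GenomicInterval],
    dcfg: DomainSearchConfig = DomainSearchConfig(),
) -> list[tuple[GeneModel, Peak]]:
    """(gene, peak) pairs within range and not separated by a CTCF site.

    A pair is retained iff the peak lies within ``max_distance`` of the gene
    and no CTCF site falls strictly inside the gap between them; a CTCF site
    overlapping the peak or the gene does not block (an insulator must
    separate, not touch), and overlapping peak/gene pairs are always kept.
    """
    out = []
    ctcf_by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in ctcf_sites:
        ctcf_by_chrom.setdefault(c.chrom, []).append(c)
    for g in genes:
        sites = ctcf_by_chrom.get(g.interval.chrom, [])
        for p in peaks:
            d = distance(p.interval, g.interval)
            if d > dcfg.max_distance:
                continue
            if d == 0:
                out.append((g, p))
                continue
            if not any(lies_between(c, p.interval, g.interval) for c in sites):
                out.append((g, p))
    return out
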