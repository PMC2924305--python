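"""Genomic interval model, coordinate conventions and format I/O.

All internal coordinates are 0-based half-open ``[start, end)``.  BED input is
taken as-is; GTF/GFF3 and browser-printed coordinates (1-based inclusive) are
converted at the I/O boundary.  Every downstream stage of the pipeline flows
through the types defined here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "ScoreTrack",
    "Genome",
    "ParseError",
    "ValidationError",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "read_bedgraph",
    "read_wiggle",
    "reverse_complement",
]

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """A malformed record in an input file (reports the line number)."""


class ValidationError(ValueError):
    """A record that parses but violates a domain invariant."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")

    @classmethod
    def from_one_based(
        cls, chrom: str, start: int, end: int, strand: str = "."
    ) -> "GenomicInterval":
        """Build from browser-style 1-based inclusive coordinates.

        ``(s, e)`` maps to internal ``[s-1, e)`` so the length equals
        ``e - s + 1`` of the browser form.
        """
        return cls(chrom, start - 1, end, strand)

    @classmethod
    def from_breakpoints(
        cls, chrom: str, left: int, right: int, strand: str = "."
    ) -> "GenomicInterval":
        """Build from a pair of boundary coordinates delimiting a segment.

        Array-CGH breakpoints name the edges of the affected segment, not
        inclusive probe positions; the segment is ``(left, right]`` and its
        length is ``right - left``.
        """
        return cls(chrom, left, right, strand)

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def interval_length(iv: GenomicInterval) -> int:
    """Length of an interval in bp (``end - start``)."""
    return iv.length()


def distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between nearest edges; 0 if overlapping, inf across chroms."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def lies_between(x: GenomicInterval, a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``x`` lies strictly within the gap separating ``a`` and ``b``."""
    if x.chrom != a.chrom or x.chrom != b.chrom:
        return False
    if distance(a, b) == 0:
        return False
    left, right = (a, b) if a.end <= b.start else (b, a)
    return x.start >= left.end and x.end <= right.start


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq binding-site interval with its summit and read height."""

    interval: GenomicInterval
    summit: int
    height: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside {self.interval.start}-{self.interval.end}"
            )
        if self.height < 0:
            raise ValidationError("height must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with its exon structure.

    The TSS is ``interval.start`` on the + strand and ``interval.end - 1`` on
    the - strand; "first exon/intron" are in transcription order.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id} must be stranded")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id} has no exons")
        exs = sorted(self.exons, key=lambda e: e.start)
        for prev, cur in zip(exs, exs[1:]):
            if cur.start < prev.end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
        for e in exs:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside gene")
        # store in transcription order
        if self.interval.strand == "-":
            exs = exs[::-1]
        object.__setattr__(self, "exons", tuple(exs))

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end (last transcribed base)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons[0]

    @property
    def first_intron(self) -> GenomicInterval | None:
        """Interval between the first and second exon, or None if single-exon."""
        if len(self.exons) < 2:
            return None
        a, b = self.exons[0], self.exons[1]
        if self.strand == "+":
            return GenomicInterval(self.interval.chrom, a.end, b.start, "+")
        return GenomicInterval(self.interval.chrom, b.end, a.start, "-")


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str | Path) -> list[Peak]:
    """Read a 3-6+ column BED file of peaks.

    Column 5 (score) is taken as peak height; an optional integer column 7 is
    the summit offset relative to ``start`` (MACS convention).  Peaks without
    a summit default to the interval midpoint (floor).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            try:
                height = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            if len(fields) > 6:
                try:
                    summit = start + int(fields[6])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
            else:
                summit = start + (end - start) // 2
            iv = GenomicInterval(chrom, start, end, strand)
            peaks.append(Peak(iv, summit=summit, height=height, name=name))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path, summit_column: bool = True) -> None:
    """Write peaks as BED6 plus an optional summit-offset column."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), p.name,
                    format(p.height, "g"), iv.strand]
            if summit_column:
                cols.append(str(p.summit - iv.start))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene models (BED12 and GTF/GFF3)


def _gene_from_bed12(fields: Sequence[str], lineno: int, path) -> GeneModel:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3]
    strand = fields[5]
    if strand not in ("+", "-"):
        raise ValidationError(f"{path}:{lineno}: gene {name} is unstranded")
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ParseError(f"{path}:{lineno}: block count mismatch")
    exons = tuple(
        GenomicInterval(chrom, start + s, start + s + sz, strand)
        for s, sz in zip(starts, sizes)
    )
    return GeneModel(name, GenomicInterval(chrom, start, end, strand), exons)


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            genes.append(_gene_from_bed12(fields, lineno, path))
    return genes


def _read_gtf(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        gid = (
            feat.attributes.get("gene_id")
            or feat.attributes.get("Parent")
            or feat.attributes.get("ID")
        )
        if not gid:
            raise ValidationError(f"{path}: exon without gene_id/Parent")
        by_gene.setdefault(gid[0], []).append(feat)
    genes = []
    for gid, feats in by_gene.items():
        strand = feats[0].strand
        if strand not in ("+", "-"):
            raise ValidationError(f"{path}: gene {gid} is unstranded")
        chrom = feats[0].seqid
        # GTF is 1-based inclusive
        exons = tuple(
            GenomicInterval(chrom, f.start - 1, f.end, strand) for f in feats
        )
        start = min(e.start for e in exons)
        end = max(e.end for e in exons)
        genes.append(GeneModel(gid, GenomicInterval(chrom, start, end, strand), exons))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED12 or GTF/GFF3 (exon features).

    The dialect is inferred from the file extension unless ``fmt`` is one of
    ``{"bed12", "gtf"}``.  Exons are ordered in transcription direction and
    the TSS derived per strand.
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "gtf" if suffix in (".gtf", ".gff", ".gff3") else "bed12"
    if fmt == "gtf":
        return _read_gtf(path)
    return _read_bed12(path)


# ---------------------------------------------------------------------------
# Genome sequence access


class Genome:
    """Nucleotide access over an indexed FASTA or an in-memory mapping."""

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, (str, Path)):
            self._fasta = Fasta(str(source), sequence_always_upper=True)
            self._mem = None
        else:
            self._fasta = None
            self._mem = {k: v.upper() for k, v in source.items()}

    def chromosomes(self) -> list[str]:
        if self._mem is not None:
            return list(self._mem)
        return list(self._fasta.keys())

    def chrom_length(self, chrom: str) -> int:
        if self._mem is not None:
            return len(self._mem[chrom])
        return len(self._fasta[chrom])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length(c) for c in self.chromosomes()}

    def fetch(self, iv: GenomicInterval) -> str:
        """Sequence of ``iv``, reverse-complemented for the - strand."""
        if self._mem is not None:
            if iv.chrom not in self._mem:
                raise KeyError(f"chromosome {iv.chrom} not in genome")
            L = len(self._mem[iv.chrom])
        else:
            if iv.chrom not in self._fasta:
                raise KeyError(f"chromosome {iv.chrom} not in genome")
            L = len(self._fasta[iv.chrom])
        if iv.end > L:
            raise IndexError(
                f"{iv.chrom}:[{iv.start},{iv.end}) beyond chromosome end {L}"
            )
        if self._mem is not None:
            seq = self._mem[iv.chrom][iv.start : iv.end]
        else:
            seq = str(self._fasta[iv.chrom][iv.start : iv.end])
        seq = seq.upper()
        return reverse_complement(seq) if iv.strand == "-" else seq


def fetch_sequence(genome: Genome, iv: GenomicInterval) -> str:
    return genome.fetch(iv)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Conservation score tracks


class ScoreTrack:
    """Per-base scores in [0, 1] with an explicit missing-data mask.

    Missing positions are stored as NaN; ``mask(chrom)`` exposes presence.
    """

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self._arrays = {}
        for chrom, arr in arrays.items():
            a = np.asarray(arr, dtype=np.float64)
            present = ~np.isnan(a)
            if present.any() and ((a[present] < 0) | (a[present] > 1)).any():
                raise ValidationError(f"{chrom}: scores outside [0, 1]")
            self._arrays[chrom] = a

    def chromosomes(self) -> list[str]:
        return list(self._arrays)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._arrays

    def values(self, chrom: str) -> np.ndarray:
        return self._arrays[chrom]

    def mask(self, chrom: str) -> np.ndarray:
        return ~np.isnan(self._arrays[chrom])

    def region(self, iv: GenomicInterval) -> np.ndarray:
        """Scores over ``iv`` (NaN outside coverage), padded past array end."""
        if iv.chrom not in self._arrays:
            raise KeyError(f"chromosome {iv.chrom} not in track")
        arr = self._arrays[iv.chrom]
        out = np.full(iv.length(), np.nan)
        hi = min(iv.end, arr.size)
        if hi > iv.start:
            out[: hi - iv.start] = arr[iv.start : hi]
        return out


def read_bedgraph(path: str | Path, chrom_lengths: Mapping[str, int] | None = None) -> ScoreTrack:
    """Read a bedGraph (0-based half-open) into a ScoreTrack."""
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if e <= s:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            records.setdefault(chrom, []).append((s, e, v))
    return _records_to_track(records, chrom_lengths)


def read_wiggle(path: str | Path, chrom_lengths: Mapping[str, int] | None = None) -> ScoreTrack:
    """Read a fixed-step wiggle (1-based starts) into a ScoreTrack."""
    records: dict[str, list[tuple[int, int, float]]] = {}
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if chrom is None:
                raise ParseError(f"{path}:{lineno}: data before fixedStep header")
            try:
                v = float(line)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.setdefault(chrom, []).append((pos, pos + span, v))
            pos += step
    return _records_to_track(records, chrom_lengths)


def _records_to_track(records, chrom_lengths) -> ScoreTrack:
    arrays = {}
    for chrom, recs in records.items():
        size = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else max(e for _, e, _ in recs)
        )
        arr = np.full(size, np.nan)
        for s, e, v in recs:
            arr[s:e] = v
        arrays[chrom] = arr
    return ScoreTrack(arrays)


def write_bedgraph(track: ScoreTrack, path: str | Path) -> None:
    """Write a ScoreTrack as bedGraph, run-length merging equal scores."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            arr = track.values(chrom)
            present = ~np.isnan(arr)
            if not present.any():
                continue
            idx = np.flatnonzero(present)
            # emit runs of equal value over contiguous covered positions
            start = idx[0]
            prev = idx[0]
            val = arr[start]
            for i in idx[1:]:
                if i != prev + 1 or arr[i] != val:
                    fh.write(f"{chrom}\t{start}\t{prev + 1}\t{val:.6g}\n")
                    start, val = i, arr[i]
                prev = i
            fh.write(f"{chrom}\t{start}\t{prev + 1}\t{val:.6g}\n")
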