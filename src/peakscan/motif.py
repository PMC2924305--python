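"""Dimeric position-weight-matrix construction and scanning.

The motif model is the p53-family architecture: two half-site probability
matrices separated by a configurable spacer (0 by default, i.e. a contiguous
site scored as two adjacent half-sites).  Placements are scored as summed
log2 odds against a background nucleotide distribution, on both strands and
over all allowed spacers; ambiguous bases (N) contribute 0.  A scan threshold
is calibrated by maximising the f-measure against a background sequence set,
and the false-discovery rate at a threshold is estimated from the background
hit rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DimericPWM",
    "MotifHit",
    "ScanCalibration",
    "ScanResult",
    "build_pwm",
    "scan_sequence",
    "batch_best_scores",
    "batch_best_hits",
    "calibrate_threshold",
    "estimate_fdr",
    "roc_auc",
    "compare_scanners",
    "read_meme",
    "write_meme",
]

#: log2-odds assigned to a zero-probability cell (finite floor)
SCORE_FLOOR = -10.0

_BASES = "ACGT"
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# complement permutation for encoded bases (N -> N)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_batch(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into an N-padded matrix plus a length vector."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    mat = np.full((len(seqs), int(lengths.max(initial=0))), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = encode(s)
    return mat, lengths


def _validate_matrix(m: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if m.size == 0:
        return m.reshape(0, 4)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError(f"{what} must have shape (w, 4)")
    if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"{what} columns must be probabilities summing to 1")
    return m


@dataclass(frozen=True)
class DimericPWM:
    """Two half-site probability matrices with a spacer range.

    ``half_a`` and ``half_b`` are (width, 4) row-per-position matrices over
    A,C,G,T.  Degenerate single-block motifs have an empty ``half_b`` and
    spacer range (0, 0).
    """

    half_a: np.ndarray
    half_b: np.ndarray
    spacer_range: tuple[int, int] = (0, 0)
    background: np.ndarray = None  # type: ignore[assignment]
    pseudocount: float = 0.0
    name: str = "motif"

    def __post_init__(self) -> None:
        object.__setattr__(self, "half_a", _validate_matrix(self.half_a, "half_a"))
        object.__setattr__(self, "half_b", _validate_matrix(self.half_b, "half_b"))
        bg = self.background
        bg = np.full(4, 0.25) if bg is None else np.asarray(bg, dtype=np.float64)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be a 4-vector summing to 1")
        object.__setattr__(self, "background", bg)
        lo, hi = self.spacer_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid spacer range")
        if self.half_a.shape[0] == 0:
            raise ValueError("half_a must be non-empty")

    @property
    def width_a(self) -> int:
        return self.half_a.shape[0]

    @property
    def width_b(self) -> int:
        return self.half_b.shape[0]

    @property
    def width(self) -> int:
        """Total informative width (both half-sites, excluding spacer)."""
        return self.width_a + self.width_b

    @property
    def min_span(self) -> int:
        return self.width_a + self.spacer_range[0] + self.width_b

    @property
    def max_span(self) -> int:
        return self.width_a + self.spacer_range[1] + self.width_b

    def span(self, spacer: int) -> int:
        return self.width_a + spacer + self.width_b

    def probability_matrix(self) -> np.ndarray:
        """Concatenated (width, 4) matrix of both half-sites."""
        return np.vstack([self.half_a, self.half_b])

    def log_odds(self, spacer: int = 0) -> np.ndarray:
        """(span, 5) log2-odds matrix for a given spacer; N column is 0.

        Zero-probability cells are floored at :data:`SCORE_FLOOR`; spacer
        positions contribute 0 for any base.
        """
        span = self.span(spacer)
        lo = np.zeros((span, 5))
        for offset, half in ((0, self.half_a), (self.width_a + spacer, self.half_b)):
            if half.shape[0] == 0:
                continue
            with np.errstate(divide="ignore"):
                vals = np.log2(half / self.background)
            vals[half == 0] = SCORE_FLOOR
            lo[offset : offset + half.shape[0], :4] = vals
        return lo

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probability_matrix().argmax(axis=1))

    def information_content(self) -> float:
        """Total relative-entropy information (bits) of both half-sites."""
        p = self.probability_matrix()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = p * np.log2(p / self.background)
        return float(np.nansum(terms))

    def max_score(self) -> float:
        """Best attainable log-odds score (consensus at the widest columns)."""
        lo = self.log_odds(self.spacer_range[0])
        return float(lo[:, :4].max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """A scored motif placement within a scanned sequence."""

    position: int
    strand: str
    spacer: int
    score: float


@dataclass(frozen=True)
class ScanResult:
    best: MotifHit | None
    hits: tuple[MotifHit, ...]
    too_short: bool = False


@dataclass(frozen=True)
class ScanCalibration:
    threshold: float
    f_measure: float
    estimated_fdr: float


def build_pwm(
    instances: Sequence[str],
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    split: int | None = None,
    spacer_range: tuple[int, int] = (0, 0),
    name: str = "motif",
) -> DimericPWM:
    """Build a PWM from aligned equal-length instances.

    Per column, frequency of base b = (count_b + pseudocount) /
    (n + 4*pseudocount).  ``split`` cuts the alignment into the two
    half-sites; without it the motif is a single block.
    """
    if not instances:
        raise ValueError("need at least one instance")
    w = len(instances[0])
    if any(len(s) != w for s in instances):
        raise ValueError("instances must be equal length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    enc, _ = encode_batch(list(instances))
    counts = np.zeros((w, 4))
    for b in range(4):
        counts[:, b] = (enc == b).sum(axis=0)
    denom = counts.sum(axis=1, keepdims=True) + 4 * pseudocount
    probs = (counts + pseudocount) / denom
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if split is None:
        return DimericPWM(probs, np.empty((0, 4)), (0, 0), bg, pseudocount, name)
    if not (0 < split < w):
        raise ValueError("split must be interior to the alignment")
    return DimericPWM(
        probs[:split], probs[split:], spacer_range, bg, pseudocount, name
    )


# ---------------------------------------------------------------------------
# Scanning


def _window_scores(lo: np.ndarray, mat: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Scores of every placement of a (span, 5) log-odds matrix.

    Returns (n, P) with -inf at placements extending past each sequence end.
    """
    n, L = mat.shape
    span = lo.shape[0]
    P = L - span + 1
    if P < 1:
        return np.full((n, 0), -np.inf)
    scores = np.zeros((n, P))
    for j in range(span):
        scores += lo[j][mat[:, j : j + P]]
    invalid = np.arange(P)[None, :] > (lengths - span)[:, None]
    scores[invalid] = -np.inf
    return scores


def _strand_spacer_scores(
    pwm: DimericPWM, mat: np.ndarray, lengths: np.ndarray
) -> Iterable[tuple[int, str, np.ndarray]]:
    for spacer in range(pwm.spacer_range[0], pwm.spacer_range[1] + 1):
        lo = pwm.log_odds(spacer)
        yield spacer, "+", _window_scores(lo, mat, lengths)
        lo_rc = lo[::-1][:, _COMP]
        yield spacer, "-", _window_scores(lo_rc, mat, lengths)


def best_scores_encoded(
    pwm: DimericPWM, mat: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """Best score per pre-encoded sequence (see :func:`encode_batch`)."""
    best = np.full(mat.shape[0], -np.inf)
    for _, _, scores in _strand_spacer_scores(pwm, mat, lengths):
        if scores.shape[1]:
            np.maximum(best, scores.max(axis=1), out=best)
    return best


def batch_best_scores(pwm: DimericPWM, seqs: Sequence[str]) -> np.ndarray:
    """Best log-odds score per sequence (max over positions, strands, spacers).

    Sequences shorter than the minimal motif span score -inf.
    """
    if len(seqs) == 0:
        return np.empty(0)
    mat, lengths = encode_batch(seqs)
    return best_scores_encoded(pwm, mat, lengths)


def batch_best_hits(
    pwm: DimericPWM, seqs: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best hit per sequence: (scores, positions, strands(+1/-1), spacers)."""
    mat, lengths = encode_batch(seqs)
    n = len(seqs)
    best = np.full(n, -np.inf)
    pos = np.zeros(n, dtype=np.int64)
    strand = np.ones(n, dtype=np.int8)
    spc = np.zeros(n, dtype=np.int64)
    for spacer, st, scores in _strand_spacer_scores(pwm, mat, lengths):
        if not scores.shape[1]:
            continue
        cand_pos = scores.argmax(axis=1)
        cand = scores[np.arange(n), cand_pos]
        better = cand > best
        best[better] = cand[better]
        pos[better] = cand_pos[better]
        strand[better] = 1 if st == "+" else -1
        spc[better] = spacer
    return best, pos, strand, spc


def scan_sequence(
    pwm: DimericPWM, seq: str, threshold: float | None = None
) -> ScanResult:
    """Scan one sequence: best hit plus all hits on both strands/spacers.

    With a ``threshold``, only placements scoring at or above it are listed;
    otherwise every placement is returned.  Sequences shorter than the
    minimal span yield an empty result flagged ``too_short``.
    """
    if len(seq) < pwm.min_span:
        return ScanResult(None, (), too_short=True)
    mat, lengths = encode_batch([seq])
    hits: list[MotifHit] = []
    for spacer, st, scores in _strand_spacer_scores(pwm, mat, lengths):
        row = scores[0]
        for p in np.flatnonzero(np.isfinite(row)):
            s = float(row[p])
            if threshold is None or s >= threshold:
                hits.append(MotifHit(int(p), st, spacer, s))
    hits.sort(key=lambda h: (-h.score, h.position, h.strand, h.spacer))
    best = hits[0] if hits else None
    if best is None and threshold is not None:
        # best placement even if sub-threshold
        allhits = scan_sequence(pwm, seq, threshold=None)
        best = allhits.best
        return ScanResult(best, (), too_short=False)
    return ScanResult(best, tuple(hits), too_short=False)


# ---------------------------------------------------------------------------
# Threshold calibration, FDR, ROC


def calibrate_threshold(
    pos_best_scores: Sequence[float], bg_best_scores: Sequence[float]
) -> ScanCalibration:
    """Pick the score threshold maximising the f-measure.

    Candidate thresholds are the union of observed scores; at threshold t,
    TP = #pos >= t, FP = #bg >= t, FN = #pos < t.  Ties resolve to the
    smallest maximising threshold (recall-favouring).
    """
    pos = np.asarray(pos_best_scores, dtype=float)
    bg = np.asarray(bg_best_scores, dtype=float)
    if pos.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    cand = np.unique(np.concatenate([pos, bg]))
    if cand.size == 1:
        warnings.warn("all scores identical: degenerate separation")
        t = float(cand[0])
        return ScanCalibration(t, _f_measure_at(t, pos, bg), estimate_fdr(t, pos, bg))
    pos_sorted = np.sort(pos)
    bg_sorted = np.sort(bg)
    tp = pos.size - np.searchsorted(pos_sorted, cand, side="left")
    fp = bg.size - np.searchsorted(bg_sorted, cand, side="left")
    fn = pos.size - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    best_idx = int(np.argmax(f))  # argmax takes first (smallest t) on ties
    t = float(cand[best_idx])
    return ScanCalibration(t, float(f[best_idx]), estimate_fdr(t, pos, bg))


def _f_measure_at(t: float, pos: np.ndarray, bg: np.ndarray) -> float:
    tp = float((pos >= t).sum())
    fp = float((bg >= t).sum())
    fn = float((pos < t).sum())
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def estimate_fdr(
    threshold: float,
    pos_best_scores: Sequence[float],
    bg_best_scores: Sequence[float],
) -> float:
    """FDR estimate: background call rate over positive call rate, in [0, 1].

    Returns 1 when the threshold admits no positive calls.
    """
    pos = np.asarray(pos_best_scores, dtype=float)
    bg = np.asarray(bg_best_scores, dtype=float)
    pos_rate = (pos >= threshold).mean() if pos.size else 0.0
    bg_rate = (bg >= threshold).mean() if bg.size else 0.0
    if pos_rate == 0:
        return 1.0
    return float(min(1.0, bg_rate / pos_rate))


def roc_auc(
    pos_best_scores: Sequence[float], bg_best_scores: Sequence[float]
) -> float:
    """Probability a random positive outscores a random background (ties 1/2)."""
    pos = np.asarray(pos_best_scores, dtype=float)
    bg = np.asarray(bg_best_scores, dtype=float)
    if pos.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, bg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * bg.size))


def compare_scanners(
    scanners: Sequence[tuple[str, Callable[[str], float]]],
    pos_seqs: Sequence[str],
    bg_seqs: Sequence[str],
) -> pd.DataFrame:
    """Sensitivity/specificity per scanner at its own calibrated threshold.

    Each scanner is (name, function mapping a sequence to its best score).
    """
    if not scanners:
        raise ValueError("need at least one scanner")
    rows = []
    for name, fn in scanners:
        pos = np.array([fn(s) for s in pos_seqs], dtype=float)
        bg = np.array([fn(s) for s in bg_seqs], dtype=float)
        cal = calibrate_threshold(pos, bg)
        rows.append(
            {
                "scanner": name,
                "threshold": cal.threshold,
                "f_measure": cal.f_measure,
                "sensitivity": float((pos >= cal.threshold).mean()),
                "specificity": float(1.0 - (bg >= cal.threshold).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("scanner")


# ---------------------------------------------------------------------------
# MEME minimal format I/O (spacer/split metadata in a JSON sidecar)


def write_meme(
    pwms: Mapping[str, DimericPWM] | Sequence[DimericPWM],
    path: str | Path,
    sidecar: str | Path | None = None,
) -> None:
    """Write motifs in MEME minimal format.

    The letter-probability matrix is the concatenation of both half-sites;
    the dimeric split and spacer range go into a JSON sidecar (defaults to
    ``<path>.dimer.json``).
    """
    if not isinstance(pwms, Mapping):
        pwms = {p.name: p for p in pwms}
    first = next(iter(pwms.values()))
    bg = first.background
    meta = {}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg)
        )
        for name, pwm in pwms.items():
            m = pwm.probability_matrix()
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.shape[0]} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in m:
                fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*row))
            fh.write("\n")
            meta[name] = {
                "split": pwm.width_a if pwm.width_b else None,
                "spacer_min": pwm.spacer_range[0],
                "spacer_max": pwm.spacer_range[1],
            }
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".dimer.json")
    sidecar.write_text(json.dumps(meta, indent=1))


def read_meme(
    path: str | Path, sidecar: str | Path | None = None
) -> dict[str, DimericPWM]:
    """Read MEME minimal motifs (via biopython), restoring dimeric metadata."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    bg_map = getattr(record, "background", None) or {}
    bg = np.array([bg_map.get(b, 0.25) for b in _BASES], dtype=float)
    bg = bg / bg.sum()
    meta = {}
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".dimer.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    out: dict[str, DimericPWM] = {}
    for m in record:
        counts = np.array([list(m.counts[b]) for b in _BASES], dtype=float).T
        probs = counts / counts.sum(axis=1, keepdims=True)
        name = m.name
        info = meta.get(name, {})
        split = info.get("split")
        spacer = (info.get("spacer_min", 0), info.get("spacer_max", 0))
        if split:
            pwm = DimericPWM(
                probs[:split], probs[split:], spacer, bg, name=name
            )
        else:
            pwm = DimericPWM(probs, np.empty((0, 4)), (0, 0), bg, name=name)
        out[name] = pwm
    return out
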