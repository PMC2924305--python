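"""De novo motif significance pipeline.

Peak sequences are split into a training set (for motif discovery) and an
evaluation set; each candidate motif is scored against the evaluation set and
two backgrounds — random genomic regions matching the peak distribution, and
first-order Markov sequences matching the peak dinucleotide composition.
Enrichment is tested with the hypergeometric upper tail per background
(conservatively taking the larger p), Benjamini-Hochberg corrected across
candidates, and filtered at >1.5-fold enrichment against BOTH backgrounds.
The best surviving motif is chosen by ROC AUC.

The built-in discoverer is an explicit stand-in for external motif finders:
over-represented exact words seed PWMs that are refined by iterative
best-site realignment.  Externally supplied PWMs (MEME format) are
first-class candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from .genomics import Genome, GenomicInterval, Peak, reverse_complement
from .motif import (
    DimericPWM,
    batch_best_hits,
    batch_best_scores,
    best_scores_encoded,
    build_pwm,
    calibrate_threshold,
    encode_batch,
    roc_auc,
)

__all__ = [
    "MotifCandidate",
    "EnrichmentResult",
    "NoSignificantMotifError",
    "split_train_eval",
    "sample_genomic_background",
    "markov_background",
    "motif_enrichment",
    "evaluate_candidates",
    "bh_correct",
    "select_best_motif",
    "discover_motifs",
    "binomial_overrepresentation",
]

SIGNIFICANCE_ALPHA = 0.001
FOLD_CUTOFF = 1.5


class NoSignificantMotifError(RuntimeError):
    """No candidate survived the dual-background significance filter."""


@dataclass(frozen=True)
class MotifCandidate:
    pwm: DimericPWM
    source: str = "builtin"

    @property
    def width(self) -> int:
        return self.pwm.width


@dataclass(frozen=True)
class EnrichmentResult:
    p_hyper: float
    q_bh: float
    fold_genomic: float
    fold_markov: float
    significant: bool
    auc: float
    threshold: float


# ---------------------------------------------------------------------------
# Sequence sets


def split_train_eval(
    peaks: Sequence[Peak],
    genome: Genome,
    train_fraction: float = 0.2,
    window: int = 200,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Random disjoint, exhaustive split into training and evaluation sets.

    Sequences are ``window``-bp intervals centred on each peak summit;
    training size is floor(train_fraction * n).  Windows running past a
    chromosome end are clipped with a warning.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    if window % 2:
        raise ValueError("window must be even")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(peaks))
    n_train = math.floor(train_fraction * len(peaks))
    seqs = [_summit_sequence(genome, p, window) for p in peaks]
    train = [seqs[i] for i in order[:n_train]]
    evals = [seqs[i] for i in order[n_train:]]
    return train, evals


def _summit_sequence(genome: Genome, peak: Peak, window: int) -> str:
    half = window // 2
    L = genome.chrom_length(peak.chrom)
    start = peak.summit - half
    end = start + window
    if start < 0 or end > L:
        warnings.warn(f"window for peak {peak.name} clipped at chromosome bounds")
        start, end = max(0, start), min(L, end)
    return genome.fetch(GenomicInterval(peak.chrom, start, end))


def sample_genomic_background(
    genome: Genome,
    template_regions: Sequence[GenomicInterval],
    n: int,
    seed: int = 0,
    exclude: Sequence[GenomicInterval] = (),
    max_tries_per_region: int = 1000,
) -> list[GenomicInterval]:
    """Random genomic regions matching the template set's distribution.

    Region lengths are resampled from the template length distribution and
    per-chromosome counts allocated proportionally to the templates (largest
    remainder), so the background shares the genomic distribution of the
    peaks.  No sampled region overlaps ``exclude``.
    """
    if not template_regions:
        raise ValueError("need template regions")
    rng = np.random.default_rng(seed)
    chroms = sorted({t.chrom for t in template_regions})
    counts = {c: sum(1 for t in template_regions if t.chrom == c) for c in chroms}
    total = sum(counts.values())
    quota = {c: n * counts[c] / total for c in chroms}
    alloc = {c: int(quota[c]) for c in chroms}
    remainders = sorted(chroms, key=lambda c: quota[c] - alloc[c], reverse=True)
    for c in remainders[: n - sum(alloc.values())]:
        alloc[c] += 1
    lengths = np.array([t.length() for t in template_regions])
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in exclude:
        excl_by_chrom.setdefault(e.chrom, []).append(e)
    out: list[GenomicInterval] = []
    for c in chroms:
        L = genome.chrom_length(c)
        blocked = excl_by_chrom.get(c, [])
        for _ in range(alloc[c]):
            ln = int(rng.choice(lengths))
            ln = min(ln, L)
            for _try in range(max_tries_per_region):
                start = int(rng.integers(0, L - ln + 1))
                iv = GenomicInterval(c, start, start + ln)
                if not any(iv.overlaps(b) for b in blocked):
                    out.append(iv)
                    break
            else:
                raise RuntimeError(
                    f"could not place background region on {c} avoiding exclusions"
                )
    return out


def markov_background(
    seqs: Sequence[str],
    order: int = 1,
    n: int = 1000,
    length: int = 200,
    seed: int = 0,
) -> list[str]:
    """Random sequences from an order-k Markov chain fit to ``seqs``.

    Transition probabilities use add-one smoothing; order 0 reduces to
    i.i.d. sampling at the mononucleotide frequencies.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if not seqs:
        raise ValueError("need training sequences")
    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    n_ctx = 4**order
    counts = np.ones((n_ctx, 4))  # add-one smoothing
    for s in seqs:
        su = s.upper()
        enc = [base_idx.get(ch, -1) for ch in su]
        for i in range(len(enc) - order):
            window = enc[i : i + order + 1]
            if any(b < 0 for b in window):
                continue
            ctx = 0
            for b in window[:-1]:
                ctx = ctx * 4 + b
            counts[ctx, window[-1]] += 1
    trans = counts / counts.sum(axis=1, keepdims=True)
    ctx_weights = counts.sum(axis=1)
    ctx_probs = ctx_weights / ctx_weights.sum()
    # cumulative tables for vectorised sampling
    cum_trans = trans.cumsum(axis=1)
    out_mat = np.empty((n, length), dtype=np.int64)
    ctx = rng.choice(n_ctx, size=n, p=ctx_probs)
    # emit the initial context bases
    for j in range(order):
        shift = 4 ** (order - 1 - j)
        out_mat[:, j] = (ctx // shift) % 4
    start = order
    cur = ctx
    for j in range(start, length):
        u = rng.random(n)
        nxt = (cum_trans[cur] < u[:, None]).sum(axis=1)
        out_mat[:, j] = nxt
        if order > 0:
            cur = (cur * 4 + nxt) % n_ctx
    bases = np.array(list("ACGT"))
    return ["".join(bases[row]) for row in out_mat[:, :length]]


# ---------------------------------------------------------------------------
# Enrichment statistics


def _hyper_upper(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(x - 1, N, K, n))


def _one_background(
    x_eval: int, n_eval: int, x_bg: int, n_bg: int
) -> tuple[float, float]:
    p = _hyper_upper(x_eval, n_eval + n_bg, x_eval + x_bg, n_eval)
    rate_eval = x_eval / n_eval
    rate_bg = x_bg / n_bg
    fold = math.inf if rate_bg == 0 else rate_eval / rate_bg
    return p, fold


def motif_enrichment(
    candidate: MotifCandidate,
    eval_seqs: Sequence[str],
    bg_genomic_seqs: Sequence[str],
    bg_markov_seqs: Sequence[str],
    threshold: float,
) -> EnrichmentResult:
    """Hypergeometric enrichment of a motif against both backgrounds.

    A sequence counts as a hit when its best score reaches ``threshold``.
    The reported p is the larger of the two backgrounds' upper-tail
    p-values (conservative); folds are hit-rate ratios.  ``q_bh`` and
    ``significant`` are filled in across a candidate set by
    :func:`evaluate_candidates`.
    """
    if not (len(eval_seqs) and len(bg_genomic_seqs) and len(bg_markov_seqs)):
        raise ValueError("all sequence sets must be non-empty")
    ev = batch_best_scores(candidate.pwm, list(eval_seqs))
    bg_g = batch_best_scores(candidate.pwm, list(bg_genomic_seqs))
    bg_m = batch_best_scores(candidate.pwm, list(bg_markov_seqs))
    return _enrichment_from_scores(ev, bg_g, bg_m, threshold)


def _enrichment_from_scores(
    ev: np.ndarray, bg_g: np.ndarray, bg_m: np.ndarray, threshold: float
) -> EnrichmentResult:
    x = int((ev >= threshold).sum())
    xg = int((bg_g >= threshold).sum())
    xm = int((bg_m >= threshold).sum())
    p_g, fold_g = _one_background(x, ev.size, xg, bg_g.size)
    p_m, fold_m = _one_background(x, ev.size, xm, bg_m.size)
    auc = roc_auc(ev, np.concatenate([bg_g, bg_m]))
    return EnrichmentResult(
        p_hyper=max(p_g, p_m),
        q_bh=math.nan,
        fold_genomic=fold_g,
        fold_markov=fold_m,
        significant=False,
        auc=auc,
        threshold=threshold,
    )


def bh_correct(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def evaluate_candidates(
    candidates: Sequence[MotifCandidate],
    train_seqs: Sequence[str],
    eval_seqs: Sequence[str],
    bg_genomic_seqs: Sequence[str],
    bg_markov_seqs: Sequence[str],
    calibration_bg_seqs: Sequence[str] | None = None,
    alpha: float = SIGNIFICANCE_ALPHA,
    fold_cutoff: float = FOLD_CUTOFF,
    use_adjusted: bool = True,
) -> list[tuple[MotifCandidate, EnrichmentResult]]:
    """Calibrate, test and filter every candidate; BH across the set.

    Each candidate's hit threshold is its own maximum-f-measure cutoff
    calibrated on (training set, Markov background); significance requires
    p (BH-adjusted by default) < ``alpha`` and >``fold_cutoff`` enrichment
    against both backgrounds.
    """
    cal_is_markov = calibration_bg_seqs is None or calibration_bg_seqs is bg_markov_seqs
    if calibration_bg_seqs is None:
        calibration_bg_seqs = bg_markov_seqs
    enc_train = encode_batch(list(train_seqs))
    enc_eval = encode_batch(list(eval_seqs))
    enc_g = encode_batch(list(bg_genomic_seqs))
    enc_m = encode_batch(list(bg_markov_seqs))
    enc_cal = None if cal_is_markov else encode_batch(list(calibration_bg_seqs))
    results: list[EnrichmentResult] = []
    for cand in candidates:
        pwm = cand.pwm
        bg_m_scores = best_scores_encoded(pwm, *enc_m)
        cal_scores = (
            bg_m_scores if enc_cal is None else best_scores_encoded(pwm, *enc_cal)
        )
        cal = calibrate_threshold(
            best_scores_encoded(pwm, *enc_train), cal_scores
        )
        res = _enrichment_from_scores(
            best_scores_encoded(pwm, *enc_eval),
            best_scores_encoded(pwm, *enc_g),
            bg_m_scores,
            cal.threshold,
        )
        results.append(res)
    q = bh_correct([r.p_hyper for r in results])
    out = []
    for cand, res, qv in zip(candidates, results, q):
        crit_p = qv if use_adjusted else res.p_hyper
        sig = bool(
            crit_p < alpha
            and res.fold_genomic > fold_cutoff
            and res.fold_markov > fold_cutoff
        )
        out.append((cand, replace(res, q_bh=float(qv), significant=sig)))
    return out


def select_best_motif(
    results: Sequence[tuple[MotifCandidate, EnrichmentResult]],
) -> MotifCandidate:
    """The significant candidate with maximal ROC AUC.

    Ties break to the narrower width, then lexicographic consensus.
    """
    sig = [(c, r) for c, r in results if r.significant]
    if not sig:
        raise NoSignificantMotifError("no significant motif candidates")
    return min(sig, key=lambda cr: (-cr[1].auc, cr[0].width, cr[0].pwm.consensus))[0]


# ---------------------------------------------------------------------------
# Built-in motif discovery (word seeding + best-site realignment)


def _word_counts(seqs: Sequence[str], width: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        su = s.upper()
        for i in range(len(su) - width + 1):
            w = su[i : i + width]
            if "N" in w:
                continue
            canon = min(w, reverse_complement(w))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def _markov1_word_logprob(word: str, mono: np.ndarray, trans: np.ndarray) -> float:
    idx = ["ACGT".index(c) for c in word]
    lp = math.log(mono[idx[0]])
    for a, b in zip(idx, idx[1:]):
        lp += math.log(trans[a, b])
    return lp


def discover_motifs(
    train_seqs: Sequence[str],
    widths: Sequence[int] = tuple(range(6, 21)),
    n_per_width: int = 10,
    seed: int = 0,
    max_iter: int = 50,
    ic_tol: float = 1e-3,
    pseudocount: float = 0.25,
) -> list[MotifCandidate]:
    """Seed candidate PWMs from over-represented words and refine them.

    For each width, the ``n_per_width`` exact words most over-represented
    relative to a first-order Markov expectation seed PWMs, which are then
    refined by iterative realignment: every training sequence contributes
    its best-scoring site, and the PWM is rebuilt from those sites until the
    information content changes by less than ``ic_tol`` (or ``max_iter``).
    """
    if len(train_seqs) < 10:
        raise ValueError("need at least 10 training sequences")
    # background composition of the training set
    mat, lengths = encode_batch(list(train_seqs))
    flat = np.concatenate([mat[i, : lengths[i]] for i in range(len(train_seqs))])
    flat = flat[flat < 4]
    mono = np.bincount(flat, minlength=4).astype(float) + 1.0
    mono /= mono.sum()
    di = np.ones((4, 4))
    for i in range(len(train_seqs)):
        row = mat[i, : lengths[i]]
        ok = (row[:-1] < 4) & (row[1:] < 4)
        np.add.at(di, (row[:-1][ok], row[1:][ok]), 1.0)
    trans = di / di.sum(axis=1, keepdims=True)

    candidates: list[MotifCandidate] = []
    total_positions = int((np.maximum(lengths, 0)).sum())
    for width in widths:
        if all(ln < width for ln in lengths):
            warnings.warn(f"all training sequences shorter than width {width}; skipped")
            continue
        counts = _word_counts(train_seqs, width)
        if not counts:
            continue
        scored = []
        n_pos = max(total_positions - width * len(train_seqs), 1)
        for word, obs in counts.items():
            if obs < 2:
                continue
            lp = _markov1_word_logprob(word, mono, trans)
            lp_rc = _markov1_word_logprob(reverse_complement(word), mono, trans)
            expected = n_pos * (math.exp(lp) + math.exp(lp_rc))
            scored.append((obs / max(expected, 1e-300), obs, word))
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        for _, _, word in scored[:n_per_width]:
            pwm = _refine_pwm(
                word, train_seqs, mono, pseudocount, max_iter, ic_tol
            )
            candidates.append(MotifCandidate(pwm, source="builtin"))
    return candidates


def _refine_pwm(
    seed_word: str,
    seqs: Sequence[str],
    background: np.ndarray,
    pseudocount: float,
    max_iter: int,
    ic_tol: float,
) -> DimericPWM:
    width = len(seed_word)
    pwm = build_pwm(
        [seed_word], pseudocount=max(pseudocount, 0.25), background=background,
        name=seed_word,
    )
    prev_ic = pwm.information_content()
    for _ in range(max_iter):
        scores, pos, strand, _ = batch_best_hits(pwm, list(seqs))
        sites = []
        for i, s in enumerate(seqs):
            if not np.isfinite(scores[i]):
                continue
            frag = s.upper()[pos[i] : pos[i] + width]
            if strand[i] < 0:
                frag = reverse_complement(frag)
            if "N" not in frag and len(frag) == width:
                sites.append(frag)
        if not sites:
            break
        pwm = build_pwm(
            sites, pseudocount=pseudocount, background=background, name=seed_word
        )
        ic = pwm.information_content()
        if abs(ic - prev_ic) < ic_tol:
            break
        prev_ic = ic
    return pwm


# ---------------------------------------------------------------------------
# Binomial over-representation of a motif library between two sequence sets


def binomial_overrepresentation(
    motif_library: Mapping[str, DimericPWM],
    setA_seqs: Sequence[str],
    setB_seqs: Sequence[str],
    threshold_per_motif: Mapping[str, float] | float,
) -> pd.DataFrame:
    """Per-motif binomial test of set-A hit counts at the set-B hit rate.

    The Bonferroni factor is the number of motifs with at least one hit in
    either set.  A motif with hits in A but rate 0 in B is flagged
    degenerate (p = 0).
    """
    if not motif_library:
        raise ValueError("motif library is empty")
    rows = []
    for name, pwm in motif_library.items():
        t = (
            threshold_per_motif[name]
            if isinstance(threshold_per_motif, Mapping)
            else float(threshold_per_motif)
        )
        a = batch_best_scores(pwm, list(setA_seqs)) >= t
        b = batch_best_scores(pwm, list(setB_seqs)) >= t
        x_a, n_a = int(a.sum()), a.size
        x_b, n_b = int(b.sum()), b.size
        p_hat = x_b / n_b
        degenerate = p_hat == 0 and x_a > 0
        if x_a == 0:
            p = 1.0
        elif degenerate:
            p = 0.0
        else:
            p = float(binom.sf(x_a - 1, n_a, p_hat))
        rows.append(
            {
                "motif": name,
                "hits_a": x_a,
                "hits_b": x_b,
                "rate_b": p_hat,
                "p_binomial": p,
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows).set_index("motif")
    m = int(((df.hits_a > 0) | (df.hits_b > 0)).sum())
    df["bonferroni_m"] = m
    df["p_bonferroni"] = np.minimum(df["p_binomial"] * max(m, 1), 1.0)
    return df
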