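"""Disease-phenotype similarity statistics.

Diseases are rows of a non-negative disease x feature-term weight matrix
(binary presence by default, arbitrary weights accepted).  Similarity of two
diseases is the cosine of their term-weight vectors (0 = no overlap, 1 =
identical overlap); a disease set is scored by the mean over all unordered
pairs and compared with a randomized-sampling null.  Feature terms are
ranked by within-set hypergeometric enrichment, with a top-k% membership
test for a query term set.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "DiseaseFeatureMatrix",
    "SimilarityResult",
    "pairwise_similarity",
    "set_similarity",
    "resampling_null",
    "evaluate_disease_set",
    "term_overrepresentation",
    "top_k_enrichment",
]


class DiseaseFeatureMatrix:
    """Disease x term non-negative weight matrix with identifier lookups."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any() or frame.columns.duplicated().any():
            raise ValueError("duplicate disease or term identifiers")
        w = frame.to_numpy(dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if (w.sum(axis=1) == 0).any():
            raise ValueError("every disease needs at least one nonzero term")
        self.frame = frame
        self.weights = w
        self.diseases = list(frame.index)
        self.terms = list(frame.columns)
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        self._unit = w / norms

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseFeatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")

    def indices(self, disease_set: Sequence[str]) -> np.ndarray:
        lookup = {d: i for i, d in enumerate(self.diseases)}
        try:
            return np.array([lookup[d] for d in disease_set], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown disease {exc}") from None

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)


@dataclass(frozen=True)
class SimilarityResult:
    set_score: float
    null_mean: float
    p_empirical: float
    n_samples: int


def pairwise_similarity(d1: np.ndarray, d2: np.ndarray) -> float:
    """Cosine similarity of two term-weight vectors, in [0, 1]."""
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero term vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def _mean_pairwise_from_unit(unit_rows: np.ndarray) -> float:
    # mean over unordered pairs via ||sum of unit vectors||^2 = k + 2*sum_pairs
    k = unit_rows.shape[0]
    s = unit_rows.sum(axis=0)
    return float((s @ s - k) / (k * (k - 1)))


def set_similarity(
    matrix: DiseaseFeatureMatrix, disease_set: Sequence[str]
) -> float:
    """Mean pairwise cosine similarity over all C(k, 2) disease pairs."""
    idx = matrix.indices(disease_set)
    if idx.size < 2:
        raise ValueError("need at least two diseases")
    return _mean_pairwise_from_unit(matrix._unit[idx])


def resampling_null(
    matrix: DiseaseFeatureMatrix,
    set_size: int,
    n_samples: int = 999,
    seed: int = 0,
    observed: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Null distribution of set scores from random without-replacement draws.

    Returns the null scores and, when an observed score is supplied, the
    empirical p = (1 + #null >= observed) / (1 + n_samples).
    """
    if set_size > matrix.n_diseases:
        raise ValueError("set_size exceeds number of diseases")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_samples)
    for i in range(n_samples):
        idx = rng.choice(matrix.n_diseases, size=set_size, replace=False)
        null[i] = _mean_pairwise_from_unit(matrix._unit[idx])
    p = None
    if observed is not None:
        p = (1 + int((null >= observed).sum())) / (1 + n_samples)
    return null, p


def evaluate_disease_set(
    matrix: DiseaseFeatureMatrix,
    disease_set: Sequence[str],
    n_samples: int = 999,
    seed: int = 0,
) -> SimilarityResult:
    """Set score, null mean and empirical p for one disease set."""
    score = set_similarity(matrix, disease_set)
    null, p = resampling_null(
        matrix, len(disease_set), n_samples=n_samples, seed=seed, observed=score
    )
    return SimilarityResult(score, float(null.mean()), float(p), n_samples)


def term_overrepresentation(
    matrix: DiseaseFeatureMatrix, disease_set: Sequence[str]
) -> pd.DataFrame:
    """Terms ranked by hypergeometric enrichment within the disease set.

    Per term: x diseases carrying the term inside the set, K overall, with
    N diseases total and a set of size n; p is the upper tail P(X >= x).
    """
    idx = matrix.indices(disease_set)
    present = matrix.weights > 0
    N = matrix.n_diseases
    n = idx.size
    K = present.sum(axis=0)
    x = present[idx].sum(axis=0)
    p = hypergeom.sf(x - 1, N, K, n)
    df = pd.DataFrame(
        {"term": matrix.terms, "in_set": x, "overall": K, "p_hyper": p}
    )
    return df.sort_values(["p_hyper", "term"], kind="stable").reset_index(drop=True)


def top_k_enrichment(
    ranked_terms: pd.DataFrame | Sequence[str],
    query_terms: Sequence[str],
    k_fraction: float,
) -> float:
    """Hypergeometric p for query-term membership in the top-k% of the ranking."""
    if not len(query_terms):
        raise ValueError("empty query term set")
    terms = (
        list(ranked_terms["term"])
        if isinstance(ranked_terms, pd.DataFrame)
        else list(ranked_terms)
    )
    unknown = set(query_terms) - set(terms)
    if unknown:
        raise KeyError(f"query terms not in ranking: {sorted(unknown)}")
    m = ceil(k_fraction * len(terms))
    top = set(terms[:m])
    x = sum(1 for t in query_terms if t in top)
    return float(hypergeom.sf(x - 1, len(terms), m, len(set(query_terms))))
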