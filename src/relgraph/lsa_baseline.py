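"""Truncated-SVD latent semantic analysis baseline for edge weighting.

Edge strength between a cross-space term pair is the cosine similarity of
the terms' latent vectors (negative cosines clipped to zero, since edge
strengths are non-negative).  Raw occurrence counts, no tf-idf or entropy
weighting — the minimal deterministic baseline.  A coefficient-of-variation
statistic quantifies how spread-out a set of edge weights is, so the
co-occurrence and LSA weightings can be compared for smoothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, TermSpace, tokenize
from .graph_inference import Association

__all__ = [
    "TermDocMatrix",
    "build_term_doc_matrix",
    "lsa_edge_weights",
    "weight_dispersion",
]

logger = logging.getLogger(__name__)


@dataclass
class TermDocMatrix:
    terms: tuple[str, ...]
    doc_ids: tuple[str, ...]
    counts: np.ndarray  # shape (len(terms), len(doc_ids)), non-negative ints

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.terms), len(self.doc_ids)):
            raise ValueError("count matrix shape does not match vocabulary x corpus")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def _phrase_occurrences(tokens: list[str], phrase: str) -> int:
    seq = phrase.split(" ")
    m = len(seq)
    if m == 0 or m > len(tokens):
        return 0
    if m == 1:
        return tokens.count(seq[0])
    return sum(1 for i in range(len(tokens) - m + 1) if tokens[i : i + m] == seq)


def build_term_doc_matrix(corpus: Corpus, vocabulary: tuple[str, ...]) -> TermDocMatrix:
    """Occurrence-count matrix of vocabulary phrases over documents."""
    counts = np.zeros((len(vocabulary), corpus.size), dtype=np.int64)
    for j, doc in enumerate(corpus):
        tokens = tokenize(doc.text)
        for i, term in enumerate(vocabulary):
            counts[i, j] = _phrase_occurrences(tokens, term)
    return TermDocMatrix(
        terms=tuple(vocabulary),
        doc_ids=tuple(d.id for d in corpus),
        counts=counts,
    )


def lsa_edge_weights(
    corpus: Corpus,
    space_a: TermSpace,
    space_b: TermSpace,
    dim: int | None = None,
) -> list[Association]:
    """Cross-space edge weights from an LSA embedding of the corpus.

    The term-document count matrix is decomposed with a (deterministic,
    full) SVD truncated to ``dim`` components; each term's latent vector is
    its row of ``U_k @ diag(S_k)``.  The weight of pair (a, b) is
    ``max(0, cos(vec_a, vec_b))``.  Terms absent from the corpus get weight
    0 with a warning.  Default ``dim``: ``min(100, rank - 1)`` (at least 1).
    """
    vocab = tuple(space_a.terms) + tuple(space_b.terms)
    tdm = build_term_doc_matrix(corpus, vocab)
    X = tdm.counts.astype(np.float64)
    if corpus.size == 0:
        raise ValueError("empty corpus")
    max_dim = min(X.shape)
    rank = int(np.linalg.matrix_rank(X)) if X.any() else 0
    if dim is None:
        dim = max(1, min(100, rank - 1)) if rank > 1 else 1
    if not (1 <= dim <= max_dim):
        raise ValueError(f"dim must be in [1, {max_dim}], got {dim}")

    U, S, _ = np.linalg.svd(X, full_matrices=False)
    vectors = U[:, :dim] * S[:dim]  # one latent vector per vocabulary term

    norms = np.linalg.norm(vectors, axis=1)
    absent = [vocab[i] for i in np.flatnonzero(tdm.counts.sum(axis=1) == 0)]
    if absent:
        warnings.warn(
            f"{len(absent)} term(s) absent from corpus get LSA weight 0: "
            f"{', '.join(absent[:5])}",
            stacklevel=2,
        )

    index = {t: i for i, t in enumerate(vocab)}
    out: list[Association] = []
    for a in space_a.terms:
        ia = index[a]
        for b in space_b.terms:
            ib = index[b]
            if norms[ia] == 0 or norms[ib] == 0:
                weight = 0.0
            else:
                cos = float(vectors[ia] @ vectors[ib] / (norms[ia] * norms[ib]))
                weight = max(0.0, min(1.0, cos))
            out.append(Association(term_a=a, term_b=b, weight=weight))
    return out


def lsa_weight_map(
    corpus: Corpus, space_a: TermSpace, space_b: TermSpace, dim: int | None = None
) -> dict[tuple[str, str], float]:
    """Convenience wrapper: cross-space pair -> LSA cosine weight in [0, 1]."""
    return {
        (a.term_a, a.term_b): float(a.weight)
        for a in lsa_edge_weights(corpus, space_a, space_b, dim=dim)
    }


def weight_dispersion(weights) -> float:
    """Coefficient of variation: population standard deviation over mean."""
    arr = np.asarray(list(weights), dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least two weights")
    if (arr < 0).any():
        raise ValueError("weights must be non-negative")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("all weights are zero; dispersion undefined")
    return float(arr.std(ddof=0) / mean)
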