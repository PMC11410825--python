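"""Improved semantic-similarity feature with cubic-map chaotic weights.

Two proteins' annotation profiles over the LCA clusters (non-negative
vectors Ra, Rb of length m, from :mod:`ppifuse.go_features`) are compared by

    Sem(Ra, Rb) = sum_a sqrt(Ra_a * Rb_a) * w_a / (sqrt(sum_a Ra_a) * sqrt(sum_a Ra_a))

where the per-dimension weights w_a come from iterating the chaotic cubic
map E_{c+1} = rho * E_c * (1 - E_c^2) on (0, 1). The denominator repeats the
Ra sum as written; ``symmetric_denominator=True`` substitutes Rb in the
second factor, which makes the score symmetric under swapping the proteins.
A plain SR-transformed cosine (``ssd_cosine``) is provided as a reference
baseline and is not part of the default feature pipeline.
"""

from __future__ import annotations

import math

import numpy as np

#: Largest control parameter for which cubic-map orbits stay inside (0, 1).
RHO_MAX = 3.0 * math.sqrt(3.0) / 2.0

DEFAULT_RHO = 2.59
DEFAULT_E0 = 0.7


def cubic_map_weights(rho: float = DEFAULT_RHO, e0: float = DEFAULT_E0, m: int = 1) -> np.ndarray:
    """First ``m`` iterates of the cubic map, used as deterministic weights.

    ``rho`` must lie in (0, 3*sqrt(3)/2) and ``e0`` in (0, 1); every iterate
    then stays in (0, 1) and the stream is fully determined by (rho, e0, m).
    """
    if not 0 < rho < RHO_MAX:
        raise ValueError(f"rho must be in (0, {RHO_MAX:.6f}), got {rho}")
    if not 0 < e0 < 1:
        raise ValueError(f"e0 must be in (0, 1), got {e0}")
    if m < 1:
        raise ValueError("m must be >= 1")
    weights = np.empty(m)
    e = e0
    for a in range(m):
        e = rho * e * (1.0 - e * e)
        weights[a] = e
    return weights


def improved_semantic_similarity(
    ra, rb, weights, symmetric_denominator: bool = False
) -> float:
    """Weighted geometric-mean overlap of two cluster profiles.

    Zero when the supports are weight-disjoint; defined as 0 when the
    denominator vanishes (e.g. both profiles all-zero).
    """
    ra = np.asarray(ra, dtype=float)
    rb = np.asarray(rb, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ra.shape != rb.shape or ra.shape != weights.shape:
        raise ValueError("ra, rb and weights must have equal lengths")
    if np.any(ra < 0) or np.any(rb < 0):
        raise ValueError("profiles must be non-negative")
    numerator = float(np.sum(np.sqrt(ra * rb) * weights))
    second = rb if symmetric_denominator else ra
    denominator = math.sqrt(float(ra.sum())) * math.sqrt(float(second.sum()))
    if denominator == 0.0:
        return 0.0
    return numerator / denominator


def ssd_cosine(ra, rb, relation: np.ndarray | None = None) -> float:
    """Cosine similarity of SR-transformed profiles (SR defaults to identity).

    With the identity relation matrix this is the plain cosine; zero-norm
    inputs yield 0.
    """
    ra = np.asarray(ra, dtype=float)
    rb = np.asarray(rb, dtype=float)
    if ra.shape != rb.shape:
        raise ValueError("ra and rb must have equal lengths")
    if relation is not None:
        relation = np.asarray(relation, dtype=float)
        if relation.shape != (ra.size, ra.size):
            raise ValueError("relation matrix must be square m x m")
        ra = relation @ ra
        rb = relation @ rb
    norm = np.linalg.norm(ra) * np.linalg.norm(rb)
    if norm == 0.0:
        return 0.0
    return float(np.dot(ra, rb) / norm)
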