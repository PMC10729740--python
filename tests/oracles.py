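"""Independent brute-force oracles used by the test suite.

These are deliberately written as plain position-by-position Python loops,
separate from the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from clonoscope.tcr_space import SIM_GERMLINE

_B62 = substitution_matrices.load("BLOSUM62")


def penalty(a: str, b: str) -> float:
    if a == b:
        return 0.0
    return min(4.0, 4.0 - float(_B62[a][b]))


def aligned_loop_score(x: str, y: str, weight: float) -> float:
    """Score one loop pair: central gap block in the shorter sequence, gap
    penalty 4 per gapped position, all times the loop weight."""
    if len(x) > len(y):
        x, y = y, x
    m, n = len(x), len(y)
    lead = (m + 1) // 2
    tail = m - lead
    score = 0.0
    for i in range(lead):
        score += penalty(x[i], y[i])
    for i in range(tail):
        score += penalty(x[lead + i], y[n - tail + i])
    return weight * (score + 4.0 * (n - m))


def brute_tcrdist(rec1, rec2, chains=("alpha", "beta"), germline=True,
                  trim_n=3, trim_c=2, cdr3_weight=3.0) -> float:
    """Position-by-position TCRdist-style score between two clonotypes."""
    total = 0.0
    for chain, v1, v2, c1, c2 in (
        ("alpha", rec1.va, rec2.va, rec1.cdr3a, rec2.cdr3a),
        ("beta", rec1.vb, rec2.vb, rec1.cdr3b, rec2.cdr3b),
    ):
        if chain not in chains:
            continue
        if germline:
            for l1, l2 in zip(SIM_GERMLINE[v1], SIM_GERMLINE[v2]):
                total += aligned_loop_score(l1, l2, 1.0)
        total += aligned_loop_score(
            c1[trim_n: len(c1) - trim_c], c2[trim_n: len(c2) - trim_c], cdr3_weight
        )
    return total


def brute_knn_diffusion(coords: np.ndarray, values: np.ndarray, k: int,
                        iterations: int) -> np.ndarray:
    """Direct matrix-power oracle for kNN density diffusion (self-loop
    included, mass-conserving transpose propagation)."""
    n = len(coords)
    A = np.zeros((n, n))
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        nearest = np.argsort(d, kind="stable")[: k + 1]
        A[i, nearest] = 1.0 / (k + 1)
    out = values.astype(float).copy()
    for _ in range(iterations):
        out = A.T @ out
    return out
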