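"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: exact
hypergeometric tail via integer binomials, AUC by pair counting,
permutation nulls by exhaustive enumeration, and superposition RMSD by
rotation grid search.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from phosfam.hotspot_stats import HotspotParams, sliding_window_mean
from phosfam.site_mapping import FamilyAlignment


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    num = sum(
        math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(a, min(r1, c1) + 1)
        if c1 - k <= r2
    )
    return num / denom


def auc_pair_counting(scores, labels) -> float:
    """AUC by explicit positive-negative pair comparison, ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def enumerate_null_profiles(
    aln: FamilyAlignment, params: HotspotParams
) -> np.ndarray:
    """Window profiles of EVERY possible per-row, per-type reassignment
    (each equally likely), shape (n_placements, n_columns)."""
    groups = []
    for rid in aln.row_ids:
        for t in ("S", "T", "Y"):
            acc = aln.acceptors[rid][t] - 1
            k = sum(1 for _c, r in aln.sites[rid] if r == t)
            if k:
                groups.append((tuple(int(x) for x in acc), k))
    choice_sets = [
        list(itertools.combinations(acc, k)) for acc, k in groups
    ]
    profiles = []
    for combo in itertools.product(*choice_sets):
        counts = np.zeros(aln.n_columns)
        for placed in combo:
            for col in placed:
                counts[col] += 1
        profiles.append(sliding_window_mean(counts, params.window))
    return np.vstack(profiles)


def grid_search_rmsd_2d(A: np.ndarray, B: np.ndarray, n_grid: int = 200_000) -> float:
    """Best RMSD between two planar (z=0) point sets over in-plane
    rotations after centroid alignment."""
    A = (A - A.mean(axis=0))[:, :2]
    B = (B - B.mean(axis=0))[:, :2]
    theta = np.linspace(0.0, 2 * math.pi, n_grid, endpoint=False)
    c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
    dx = c * A[:, 0] - s * A[:, 1] - B[:, 0]
    dy = s * A[:, 0] + c * A[:, 1] - B[:, 1]
    ss = (dx * dx + dy * dy).sum(axis=1)
    return math.sqrt(ss.min() / len(A))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
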