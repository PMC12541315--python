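"""Rigid alignment of unordered atom clouds.

Generated ligands carry no canonical atom order, so comparing a sample with
a reference requires minimizing RMSD jointly over proper rotations,
translation, and atom correspondence. For small molecules the correspondence
is solved exactly by enumerating permutations (Kabsch alignment per
permutation); larger inputs fall back to multi-start
iterative-closest-point with Hungarian assignment.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

__all__ = ["kabsch_rmsd", "matched_rmsd"]

_EXACT_LIMIT = 8  # n! Kabsch evaluations up to here (8! = 40320)


def kabsch_rmsd(ref: np.ndarray, mobile: np.ndarray) -> float:
    """Per-atom RMSD after optimal rotation+translation, fixed correspondence."""
    ref = np.asarray(ref, float)
    mobile = np.asarray(mobile, float)
    a = ref - ref.mean(axis=0)
    b = mobile - mobile.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(ref)))


def matched_rmsd(ref: np.ndarray, mobile: np.ndarray, n_starts: int = 24,
                 seed: int = 0) -> float:
    """Minimum per-atom RMSD over correspondence and rigid motion.

    Exact for up to 8 atoms (permutation enumeration); beyond that, ICP from
    ``n_starts`` random rotations (a lower bound is not guaranteed, but local
    minima are rare with that many starts).
    """
    ref = np.asarray(ref, float)
    mobile = np.asarray(mobile, float)
    if ref.shape != mobile.shape:
        raise ValueError("point sets must have identical shape")
    n = len(ref)
    if n <= _EXACT_LIMIT:
        best = np.inf
        a = ref - ref.mean(axis=0)
        b = mobile - mobile.mean(axis=0)
        for p in itertools.permutations(range(n)):
            _, rssd = Rotation.align_vectors(a[list(p)], b)
            best = min(best, float(rssd / np.sqrt(n)))
        return best
    rng = np.random.default_rng(seed)
    a = ref - ref.mean(axis=0)
    b = mobile - mobile.mean(axis=0)
    best = np.inf
    for start in range(n_starts):
        R = Rotation.random(random_state=rng)
        br = R.apply(b)
        for _ in range(30):
            D = np.linalg.norm(a[:, None, :] - br[None, :, :], axis=2)
            ri, ci = linear_sum_assignment(D)
            rmsd = float(np.sqrt((D[ri, ci] ** 2).mean()))
            best = min(best, rmsd)
            Rstep, _ = Rotation.align_vectors(a[ri], br[ci])
            br = Rstep.apply(br)
    return best
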