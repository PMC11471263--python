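"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations kept separate from the package: a pure
Python Gotoh affine-gap aligner over Biopython's BLOSUM62, a double-loop
contact computation, and helpers for constructing rigid transforms.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11   # gap of length k costs GAP_OPEN + k * GAP_EXTEND
GAP_EXTEND = 1


def blosum62(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a][b])


def gotoh_score(query: str, ref: str, mode: str) -> float:
    """Affine-gap DP score: Smith-Waterman ("local") or strict global
    Needleman-Wunsch ("global_query")."""
    n, m = len(query), len(ref)
    neg = -1e9
    H = np.full((n + 1, m + 1), neg)
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    local = mode == "local"
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        H[i, 0] = 0.0 if local else -(GAP_OPEN + i * GAP_EXTEND)
        F[i, 0] = H[i, 0]
    for j in range(1, m + 1):
        H[0, j] = 0.0 if local else -(GAP_OPEN + j * GAP_EXTEND)
        E[0, j] = H[0, j]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - (GAP_OPEN + GAP_EXTEND), E[i, j - 1] - GAP_EXTEND)
            F[i, j] = max(H[i - 1, j] - (GAP_OPEN + GAP_EXTEND), F[i - 1, j] - GAP_EXTEND)
            h = max(H[i - 1, j - 1] + blosum62(query[i - 1], ref[j - 1]), E[i, j], F[i, j])
            if local:
                h = max(h, 0.0)
                best = max(best, h)
            H[i, j] = h
    return best if local else float(H[n, m])


def brute_force_contacts(coords_a: dict[str, np.ndarray],
                         coords_b: dict[str, np.ndarray],
                         cutoff: float) -> tuple[dict, set]:
    """Double loop over all label pairs: distances and the contact set."""
    distances = {}
    contacts = set()
    for la, pa in coords_a.items():
        for lb, pb in coords_b.items():
            d = float(np.sqrt(((np.asarray(pa) - np.asarray(pb)) ** 2).sum()))
            distances[(la, lb)] = d
            if d <= cutoff:
                contacts.add((la, lb))
    return distances, contacts


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation plus a random translation."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.normal(scale=30.0, size=3)
    return lambda x: rot.apply(x) + t
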