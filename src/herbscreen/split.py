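"""Duplex calibration/validation splitting.

The duplex algorithm builds two representative, mutually independent
subsets by alternately handing the farthest remaining point pair
(Euclidean distance) to the calibration set and the next farthest to the
validation set.  Here the alternation runs until the validation set
reaches ``ceil(test_fraction * n)`` members -- the only rounding that
yields both a 17-of-67 and a 59-of-235 validation set at a 25 % fraction
-- after which every remaining point joins the calibration set.  If the
validation set needs a single final point on its turn, the member of the
next pair lying farther from the existing validation set is taken.

Ties in pair distance resolve to the lexicographically smallest
(row-index, row-index) pair, so the split is deterministic for a given
row order, and a permutation of rows with all-distinct pairwise distances
yields the same partition as sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cube import FingerprintMatrix

__all__ = ["SplitAssignment", "duplex_split"]


@dataclass
class SplitAssignment:
    calibration_ids: list[str]
    validation_ids: list[str]
    distances_log: list[dict] = field(default_factory=list)

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_validation(self) -> int:
        return len(self.validation_ids)


def _farthest_remaining_pair(dist: np.ndarray, remaining: np.ndarray) -> tuple[int, int]:
    sub = dist[np.ix_(remaining, remaining)]
    np.fill_diagonal(sub, -1.0)
    best = sub.max()
    # lexicographically smallest (i, j) among ties, in original row indices
    ii, jj = np.nonzero(sub == best)
    keep = ii < jj
    ii, jj = ii[keep], jj[keep]
    k = np.lexsort((jj, ii))[0]
    return int(remaining[ii[k]]), int(remaining[jj[k]])


def duplex_split(matrix: FingerprintMatrix, test_fraction: float = 0.25) -> SplitAssignment:
    """Split a fingerprint matrix into calibration and validation rows.

    Validation size is ``ceil(test_fraction * n)``; distances are computed
    on the matrix exactly as given (post-warping, unscaled).  Duplicate
    rows (distance 0) are legal and resolved by the index tie rule.
    """
    n = matrix.n_samples
    if n < 4:
        raise ValueError("duplex needs at least 4 samples")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")

    n_val = math.ceil(test_fraction * n)
    dist = squareform(pdist(matrix.values))
    ids = matrix.sample_ids

    remaining = np.arange(n)
    cal: list[int] = []
    val: list[int] = []
    log: list[dict] = []
    turn = "calibration"
    while remaining.size:
        if len(val) >= n_val:
            cal.extend(int(i) for i in remaining)
            log.append({"set": "calibration", "members": [ids[int(i)] for i in remaining],
                        "note": "validation full; remainder to calibration"})
            break
        if remaining.size == 1:
            i = int(remaining[0])
            (val if turn == "validation" and len(val) < n_val else cal).append(i)
            break
        i, j = _farthest_remaining_pair(dist, remaining)
        if turn == "validation" and n_val - len(val) == 1:
            di = dist[i, val].min() if val else np.inf
            dj = dist[j, val].min() if val else np.inf
            pick = i if di >= dj else j  # tie: smaller row index (i < j)
            val.append(pick)
            log.append({"set": "validation", "pair": (ids[i], ids[j]),
                        "distance": float(dist[i, j]), "taken": ids[pick]})
            remaining = remaining[remaining != pick]
        else:
            (cal if turn == "calibration" else val).extend([i, j])
            log.append({"set": turn, "pair": (ids[i], ids[j]),
                        "distance": float(dist[i, j])})
            remaining = remaining[(remaining != i) & (remaining != j)]
        turn = "validation" if turn == "calibration" else "calibration"

    return SplitAssignment(
        calibration_ids=[ids[k] for k in sorted(cal)],
        validation_ids=[ids[k] for k in sorted(val)],
        distances_log=log,
    )
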