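"""Margin-preserving permutation null and permutation-count FDR estimation.

Binary event matrices (sample × event, one matrix per event class —
mutation, CNA loss, CNA gain — per cancer type) are randomized by repeated
2×2 checkerboard swaps, which preserve every row and column sum exactly.
The swap proposal is symmetric and the swap is an involution, so the walk's
stationary distribution is uniform over the fill class of matrices sharing
the input's margins.

The FDR at a p-value cutoff c is the mean number of detections (p ≤ c) in
permuted data divided by the number of detections in the real data; a
running minimum from the largest cutoff downward makes the reported curve
monotone non-decreasing in c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "permute_margins",
    "FDRCurve",
    "estimate_fdr",
    "calls_at_fdr",
]


@njit(cache=True)
def _checkerboard_swaps(mat: np.ndarray, n_swaps: int, seed: int) -> None:  # pragma: no cover
    # xorshift64* keeps the hot loop cheap; the proposal stays symmetric
    # (row/col picks depend only on the generator state), which is all the
    # uniform stationary distribution requires.
    n, m = mat.shape
    state = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    if state == np.uint64(0):
        state = np.uint64(88172645463325252)
    for _ in range(n_swaps):
        state ^= state << np.uint64(13)
        state ^= state >> np.uint64(7)
        state ^= state << np.uint64(17)
        x = state * np.uint64(2685821657736338717)
        state ^= state << np.uint64(13)
        state ^= state >> np.uint64(7)
        state ^= state << np.uint64(17)
        y = state * np.uint64(2685821657736338717)
        r1 = int((x & np.uint64(0xFFFFFFFF)) % np.uint64(n))
        r2 = int((x >> np.uint64(32)) % np.uint64(n))
        c1 = int((y & np.uint64(0xFFFFFFFF)) % np.uint64(m))
        c2 = int((y >> np.uint64(32)) % np.uint64(m))
        a = mat[r1, c1]
        d = mat[r2, c2]
        b = mat[r1, c2]
        c = mat[r2, c1]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[r1, c1] = 1
            mat[r2, c2] = 1
            mat[r1, c2] = 0
            mat[r2, c1] = 0


def permute_margins(
    matrix: np.ndarray, seed: int, min_swaps: int | None = None
) -> np.ndarray:
    """Uniform margin-preserving permutation of a binary matrix.

    Performs ``min_swaps`` checkerboard swap attempts (default 10× the
    number of 1s, a burn-in long enough to decorrelate the walk); row and
    column sums of the output equal the input's exactly. Deterministic for
    a given seed.
    """
    arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise ValueError("event matrix must be two-dimensional")
    if arr.size and not np.isin(np.unique(arr), [0, 1]).all():
        raise ValueError("event matrix must be binary")
    out = arr.astype(np.uint8).copy()
    ones = int(out.sum())
    if ones == 0 or ones == out.size:
        return out
    n_swaps = int(min_swaps) if min_swaps is not None else 10 * ones
    _checkerboard_swaps(out, n_swaps, int(seed) % (2**31 - 1))
    return out


# ---------------------------------------------------------------------------
# FDR estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FDRCurve:
    """Permutation-count FDR over a grid of p-value cutoffs.

    ``fdr`` is NaN at cutoffs with zero real detections; ``fdr_adjusted``
    is the monotone (running-minimum-from-the-right) curve used for calls.
    """

    cutoffs: np.ndarray
    real_counts: np.ndarray
    perm_counts: np.ndarray
    fdr: np.ndarray
    fdr_adjusted: np.ndarray
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "real_count": self.real_counts,
                "mean_perm_count": self.perm_counts,
                "fdr": self.fdr,
                "fdr_adjusted": self.fdr_adjusted,
            }
        )

    def threshold(self, target: float) -> float | None:
        """Largest cutoff whose adjusted FDR is ≤ target, or None."""
        if not 0.0 < target < 1.0:
            raise ValueError("FDR target must lie in (0, 1)")
        ok = np.where(~np.isnan(self.fdr_adjusted) & (self.fdr_adjusted <= target))[0]
        if ok.size == 0:
            return None
        return float(self.cutoffs[ok[-1]])


def _count_leq(sorted_values: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_values, cutoffs, side="right").astype(float)


def estimate_fdr(
    real_p: Sequence[float] | np.ndarray,
    permuted_p: Sequence[Sequence[float] | np.ndarray],
    cutoffs: Sequence[float] | np.ndarray | None = None,
    *,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> FDRCurve:
    """Estimate FDR(c) = mean permuted detections / real detections at each
    p-value cutoff c.

    ``permuted_p`` is one p-value collection per permutation replicate (NaN
    entries, e.g. non-estimable fits, are ignored). The default cutoff grid
    is the sorted distinct real p-values — the curve only changes there.
    """
    real = np.asarray(real_p, dtype=float)
    real = real[~np.isnan(real)]
    if real.size == 0:
        raise ValueError("estimate_fdr requires at least one real p-value")
    if len(permuted_p) == 0:
        raise ValueError("estimate_fdr requires at least one permutation replicate")
    if cutoffs is None:
        grid = np.unique(real)
    else:
        grid = np.asarray(cutoffs, dtype=float)
    real_sorted = np.sort(real)
    real_counts = _count_leq(real_sorted, grid)

    perm_counts = np.zeros_like(grid)
    for rep in permuted_p:
        rep_arr = np.asarray(rep, dtype=float)
        rep_arr = np.sort(rep_arr[~np.isnan(rep_arr)])
        perm_counts += _count_leq(rep_arr, grid)
    perm_counts /= len(permuted_p)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(real_counts > 0, perm_counts / real_counts, np.nan)

    adjusted = fdr.copy()
    running = np.inf
    for i in range(len(adjusted) - 1, -1, -1):
        if np.isnan(adjusted[i]):
            continue
        running = min(running, adjusted[i])
        adjusted[i] = running
    return FDRCurve(
        cutoffs=grid,
        real_counts=real_counts,
        perm_counts=perm_counts,
        fdr=fdr,
        fdr_adjusted=adjusted,
        n_permutations=n_permutations if n_permutations is not None else len(permuted_p),
        seed=seed,
    )


def calls_at_fdr(results: Sequence, curve: FDRCurve, target: float = 0.10) -> list:
    """Results significant at the FDR target: p ≤ the largest cutoff whose
    adjusted FDR is ≤ target. Empty when no cutoff qualifies."""
    cstar = curve.threshold(target)
    if cstar is None:
        return []
    return [r for r in results if r.pvalue is not None and r.pvalue <= cstar]
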