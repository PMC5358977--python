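"""Dynamic-time-warped mean-squared-error distances between contours.

Each contour is first mean-frequency subtracted (so the comparison reflects
contour *shape*, not register), then every pair is aligned by classic
dynamic time warping with squared-difference local cost and the symmetric
(match/insert/delete, unit weight) step pattern.  The dissimilarity is the
accumulated squared error along the optimal boundary-to-boundary warping
path divided by that path's length — a mean squared error in kHz², so that
scores are comparable across contours of different durations.  Among paths
of equal (minimal) total cost the shortest is used, which makes the value a
deterministic, well-defined function of the pair.

The all-pairs computation over a collection of n contours performs the
n(n-1)/2 pairwise alignments (a 9013-call data set entails the order of
(9013 x 9013)/2 comparisons) and is accelerated with numba when available;
a pure-numpy fallback keeps small problems runnable anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contour_core import ContourCollection, FrequencyContour

__all__ = [
    "DistanceMatrix",
    "mean_subtract",
    "dtw_mse",
    "all_pairs",
    "n_comparisons",
    "save_distances",
    "load_distances",
]

try:  # optional JIT acceleration
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class DistanceMatrix:
    """Symmetric all-to-all dissimilarity over an ordered contour collection.

    ``condensed`` stores the upper triangle row-major (scipy
    ``squareform`` convention); ``square()`` materializes the full matrix.
    Row/column ``i`` refers to ``syllable_order[i]``.
    """

    n: int
    condensed: np.ndarray
    syllable_order: list[str]

    def __post_init__(self) -> None:
        expected = self.n * (self.n - 1) // 2
        if self.condensed.shape != (expected,):
            raise ValueError(
                f"condensed length {self.condensed.shape} != n(n-1)/2 = {expected}"
            )
        if len(self.syllable_order) != self.n:
            raise ValueError("syllable_order length mismatch")
        if len(set(self.syllable_order)) != self.n:
            raise ValueError("duplicate syllable ids in syllable_order")
        if not np.all(np.isfinite(self.condensed)) or np.any(self.condensed < 0):
            raise ValueError("distances must be finite and >= 0")

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        if self.n == 1:
            return np.zeros((1, 1))
        return squareform(self.condensed)

    @property
    def n_comparisons(self) -> int:
        return self.n * (self.n - 1) // 2


def n_comparisons(n: int) -> int:
    """Number of pairwise alignments for an n-contour collection."""
    return n * (n - 1) // 2


def mean_subtract(c: FrequencyContour) -> FrequencyContour:
    """Subtract the contour's mean frequency (output samples sum to ~0).

    Returns a contour-like object; note the result intentionally bypasses the
    positive-frequency invariant of raw contours.
    """
    centered = c.frequencies - c.frequencies.mean()
    out = object.__new__(FrequencyContour)
    for name in ("syllable_id", "individual_id", "group", "start_time", "hop", "clipped"):
        object.__setattr__(out, name, getattr(c, name))
    object.__setattr__(out, "frequencies", centered)
    return out


# ---------------------------------------------------------------------------
# DTW core: lexicographic (total cost, path length) dynamic program
# ---------------------------------------------------------------------------

def _dtw_py(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.size, b.size
    big = np.inf
    cost = np.full((n + 1, m + 1), big)
    plen = np.zeros((n + 1, m + 1), dtype=np.int64)
    cost[0, 0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            d = ai - b[j - 1]
            d *= d
            c_diag, c_up, c_left = cost[i - 1, j - 1], cost[i - 1, j], cost[i, j - 1]
            best = min(c_diag, c_up, c_left)
            best_len = big
            if c_diag == best:
                best_len = plen[i - 1, j - 1]
            if c_up == best and plen[i - 1, j] < best_len:
                best_len = plen[i - 1, j]
            if c_left == best and plen[i, j - 1] < best_len:
                best_len = plen[i, j - 1]
            cost[i, j] = best + d
            plen[i, j] = best_len + 1
    return cost[n, m] / plen[n, m]


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _dtw_nb(a, b):  # pragma: no cover - exercised via dtw_mse
        n, m = a.size, b.size
        cost = np.full((n + 1, m + 1), np.inf)
        plen = np.zeros((n + 1, m + 1), dtype=np.int64)
        cost[0, 0] = 0.0
        for i in range(1, n + 1):
            ai = a[i - 1]
            for j in range(1, m + 1):
                d = ai - b[j - 1]
                d *= d
                c_diag = cost[i - 1, j - 1]
                c_up = cost[i - 1, j]
                c_left = cost[i, j - 1]
                best = c_diag
                if c_up < best:
                    best = c_up
                if c_left < best:
                    best = c_left
                best_len = np.int64(2 ** 62)
                if c_diag == best and plen[i - 1, j - 1] < best_len:
                    best_len = plen[i - 1, j - 1]
                if c_up == best and plen[i - 1, j] < best_len:
                    best_len = plen[i - 1, j]
                if c_left == best and plen[i, j - 1] < best_len:
                    best_len = plen[i, j - 1]
                cost[i, j] = best + d
                plen[i, j] = best_len + 1
        return cost[n, m] / plen[n, m]

    @numba.njit(cache=True, parallel=True)
    def _all_pairs_nb(data, lengths, out):  # pragma: no cover
        n = lengths.size
        for i in numba.prange(n - 1):
            a = data[i, : lengths[i]]
            # condensed offset for row i
            base = i * n - (i * (i + 1)) // 2 - (i + 1)
            for j in range(i + 1, n):
                out[base + j] = _dtw_nb(a, data[j, : lengths[j]])


def dtw_mse(a, b) -> float:
    """DTW mean-squared-error dissimilarity between two contours (kHz²).

    Accepts :class:`FrequencyContour` objects or plain 1-D arrays of
    (mean-subtracted) frequency samples.  Zero iff the two sequences are
    repetition-equivalent under monotone warping; symmetric by construction.
    """
    fa = np.asarray(a.frequencies if hasattr(a, "frequencies") else a, dtype=float)
    fb = np.asarray(b.frequencies if hasattr(b, "frequencies") else b, dtype=float)
    if fa.size < 2 or fb.size < 2:
        raise ValueError("contours must have >= 2 samples")
    if _HAVE_NUMBA:
        return float(_dtw_nb(fa, fb))
    return float(_dtw_py(fa, fb))


def all_pairs(
    collection: ContourCollection, mean_subtracted: bool = False
) -> DistanceMatrix:
    """All-to-all DTW-MSE distances over the non-clipped contours.

    Contours are mean-frequency subtracted first (unless the caller already
    did so).  Exactly n(n-1)/2 alignments are performed; the result is
    deterministic and symmetric with zero diagonal.
    """
    coll = collection.non_clipped()
    n = len(coll)
    if n < 2:
        raise ValueError("need >= 2 non-clipped contours")
    lengths = np.array([c.n_samples for c in coll], dtype=np.int64)
    data = np.zeros((n, int(lengths.max())), dtype=float)
    for i, c in enumerate(coll):
        f = c.frequencies.astype(float)
        if not mean_subtracted:
            f = f - f.mean()
        data[i, : f.size] = f
    condensed = np.empty(n * (n - 1) // 2, dtype=float)
    if _HAVE_NUMBA:
        _all_pairs_nb(data, lengths, condensed)
    else:
        k = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                condensed[k] = _dtw_py(data[i, : lengths[i]], data[j, : lengths[j]])
                k += 1
    return DistanceMatrix(
        n=n,
        condensed=condensed,
        syllable_order=[c.syllable_id for c in coll],
    )


# ---------------------------------------------------------------------------
# persistence: dense binary condensed array + JSON sidecar
# ---------------------------------------------------------------------------

def save_distances(d: DistanceMatrix, path: str | Path) -> Path:
    """Write the condensed matrix (float32 ``.npy``) plus a JSON sidecar."""
    path = Path(path)
    np.save(path, d.condensed.astype(np.float32))
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    sidecar = npy.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"n": d.n, "syllable_order": d.syllable_order}, fh)
    return npy


def load_distances(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(path.suffix + ".npy")
    condensed = np.load(path).astype(float)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return DistanceMatrix(
        n=int(meta["n"]),
        condensed=condensed,
        syllable_order=list(meta["syllable_order"]),
    )
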