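"""Sequence alignment: DTW, adaptive-penalty ACDTW, and multi-resolution QAQA.

Classic DTW fills the full ``a x b`` cumulative-cost matrix. ACDTW modifies
the recursion with a penalty on non-diagonal (singularity-producing) steps:

    ACDTW(i, j) = MED(i, j) + min( ACDTW(i-1, j-1),
                                   ACDTW(i-1, j) + C * MED(i, j),
                                   ACDTW(i, j-1) + C * MED(i, j) )

with the constant penalty factor ``C = 2 * max(a, b) / (a + b)`` (so C = 1
for equal lengths and grows with length imbalance). ``MED`` is the
Euclidean distance between 27-D feature frames by default.

QAQA makes this linear in sequence length: coarsen both sequences by
averaging adjacent frame pairs until a minimum length, align at the coarse
level, project the warp path up one resolution (each coarse cell maps to a
2 x 2 block), dilate the projected path by ``radius`` cells, and run ACDTW
restricted to that search window. Cell counts are accumulated across
levels, giving O(n * radius) total work.

All path indices are 1-based, matching the recurrence above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureSequence

__all__ = [
    "WarpPath",
    "SearchWindow",
    "AlignmentResult",
    "QaqaConfig",
    "med",
    "penalty_factor",
    "dtw",
    "acdtw",
    "coarsen",
    "expand_window",
    "qaqa_align",
]


@dataclass
class WarpPath:
    """Monotone alignment path: 1-based (i, j) pairs from (1, 1) to (a, b)."""

    pairs: list[tuple[int, int]]

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, a: int, b: int) -> None:
        if not self.pairs:
            raise ValueError("empty warp path")
        if self.pairs[0] != (1, 1) or self.pairs[-1] != (a, b):
            raise ValueError(f"path must run (1,1) -> ({a},{b}); got {self.pairs[0]} -> {self.pairs[-1]}")
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if (i1 - i0, j1 - j0) not in ((1, 0), (0, 1), (1, 1)):
                raise ValueError(f"illegal step ({i0},{j0}) -> ({i1},{j1})")


@dataclass
class SearchWindow:
    """Per-row inclusive column ranges ``[lo[i], hi[i]]``, 1-based."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=int)
        self.hi = np.asarray(self.hi, dtype=int)

    @property
    def n_rows(self) -> int:
        return len(self.lo)

    def n_cells(self) -> int:
        return int(np.sum(self.hi - self.lo + 1))

    def validate(self, a: int, b: int) -> None:
        if self.n_rows != a or len(self.hi) != a:
            raise ValueError(f"window has {self.n_rows} rows, expected {a}")
        if np.any(self.lo < 1) or np.any(self.hi > b) or np.any(self.lo > self.hi):
            raise ValueError("window ranges must be non-empty and inside [1, b]")
        if self.lo[0] != 1 or self.hi[-1] != b:
            raise ValueError("window must contain (1, 1) and (a, b)")

    def contains(self, i: int, j: int) -> bool:
        """1-based membership test."""
        return 1 <= i <= self.n_rows and self.lo[i - 1] <= j <= self.hi[i - 1]


@dataclass
class AlignmentResult:
    """Alignment distance, warp path, and evaluated-cell accounting."""

    distance: float
    path: WarpPath
    cells_computed: int
    levels: int = 1


@dataclass(frozen=True)
class QaqaConfig:
    """Multi-resolution alignment tunables.

    ``radius`` dilates the projected coarse path at each refinement (larger
    = closer to full ACDTW, more cells). ``min_size`` is the sequence length
    at which recursion bottoms out in a full ACDTW (default ``radius + 2``).
    """

    radius: int = 10
    min_size: int | None = None
    distance_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.min_size is not None and self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.distance_metric not in ("euclidean", "manhattan"):
            raise ValueError("distance_metric must be 'euclidean' or 'manhattan'")

    @property
    def effective_min_size(self) -> int:
        return self.radius + 2 if self.min_size is None else self.min_size


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureSequence):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("sequence must be a non-empty (n, d) array")
    return X


def med(f1: np.ndarray, f2: np.ndarray, metric: str = "euclidean") -> float:
    """Frame-to-frame distance (Euclidean by default) between feature vectors."""
    f1 = np.asarray(f1, dtype=float).ravel()
    f2 = np.asarray(f2, dtype=float).ravel()
    if f1.shape != f2.shape:
        raise ValueError(f"dimension mismatch: {f1.shape} vs {f2.shape}")
    d = f1 - f2
    return float(np.abs(d).sum()) if metric == "manhattan" else float(np.linalg.norm(d))


def penalty_factor(a: int, b: int) -> float:
    """Constant non-diagonal step penalty ``C = 2 * max(a, b) / (a + b)``."""
    return 2.0 * max(a, b) / (a + b)


def _med_matrix(X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
    return cdist(X, Y, metric="cityblock" if metric == "manhattan" else "euclidean")


# ---------------------------------------------------------------------------
# Full-matrix dynamic program (vectorised over anti-diagonals)
# ---------------------------------------------------------------------------


def _full_dp(medM: np.ndarray, C: float) -> np.ndarray:
    a, b = medM.shape
    D = np.full((a, b), np.inf)
    D[0, 0] = medM[0, 0]
    for k in range(1, a + b - 1):
        i = np.arange(max(0, k - b + 1), min(a - 1, k) + 1)
        j = k - i
        m = medM[i, j]
        best = np.full(len(i), np.inf)
        has_diag = (i > 0) & (j > 0)
        if has_diag.any():
            np.minimum(best, np.where(has_diag, D[i - 1, j - 1], np.inf), out=best)
        has_up = i > 0
        if has_up.any():
            np.minimum(best, np.where(has_up, D[i - 1, j] + C * m, np.inf), out=best)
        has_left = j > 0
        if has_left.any():
            np.minimum(best, np.where(has_left, D[i, j - 1] + C * m, np.inf), out=best)
        D[i, j] = m + best
    return D


def _backtrack_full(D: np.ndarray, medM: np.ndarray, C: float) -> WarpPath:
    a, b = D.shape
    i, j = a - 1, b - 1
    pairs = [(a, b)]
    while (i, j) != (0, 0):
        m = medM[i, j]
        cand_diag = D[i - 1, j - 1] if i > 0 and j > 0 else math.inf
        cand_up = D[i - 1, j] + C * m if i > 0 else math.inf
        cand_left = D[i, j - 1] + C * m if j > 0 else math.inf
        best = min(cand_diag, cand_up, cand_left)
        # tie preference: diagonal, then vertical, then horizontal --
        # minimises singularities and keeps paths deterministic
        if cand_diag == best:
            i, j = i - 1, j - 1
        elif cand_up == best:
            i -= 1
        else:
            j -= 1
        pairs.append((i + 1, j + 1))
    pairs.reverse()
    return WarpPath(pairs)


# ---------------------------------------------------------------------------
# Windowed dynamic program (sparse per-row storage)
# ---------------------------------------------------------------------------


def _windowed_dp(
    X: np.ndarray, Y: np.ndarray, window: SearchWindow, C: float, metric: str
) -> tuple[float, WarpPath, int]:
    a, b = len(X), len(Y)
    lo = window.lo - 1  # 0-based
    hi = window.hi - 1
    mname = "cityblock" if metric == "manhattan" else "euclidean"
    D_rows: list[np.ndarray] = []
    med_rows: list[np.ndarray] = []
    cells = 0
    for i in range(a):
        l, h = lo[i], hi[i]
        m_row = cdist(X[i : i + 1], Y[l : h + 1], metric=mname)[0]
        D_row = np.full(h - l + 1, np.inf)
        cells += h - l + 1
        for idx, j in enumerate(range(l, h + 1)):
            m = m_row[idx]
            if i == 0 and j == 0:
                D_row[idx] = m
                continue
            best = math.inf
            if i > 0:
                pl, ph = lo[i - 1], hi[i - 1]
                if pl <= j - 1 <= ph:  # diagonal
                    v = D_rows[i - 1][j - 1 - pl]
                    if v < best:
                        best = v
                if pl <= j <= ph:  # vertical
                    v = D_rows[i - 1][j - pl] + C * m
                    if v < best:
                        best = v
            if j - 1 >= l:  # horizontal
                v = D_row[idx - 1] + C * m
                if v < best:
                    best = v
            D_row[idx] = m + best
        D_rows.append(D_row)
        med_rows.append(m_row)
    dist = float(D_rows[-1][b - 1 - lo[-1]])
    if not math.isfinite(dist):
        raise ValueError("search window admits no monotone path from (1,1) to (a,b)")

    # backtrack with the same candidate preference as the full-matrix case
    i, j = a - 1, b - 1
    pairs = [(a, b)]
    while (i, j) != (0, 0):
        m = med_rows[i][j - lo[i]]
        cand_diag = cand_up = cand_left = math.inf
        if i > 0:
            pl, ph = lo[i - 1], hi[i - 1]
            if pl <= j - 1 <= ph:
                cand_diag = D_rows[i - 1][j - 1 - pl]
            if pl <= j <= ph:
                cand_up = D_rows[i - 1][j - pl] + C * m
        if j - 1 >= lo[i]:
            cand_left = D_rows[i][j - 1 - lo[i]] + C * m
        best = min(cand_diag, cand_up, cand_left)
        if cand_diag == best:
            i, j = i - 1, j - 1
        elif cand_up == best:
            i -= 1
        else:
            j -= 1
        pairs.append((i + 1, j + 1))
    pairs.reverse()
    return dist, WarpPath(pairs), cells


def _adaptive_dp(X: np.ndarray, Y: np.ndarray, C: float, metric: str) -> tuple[float, WarpPath, int]:
    """Match-count penalty variant: the penalty scales with how many times
    the repeated point has already been matched along the incoming path.

    Optional research mode (``penalty='adaptive'``); the constant-penalty
    form is the default and the one used everywhere else in the package.
    """
    a, b = len(X), len(Y)
    medM = _med_matrix(X, Y, metric)
    D = np.full((a, b), np.inf)
    runs_v = np.zeros((a, b), dtype=int)  # consecutive vertical steps into the cell
    runs_h = np.zeros((a, b), dtype=int)
    choice = np.zeros((a, b), dtype=np.int8)
    D[0, 0] = medM[0, 0]
    for i in range(a):
        for j in range(b):
            if i == 0 and j == 0:
                continue
            m = medM[i, j]
            cand_diag = D[i - 1, j - 1] if i > 0 and j > 0 else math.inf
            cand_up = D[i - 1, j] + C * (runs_v[i - 1, j] + 1) * m if i > 0 else math.inf
            cand_left = D[i, j - 1] + C * (runs_h[i, j - 1] + 1) * m if j > 0 else math.inf
            best = min(cand_diag, cand_up, cand_left)
            if cand_diag == best:
                choice[i, j] = 0
            elif cand_up == best:
                choice[i, j] = 1
                runs_v[i, j] = runs_v[i - 1, j] + 1
            else:
                choice[i, j] = 2
                runs_h[i, j] = runs_h[i, j - 1] + 1
            D[i, j] = m + best
    i, j = a - 1, b - 1
    pairs = [(a, b)]
    while (i, j) != (0, 0):
        c = choice[i, j]
        if c == 0:
            i, j = i - 1, j - 1
        elif c == 1:
            i -= 1
        else:
            j -= 1
        pairs.append((i + 1, j + 1))
    pairs.reverse()
    return float(D[a - 1, b - 1]), WarpPath(pairs), a * b


# ---------------------------------------------------------------------------
# Public alignment operations
# ---------------------------------------------------------------------------


def dtw(X, Y, metric: str = "euclidean") -> AlignmentResult:
    """Classic full-matrix DTW (comparison baseline, no step penalty)."""
    X, Y = _as_matrix(X), _as_matrix(Y)
    medM = _med_matrix(X, Y, metric)
    D = _full_dp(medM, 0.0)
    path = _backtrack_full(D, medM, 0.0)
    return AlignmentResult(float(D[-1, -1]), path, X.shape[0] * Y.shape[0])


def acdtw(
    X,
    Y,
    window: SearchWindow | None = None,
    metric: str = "euclidean",
    penalty: str = "constant",
) -> AlignmentResult:
    """Adaptive-penalty DTW, optionally restricted to a search window.

    Cells outside the window are treated as unreachable (+inf). The
    ``cells_computed`` field counts exactly the evaluated cost cells.
    """
    X, Y = _as_matrix(X), _as_matrix(Y)
    a, b = X.shape[0], Y.shape[0]
    C = penalty_factor(a, b)
    if penalty == "adaptive":
        if window is not None:
            raise ValueError("adaptive penalty supports full-matrix alignment only")
        dist, path, cells = _adaptive_dp(X, Y, C, metric)
        return AlignmentResult(dist, path, cells)
    if window is None:
        medM = _med_matrix(X, Y, metric)
        D = _full_dp(medM, C)
        return AlignmentResult(float(D[-1, -1]), _backtrack_full(D, medM, C), a * b)
    window.validate(a, b)
    dist, path, cells = _windowed_dp(X, Y, window, C, metric)
    return AlignmentResult(dist, path, cells)


def coarsen(F):
    """Halve temporal resolution by averaging adjacent frame pairs.

    ``out[k] = (F[2k] + F[2k+1]) / 2``; an odd trailing frame is kept
    as-is, so the output length is ``ceil(n / 2)``.
    """
    is_fs = isinstance(F, FeatureSequence)
    V = F.values if is_fs else np.asarray(F, dtype=float)
    n = V.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames to coarsen")
    half = n // 2
    out = (V[0 : 2 * half : 2] + V[1 : 2 * half : 2]) / 2.0
    if n % 2:
        out = np.vstack([out, V[-1:]])
    return FeatureSequence(out, F.fps, F.names) if is_fs else out


def expand_window(path: WarpPath, a: int, b: int, radius: int) -> SearchWindow:
    """Project a half-resolution warp path to full resolution and dilate it.

    Each coarse cell (i, j) maps to the 2 x 2 full-resolution block
    {2i-1, 2i} x {2j-1, 2j}; the block set is then dilated by ``radius``
    cells in every (Chebyshev) direction and clipped to [1, a] x [1, b],
    stored as contiguous per-row column ranges.
    """
    if not len(path):
        raise ValueError("empty warp path")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n_rows_proj = 2 * path.pairs[-1][0]
    lo0 = np.full(n_rows_proj, np.iinfo(np.int64).max, dtype=np.int64)
    hi0 = np.full(n_rows_proj, np.iinfo(np.int64).min, dtype=np.int64)
    for i, j in path.pairs:
        for r in (2 * i - 2, 2 * i - 1):  # 0-based projected rows
            lo0[r] = min(lo0[r], 2 * j - 1)
            hi0[r] = max(hi0[r], 2 * j)
    # Chebyshev dilation: take min/max over the +-radius row band, widen
    # columns by radius
    lo_d = lo0.copy()
    hi_d = hi0.copy()
    for off in range(1, radius + 1):
        lo_d[off:] = np.minimum(lo_d[off:], lo0[:-off])
        lo_d[:-off] = np.minimum(lo_d[:-off], lo0[off:])
        hi_d[off:] = np.maximum(hi_d[off:], hi0[:-off])
        hi_d[:-off] = np.maximum(hi_d[:-off], hi0[off:])
    lo_d = lo_d - radius
    hi_d = hi_d + radius
    lo = np.clip(lo_d[:a], 1, b)
    hi = np.clip(hi_d[:a], 1, b)
    if len(lo) < a:  # path shorter than ceil(a/2) rows cannot happen for valid paths
        raise ValueError("projected path does not cover all rows")
    win = SearchWindow(lo, hi)
    win.validate(a, b)
    return win


def qaqa_align(X, Y, config: QaqaConfig | None = None) -> AlignmentResult:
    """Multi-resolution ACDTW: coarsen, align, project, refine.

    Recursion bottoms out in a full ACDTW once either sequence is no longer
    than ``min_size``; above that, the coarse path is projected up and
    ACDTW runs inside the radius-dilated window. ``cells_computed`` sums
    evaluated cells over all levels; ``levels`` counts them.
    """
    config = config or QaqaConfig()
    X, Y = _as_matrix(X), _as_matrix(Y)
    a, b = X.shape[0], Y.shape[0]
    if min(a, b) <= config.effective_min_size:
        return acdtw(X, Y, metric=config.distance_metric)
    sub = qaqa_align(coarsen(X), coarsen(Y), config)
    window = expand_window(sub.path, a, b, config.radius)
    res = acdtw(X, Y, window=window, metric=config.distance_metric)
    res.cells_computed += sub.cells_computed
    res.levels = sub.levels + 1
    return res
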