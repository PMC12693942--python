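"""Scoring-accuracy metrics and the alignment scaling benchmark.

Metrics follow the usual action-quality-assessment conventions: Spearman
rank correlation between true and predicted scores, plus MAE, relative MAE
(normalised by the true score) and MSE. The benchmark harness measures
evaluated-cell counts (hardware independent) and wall time (informational)
for DTW, full ACDTW and QAQA across sequence lengths and radii.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
from scipy import stats

from . import alignment, synthetic
from .features import build_features

__all__ = ["spearman", "mae", "rmae", "mse", "scaling_benchmark", "loglog_slope"]


def _check(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def spearman(y, y_hat) -> float:
    """Spearman rank correlation; ties get average ranks."""
    y, y_hat = _check(y, y_hat)
    if len(y) < 2:
        raise ValueError("Spearman needs at least 2 samples")
    return float(stats.spearmanr(y, y_hat).statistic)


def mae(y, y_hat) -> float:
    y, y_hat = _check(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def rmae(y, y_hat) -> float:
    """Mean absolute error relative to the true score; y must be nonzero."""
    y, y_hat = _check(y, y_hat)
    if np.any(y == 0):
        raise ValueError("RMAE undefined for zero true scores")
    return float(np.mean(np.abs(y - y_hat) / np.abs(y)))


def mse(y, y_hat) -> float:
    y, y_hat = _check(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def scaling_benchmark(
    lengths: list[int],
    radii: list[int] = (10,),
    seed: int = 0,
    algorithms: tuple[str, ...] = ("dtw", "acdtw", "qaqa"),
    n_seeds: int = 1,
) -> pd.DataFrame:
    """Cells/time table over synthetic warped pairs.

    Returns one row per (algorithm, n, radius, seed) with the
    ``cells_computed`` accounting and elapsed seconds. Wall time depends on
    the machine and is reported but never asserted anywhere.
    """
    if list(lengths) != sorted(lengths):
        raise ValueError("lengths must be sorted ascending")
    rows = []
    for n in lengths:
        for s in range(n_seeds):
            template, test, _ = synthetic.make_pair("warped", n_frames=n, seed=seed + s)
            F1 = build_features(template)
            F2 = build_features(test)
            if "dtw" in algorithms:
                t0 = time.perf_counter()
                res = alignment.dtw(F1, F2)
                rows.append(("dtw", n, None, seed + s, res.cells_computed, time.perf_counter() - t0))
            if "acdtw" in algorithms:
                t0 = time.perf_counter()
                res = alignment.acdtw(F1, F2)
                rows.append(("acdtw", n, None, seed + s, res.cells_computed, time.perf_counter() - t0))
            if "qaqa" in algorithms:
                for r in radii:
                    t0 = time.perf_counter()
                    res = alignment.qaqa_align(F1, F2, alignment.QaqaConfig(radius=r))
                    rows.append(("qaqa", n, r, seed + s, res.cells_computed, time.perf_counter() - t0))
    return pd.DataFrame(rows, columns=["algorithm", "n", "radius", "seed", "cells_computed", "seconds"])


def loglog_slope(ns, cells) -> float:
    """Least-squares exponent of cells vs n (the empirical scaling order)."""
    ns = np.asarray(ns, dtype=float)
    cells = np.asarray(cells, dtype=float)
    return float(np.polyfit(np.log(ns), np.log(cells), 1)[0])
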