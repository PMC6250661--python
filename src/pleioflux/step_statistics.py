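"""Randomization test linking knockout pleiotropy to step counts.

A gene's full-knockout pleiotropy bounds its number of stepwise pleiotropy
increases from above. Under the null hypothesis that, apart from this
bound, step counts carry no information about knockout pleiotropy, each
gene's step count is uniform on the integers {0, ..., max pleiotropy}. The
test draws many such datasets, computes the Spearman rank correlation
between knockout pleiotropy and steps for each, and reports the fraction of
null correlations at least as large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["StepTestResult", "spearman_rho", "step_randomization_test"]


@dataclass
class StepTestResult:
    rho: float
    n_genes: int
    n_rand: int
    p: float
    null_mean: float
    null_sd: float
    null_max: float
    seed: int


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN when either input has zero variance (the coefficient is
    undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def _null_rho_batch(
    rank_x: np.ndarray, maxp: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Spearman rho for `size` null datasets, vectorized over rows."""
    draws = rng.integers(0, maxp + 1, size=(size, len(maxp)))
    ry = stats.rankdata(draws, axis=1)
    rx_c = rank_x - rank_x.mean()
    denom_x = np.sqrt((rx_c**2).sum())
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((ry_c**2).sum(axis=1))
    num = ry_c @ rx_c
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / (denom_x * denom_y)
    # a draw with all-tied steps has undefined rho; it cannot beat any
    # positive observed correlation, score it as 0
    return np.where(np.isfinite(rho), rho, 0.0)


def step_randomization_test(
    max_pleiotropies: Sequence[int],
    steps: Sequence[int],
    n_rand: int = 1_000_000,
    seed: int = 0,
    include_zero_max: bool = False,
    chunk: int = 50_000,
) -> StepTestResult:
    """Empirical test of the pleiotropy--steps rank correlation.

    Genes with zero knockout pleiotropy are excluded by default: both of
    their variables are forced to zero, so they only add ties.
    ``p = (1 + #{null rho >= observed rho}) / (1 + n_rand)``.
    """
    maxp = np.asarray(max_pleiotropies, dtype=int)
    st = np.asarray(steps, dtype=int)
    if maxp.shape != st.shape:
        raise ValueError("inputs must align gene by gene")
    bad = np.nonzero(st > maxp)[0]
    if bad.size:
        raise ValueError(
            f"step count exceeds knockout pleiotropy at gene indices {bad.tolist()}"
        )
    if not include_zero_max:
        keep = maxp > 0
        maxp, st = maxp[keep], st[keep]
    if len(maxp) < 3:
        raise ValueError("need at least 3 genes with nonzero knockout pleiotropy")

    rho_obs = spearman_rho(maxp, st)
    obs_defined = np.isfinite(rho_obs)
    rank_x = stats.rankdata(maxp)

    rng = np.random.default_rng(seed)
    n_ge = 0
    total = 0.0
    total_sq = 0.0
    null_max = -np.inf
    remaining = n_rand
    while remaining > 0:
        size = min(chunk, remaining)
        rho = _null_rho_batch(rank_x, maxp, size, rng)
        n_ge += int(np.sum(rho >= rho_obs))
        total += float(rho.sum())
        total_sq += float((rho**2).sum())
        null_max = max(null_max, float(rho.max()))
        remaining -= size
    mean = total / n_rand
    var = max(total_sq / n_rand - mean**2, 0.0)
    return StepTestResult(
        rho=rho_obs,
        n_genes=len(maxp),
        n_rand=n_rand,
        p=(1 + n_ge) / (1 + n_rand) if obs_defined else float("nan"),
        null_mean=mean,
        null_sd=float(np.sqrt(var)),
        null_max=null_max,
        seed=seed,
    )
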