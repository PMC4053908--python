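"""Inter-model comparison statistics.

Summary tables, Bland-Altman limits of agreement, Spearman correlation,
polynomial relation fits, Wilcoxon signed-rank and Fisher-Pitman
permutation tests, and validation of a raster against point measurements.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .models import ComparisonResult, ConcentrationGrid


def summarize(values: Sequence[float]) -> dict:
    """n, mean, sd, min, p5, median, p95, max (sample SD, linear-interp percentiles)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    out = {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "p5": float(np.percentile(v, 5)),
        "median": float(np.median(v)),
        "p95": float(np.percentile(v, 95)),
        "max": float(v.max()),
        "sd_defined": v.size > 1,
    }
    return out


def bland_altman(a: Sequence[float], b: Sequence[float]) -> dict:
    """Paired differences b - a: mean, sample SD and limits mean ± 2*SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length pairs with n >= 2")
    d = b - a
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return {
        "n": int(a.size),
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_low": mean_diff - 2.0 * sd_diff,
        "loa_high": mean_diff + 2.0 * sd_diff,
        "mean_of_pairs": (a + b) / 2.0,
        "diffs": d,
    }


def polynomial_relation(
    a: Sequence[float], b: Sequence[float], max_degree: int = 3
) -> tuple[int, dict[int, float], dict[int, np.ndarray]]:
    """Least-squares fits of b on polynomials of a, degrees 1..max_degree.

    Returns (best degree, {degree: R^2}, {degree: coefficients}).  "Best"
    is the lowest degree after which the R^2 gain over the previous degree
    never exceeds 0.01.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size <= max_degree + 1:
        raise ValueError(f"need n > max_degree + 1 = {max_degree + 1}")
    sst = float(np.sum((b - b.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has zero variance")
    r2: dict[int, float] = {}
    coefs: dict[int, np.ndarray] = {}
    for deg in range(1, max_degree + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            c = np.polyfit(a, b, deg)
        pred = np.polyval(c, a)
        r2[deg] = 1.0 - float(np.sum((b - pred) ** 2)) / sst
        coefs[deg] = c
    best = 1
    for deg in range(2, max_degree + 1):
        if r2[deg] - r2[deg - 1] > 0.01:
            best = deg
        else:
            break
    return best, r2, coefs


def spearman(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation, average ranks on ties."""
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact null distribution for n <= 25 nonzero differences; normal
    approximation with continuity correction above.  All-zero differences
    give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b - a
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p-value defined as 1")
        return 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= 25 and not has_ties:
        method = "exact"
        res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    else:
        res = stats.wilcoxon(
            nz, alternative="two-sided", method="approx", correction=True
        )
    return float(min(res.pvalue, 1.0))


def _sd_gap(a: np.ndarray, b: np.ndarray) -> float:
    return abs(a.std(ddof=1) - b.std(ddof=1))


def fisher_pitman(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = None,
    statistic: Callable[[np.ndarray, np.ndarray], float] = _sd_gap,
) -> float:
    """Permutation test of a paired difference in spread.

    The default statistic is |SD(a) - SD(b)|; the null is built by
    randomly swapping pair members.  Monte-Carlo p-value:
    (1 + #{perm >= observed}) / (1 + n_perm).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length pairs with n >= 2")
    rng = np.random.default_rng(seed)
    obs = statistic(a, b)
    n = a.size
    if statistic is _sd_gap:
        # vectorised fast path for the default statistic
        count = 0
        chunk = max(1, min(n_perm, 2_000_000 // max(n, 1)))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            swap = rng.random((m, n)) < 0.5
            pa = np.where(swap, b, a)
            pb = np.where(swap, a, b)
            gap = np.abs(pa.std(ddof=1, axis=1) - pb.std(ddof=1, axis=1))
            count += int(np.count_nonzero(gap >= obs - 1e-15))
            done += m
        return (1 + count) / (1 + n_perm)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        if statistic(pa, pb) >= obs - 1e-15:
            count += 1
    return (1 + count) / (1 + n_perm)


def validate_against_points(
    grid: ConcentrationGrid, sites: Sequence[tuple[float, float]], measured: Sequence[float]
) -> float:
    """R^2 of grid-cell values against point measurements across sites."""
    if len(sites) != len(measured) or len(sites) < 3:
        raise ValueError("need >= 3 sites with one measurement each")
    predicted = np.array([grid.value_at(x, y) for x, y in sites])
    measured = np.asarray(measured, dtype=float)
    if np.var(predicted) == 0 or np.var(measured) == 0:
        raise ValueError("zero variance in predictions or measurements")
    res = stats.linregress(predicted, measured)
    return float(res.rvalue**2)


def compare_pair(
    name_a: str,
    name_b: str,
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = None,
) -> ComparisonResult:
    """All paired statistics for one model pair (differences are b - a)."""
    ba = bland_altman(a, b)
    best, r2, _ = polynomial_relation(a, b)
    return ComparisonResult(
        model_a=name_a,
        model_b=name_b,
        n=ba["n"],
        mean_diff=ba["mean_diff"],
        sd_diff=ba["sd_diff"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        spearman_rho=spearman(a, b),
        fit_degree=best,
        fit_r2=r2,
        wilcoxon_p=wilcoxon_signed_rank(a, b),
        fisher_pitman_p=fisher_pitman(a, b, n_perm=n_perm, seed=seed),
    )
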