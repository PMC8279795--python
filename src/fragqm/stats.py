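"""Paired-outcome symmetry testing for quality-measure transition tables.

The paired origin-scope vs all-sources outcome of each (patient, measure)
calculation lands in a k×k transition table.  Under the null hypothesis that
adding external data shifts outcomes in no preferred direction, the table is
symmetric: for every unordered pair of distinct outcomes (i, j), a discordant
calculation is equally likely to move i→j as j→i.  The test statistic is the
Bowker-type quantity

    T = Σ_{i<j, n_ij+n_ji>0} (n_ij − n_ji)² / (n_ij + n_ji)

which reduces to McNemar's (b−c)²/(b+c) for two categories.  The asymptotic
reference distribution is χ² with one degree of freedom per contributing
pair; for the sparse per-measure tables a Monte Carlo test is provided that
resamples each pair's discordant units as fair coin flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SymmetryTestResult",
    "symmetry_statistic",
    "asymptotic_symmetry_test",
    "monte_carlo_symmetry_test",
    "bh_fdr",
]


class TestMethod(str, Enum):
    ASYMPTOTIC = "asymptotic"
    MONTE_CARLO = "monte_carlo"


@dataclass(frozen=True)
class SymmetryTestResult:
    statistic: float
    dof: int
    p_value: float
    method: TestMethod
    n_resamples: int | None = None
    seed: int | None = None


def _as_square(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"transition table must be square, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("transition table counts must be non-negative")
    return arr


def _pair_counts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal counts (n_ij, n_ji) for unordered pairs i<j with any mass."""
    k = arr.shape[0]
    iu, ju = np.triu_indices(k, k=1)
    a = arr[iu, ju]
    b = arr[ju, iu]
    mask = (a + b) > 0
    return a[mask], b[mask]


def symmetry_statistic(table: np.ndarray) -> tuple[float, int]:
    """Bowker-type symmetry statistic and its degrees of freedom.

    Pairs with no discordant mass contribute nothing and no degrees of
    freedom.  A table with no off-diagonal mass has statistic 0 and dof 0
    (its p-value is defined as 1).
    """
    arr = _as_square(table)
    a, b = _pair_counts(arr)
    if a.size == 0:
        return 0.0, 0
    stat = float(np.sum((a - b) ** 2 / (a + b)))
    return stat, int(a.size)


def asymptotic_symmetry_test(table: np.ndarray) -> SymmetryTestResult:
    """χ² symmetry test; valid when discordant counts are reasonably large."""
    stat, dof = symmetry_statistic(table)
    p = 1.0 if dof == 0 else float(sps.chi2.sf(stat, dof))
    return SymmetryTestResult(stat, dof, p, TestMethod.ASYMPTOTIC)


def monte_carlo_symmetry_test(
    table: np.ndarray, n_resamples: int = 2000, seed: int | None = None
) -> SymmetryTestResult:
    """Monte Carlo symmetry test for sparse transition tables.

    Null model: within each unordered outcome pair the direction of every
    discordant unit is a fair coin flip, so each pair's i→j count is resampled
    as Binomial(n_ij+n_ji, ½) with the total held fixed.  The p-value uses the
    add-one correction p = (1 + #{T* ≥ T}) / (1 + B), which avoids p = 0 and
    keeps the test level-valid.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    arr = _as_square(table)
    a, b = _pair_counts(arr)
    if a.size == 0:
        return SymmetryTestResult(
            0.0, 0, 1.0, TestMethod.MONTE_CARLO, n_resamples=n_resamples, seed=seed
        )
    totals = a + b
    obs = float(np.sum((a - b) ** 2 / totals))
    rng = np.random.default_rng(seed)
    sim_a = rng.binomial(totals.astype(np.int64), 0.5, size=(n_resamples, totals.size))
    sim_stats = np.sum((2 * sim_a - totals) ** 2 / totals, axis=1)
    # tolerance guards against ties lost to floating-point noise
    n_ge = int(np.count_nonzero(sim_stats >= obs - 1e-12))
    p = (1 + n_ge) / (1 + n_resamples)
    return SymmetryTestResult(
        obs, int(a.size), float(p), TestMethod.MONTE_CARLO, n_resamples=n_resamples, seed=seed
    )


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, preserving input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]
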