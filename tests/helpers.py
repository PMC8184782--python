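"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the superposition
oracle is Horn's closed-form quaternion method, the statistics oracles are
direct brute-force enumerations, so agreement with the package is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def horn_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition via Horn's quaternion eigenvalue method."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    S = mc.T @ rc  # correlation matrix
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy,       Szx - Sxz,       Sxy - Syx],
        [Syz - Szy,       Sxx - Syy - Szz, Sxy + Syx,       Szx + Sxz],
        [Szx - Sxz,       Sxy + Syx,       -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx,       Szx + Sxz,       Syz + Szy,       -Sxx - Syy + Szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(N)
    w, x, y, z = eigvecs[:, -1]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    resid = mobile @ R.T + t - reference
    rmsd = float(np.sqrt((resid ** 2).sum() / mobile.shape[0]))
    return R, t, rmsd


def brute_permutation_pvalue(a, b) -> tuple[float, float]:
    """Exhaustive |Δmean| permutation p-value by direct subset enumeration."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)
    observed = abs(sum(a) / n1 - sum(b) / len(b))
    count = total = 0
    for subset in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in subset]
        gb = [pooled[i] for i in range(len(pooled)) if i not in subset]
        stat = abs(sum(ga) / len(ga) - sum(gb) / len(gb))
        total += 1
        if stat >= observed - 1e-12 * (1.0 + observed):
            count += 1
    return observed, count / total


def brute_mannwhitney(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by enumeration, U computed pairwise.

    U is the number of (x_i, y_j) pairs with x_i > y_j, counting ties as 1/2
    — an independent route to the rank-sum formula used by the package.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)

    def u_stat(ga, gb) -> float:
        u = 0.0
        for xi in ga:
            for yj in gb:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    centre = n1 * n2 / 2.0
    dev_obs = abs(u_obs - centre)
    pooled = x + y
    count = total = 0
    for subset in combinations(range(n1 + n2), n1):
        ga = [pooled[i] for i in subset]
        gb = [pooled[i] for i in range(n1 + n2) if i not in subset]
        total += 1
        if abs(u_stat(ga, gb) - centre) >= dev_obs - 1e-9:
            count += 1
    return u_obs, count / total


def binomial_ci99(p: float, n: int) -> tuple[float, float]:
    """Central 99% normal-approximation interval for a binomial proportion."""
    half = 2.5758293035489004 * np.sqrt(p * (1.0 - p) / n)
    return p - half, p + half
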