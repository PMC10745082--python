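"""Independent brute-force oracles used to validate the solvers."""

from __future__ import annotations

import itertools

import numpy as np


def oracle_lasso(D: np.ndarray, s: np.ndarray, lam: float) -> np.ndarray:
    """Global LASSO minimizer by enumeration of all 3^k sign patterns.

    For each pattern the nonzero block is solved in closed form from the
    stationarity conditions and the candidate is kept only if it satisfies
    the full KKT system; the feasible candidate with the lowest objective is
    returned.  Independent of any coordinate-descent code path.
    """
    D = np.asarray(D, dtype=float)
    s = np.asarray(s, dtype=float).ravel()
    t, k = D.shape
    best_obj, best_a = np.inf, None
    for signs in itertools.product((-1, 0, 1), repeat=k):
        signs = np.array(signs)
        Z = np.flatnonzero(signs)
        a = np.zeros(k)
        if Z.size:
            DZ = D[:, Z]
            try:
                a[Z] = np.linalg.solve(DZ.T @ DZ, DZ.T @ s - lam * signs[Z])
            except np.linalg.LinAlgError:
                continue
            if np.any(np.sign(a[Z]) != signs[Z]):
                continue
        g = D.T @ (s - D @ a)
        feasible = True
        for j in range(k):
            if a[j] == 0 and abs(g[j]) > lam + 1e-9:
                feasible = False
                break
            if a[j] != 0 and abs(g[j] - lam * np.sign(a[j])) > 1e-9:
                feasible = False
                break
        if not feasible:
            continue
        obj = 0.5 * np.sum((s - D @ a) ** 2) + lam * np.sum(np.abs(a))
        if obj < best_obj:
            best_obj, best_a = obj, a
    assert best_a is not None, "oracle found no KKT point"
    return best_a


def kkt_residual(D: np.ndarray, s: np.ndarray, a: np.ndarray, lam: float) -> float:
    """Max violation of the LASSO KKT conditions at ``a``."""
    g = D.T @ (s - D @ a)
    resid = 0.0
    for j in range(a.size):
        if abs(a[j]) < 1e-12:
            resid = max(resid, max(0.0, abs(g[j]) - lam))
        else:
            resid = max(resid, abs(g[j] - lam * np.sign(a[j])))
    return resid


def population_sd(values) -> float:
    """Textbook population standard deviation, written independently."""
    values = [float(v) for v in values]
    mean = sum(values) / len(values)
    return (sum((v - mean) ** 2 for v in values) / len(values)) ** 0.5
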