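"""Independent reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way (textbook
formulas, brute-force enumeration, plain Python loops) and shares no code
with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def pearson_reference(a, b) -> float:
    """Textbook Pearson correlation: covariance over the product of
    standard deviations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cov = np.cov(a, b, ddof=1)[0, 1]
    return float(cov / (np.std(a, ddof=1) * np.std(b, ddof=1)))


def simplex_grid(n: int, step: float) -> np.ndarray:
    """All points of the unit simplex lattice with resolution ``step``."""
    m = round(1.0 / step)
    pts = []

    def rec(prefix, remaining, depth):
        if depth == n - 1:
            pts.append(prefix + [remaining])
            return
        for i in range(remaining + 1):
            rec(prefix + [i], remaining - i, depth + 1)

    rec([], m, 0)
    return np.array(pts, dtype=float) * step


def fcls_grid_best(R: np.ndarray, C: np.ndarray, step: float = 0.005
                   ) -> float:
    """Best (lowest) least-squares objective over a simplex grid."""
    grid = simplex_grid(C.shape[1], step)          # (G, n)
    resid = R[None, :] - grid @ C.T                # (G, m)
    return float(np.min(np.sum(resid ** 2, axis=1)))


def selection_reference(R, S, eta, delta_tol, include_final=True,
                        max_iterations=None):
    """Straight-line re-implementation of the selective-endmember loop.

    Follows the documented conventions step by step: responses are Pearson
    correlations of the current residual with every endmember, the
    normalization denominator is the positive-clamped response sum over the
    whole library, each endmember is chosen at most once (ties to the
    lowest index), and the loop stops on a negative residual component, a
    small residual change, no positive candidate response, or exhaustion.

    Returns (choices, x_maxes, r_maxes, residuals, selected, stop_reason).
    """
    R = np.asarray(R, dtype=float)
    S = np.asarray(S, dtype=float)  # (n, m) endmember rows
    n = S.shape[0]
    limit = n if max_iterations is None else max_iterations
    residual = R.copy()
    candidates = list(range(n))
    choices, x_maxes, r_maxes, residuals = [], [], [], []
    selected = []
    stop = None
    stop_on_choice = False
    for _ in range(limit):
        if not candidates:
            break
        if np.std(residual) == 0.0:
            stop = "no_positive_response"
            break
        rs = np.array([min(1.0, max(-1.0, pearson_reference(residual, S[j])))
                       if np.std(S[j]) > 0 else np.nan for j in range(n)])
        pos = np.array([0.0 if np.isnan(v) else max(v, 0.0) for v in rs])
        cand_rs = [(-1.0 if np.isnan(rs[j]) else rs[j]) for j in candidates]
        if max(cand_rs) <= 0.0:
            stop = "no_positive_response"
            break
        j = candidates[int(np.argmax(cand_rs))]
        r_max = rs[j]
        x_max = pos[j] / pos.sum()
        residual = residual - eta * x_max * S[j]
        choices.append(j)
        r_maxes.append(float(r_max))
        x_maxes.append(float(x_max))
        residuals.append(residual.copy())
        selected.append(j)
        candidates.remove(j)
        if np.any(residual < 0.0):
            stop = "negative_component"
            stop_on_choice = True
            break
        if np.max(np.abs(eta * x_max * S[j])) < delta_tol:
            stop = "small_delta"
            stop_on_choice = True
            break
    if stop is None:
        stop = "candidates_exhausted"
    if stop_on_choice and not include_final and len(selected) > 1:
        selected = selected[:-1]
    return choices, x_maxes, r_maxes, residuals, selected, stop
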