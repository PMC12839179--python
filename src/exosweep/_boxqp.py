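"""Box-constrained strictly convex QP used by static optimization.

Solves  min_a  a'a + w * ||G a - b||^2   s.t.  0 <= a <= 1

by a primal active-set method on H = I + w G'G (always positive
definite). Problems are tiny (<= ~10 variables) but are solved a few
hundred thousand times per sweep, so this avoids general-purpose solver
overhead. Falls back to scipy's bounded least squares in the (never
observed, but guarded) event the active-set loop fails to settle.
"""

from __future__ import annotations

import numpy as np

_TOL = 1e-12
_MAX_ITER = 200


class SolverError(RuntimeError):
    pass


def solve_box_qp(H: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Minimize 0.5 a'H a - c'a over the unit box (H symmetric PD).

    With H = I + w G'G and c = w G'b this is the static-optimization
    subproblem up to a constant.
    """
    n = H.shape[0]
    a = np.clip(np.linalg.solve(H, c), 0.0, 1.0)
    free = (a > 0.0) & (a < 1.0)

    for _ in range(_MAX_ITER):
        idx = np.flatnonzero(free)
        if idx.size:
            rhs = c[idx] - H[np.ix_(idx, ~free)] @ a[~free]
            a_f = np.linalg.solve(H[np.ix_(idx, idx)], rhs)
        else:
            a_f = np.empty(0)

        inside = (a_f >= -_TOL) & (a_f <= 1.0 + _TOL)
        if inside.all():
            a[idx] = np.clip(a_f, 0.0, 1.0)
            g = H @ a - c
            lo_viol = (~free) & (a <= 0.0) & (g < -_TOL)
            hi_viol = (~free) & (a >= 1.0) & (g > _TOL)
            viol = lo_viol | hi_viol
            if not viol.any():
                return a
            worst = np.flatnonzero(viol)[np.argmax(np.abs(g[viol]))]
            free[worst] = True
            continue

        # Step from the current feasible point toward a_f, stop at the
        # first bound crossing and fix that variable there.
        d = a_f - a[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = np.where(d < 0, -a[idx] / d, np.inf)
            t_hi = np.where(d > 0, (1.0 - a[idx]) / d, np.inf)
        t = np.minimum(t_lo, t_hi)
        j = int(np.argmin(t))
        alpha = min(1.0, t[j])
        a[idx] = np.clip(a[idx] + alpha * d, 0.0, 1.0)
        if alpha < 1.0:
            a[idx[j]] = 0.0 if d[j] < 0 else 1.0
            free[idx[j]] = False

    raise SolverError("active-set iteration limit reached")


def solve_activation_qp(G: np.ndarray, b: np.ndarray, weight: float,
                        H: np.ndarray | None = None) -> np.ndarray:
    """Solve min ||a||^2 + weight*||G a - b||^2, 0 <= a <= 1.

    ``H`` may carry the precomputed I + weight*G'G (it is independent of
    b, so sweeps reuse it across grid cells).
    """
    if H is None:
        n = G.shape[1]
        H = np.eye(n) + weight * (G.T @ G)
    c = weight * (G.T @ b)
    try:
        return solve_box_qp(H, c)
    except SolverError:
        from scipy.optimize import lsq_linear
        A = np.vstack([np.eye(G.shape[1]), np.sqrt(weight) * G])
        y = np.concatenate([np.zeros(G.shape[1]), np.sqrt(weight) * b])
        res = lsq_linear(A, y, bounds=(0.0, 1.0), method="bvls")
        return np.clip(res.x, 0.0, 1.0)
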