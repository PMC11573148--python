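"""Independent brute-force oracle for tiny non-negative least squares.

For problems with a handful of unknowns the constrained optimum can be
found exactly by exhaustive enumeration: at the minimum of
``||target - X w||^2`` over ``w >= 0``, every coordinate is either zero
(active constraint) or solves the unconstrained least-squares problem on
the remaining coordinates. Enumerating all 2^n zero-patterns and keeping
the feasible candidate with the lowest objective is therefore exact. A
fine local grid sweep (step 1e-3) around the winner double-checks that
no nearby grid point does better. No NNLS routine is involved.
"""

import itertools

import numpy as np


def _objective(X: np.ndarray, target: np.ndarray, w: np.ndarray) -> float:
    r = target - X @ w
    return float(r @ r)


def nnls_grid_search(X: np.ndarray, target: np.ndarray, upper: float = 3.0) -> np.ndarray:
    """Exact brute-force solution of min ||target - X w||^2, w >= 0."""
    n = X.shape[1]
    best, best_obj = np.zeros(n), _objective(X, target, np.zeros(n))
    for free in itertools.chain.from_iterable(
        itertools.combinations(range(n), k) for k in range(1, n + 1)
    ):
        free = list(free)
        sol, *_ = np.linalg.lstsq(X[:, free], target, rcond=None)
        if np.any(sol < 0):
            continue
        w = np.zeros(n)
        w[free] = sol
        obj = _objective(X, target, w)
        if obj < best_obj:
            best, best_obj = w, obj

    # confirmation: no grid point (step 1e-3) in a local box beats the winner
    axes = [
        np.arange(max(0.0, b - 0.01), b + 0.01 + 1e-12, 1e-3) for b in best
    ]
    for cand in itertools.product(*axes):
        assert _objective(X, target, np.array(cand)) >= best_obj - 1e-9
    return best
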