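"""Independent brute-force oracle for the simplex-constrained inversion.

Solves  min ||R - A q||^2  s.t.  q >= 0, sum(q) = 1  exactly, by exhaustive
enumeration of every possible support set (2^n - 1 candidate faces of the
simplex): on each face the equality-constrained least-squares problem is a
small KKT linear solve, and the global constrained optimum is the best
feasible face solution.  Exact for the small grids (n <= ~12) it is used on,
and fully independent of the production NNLS path.
"""

import itertools

import numpy as np


def simplex_lstsq_bruteforce(retentions: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    r = np.asarray(retentions, dtype=float)
    a = np.asarray(kernel, dtype=float)
    n = a.shape[1]
    best_q, best_val = None, np.inf
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            a_s = a[:, support]
            k = len(support)
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = a_s.T @ a_s
            kkt[:k, k] = 1.0
            kkt[k, :k] = 1.0
            rhs = np.concatenate([a_s.T @ r, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            q_s = sol[:k]
            if np.any(q_s < -1e-12):
                continue
            q = np.zeros(n)
            q[list(support)] = np.clip(q_s, 0.0, None)
            val = float(np.sum((r - a @ q) ** 2))
            if val < best_val - 1e-15:
                best_q, best_val = q, val
    assert best_q is not None
    return best_q
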