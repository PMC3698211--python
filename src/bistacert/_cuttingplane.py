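"""Cutting-plane LP engine for small LMI feasibility problems.

Finds a symmetric matrix ``M`` satisfying a collection of constraints that
are affine in ``M``:

* PSD blocks ``B(M) = C + sum_r (P_r M Q_r' + Q_r M P_r')  >=  margin * I``
* scalar linear inequalities ``a' M a <= b`` (more generally any linear
  functional of ``M``)
* elementwise bounds ``|M_ij| <= bound_ij``

Each PSD block is outer-approximated by the valid linear cuts
``v' B(M) v >= margin`` (``v`` unit vectors).  The LP maximizes the worst
surplus ``t`` over all generated cuts; eigenvector cuts of violated blocks
are added until either a candidate ``M`` passes an independent eigenvalue
check of every block (feasible), or the LP proves that no ``M`` within the
bounds can reach surplus ``t >= 0`` (infeasible — the cuts are necessary
conditions, so this is a certificate).

This deliberately trades speed for having zero dependencies beyond
``scipy.optimize.linprog``; problem sizes here are tiny (n <= 10,
hundreds of blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = ["AffineBlock", "LMIResult", "solve_lmi_feasibility", "sym_to_vec", "vec_to_sym", "pair_coeffs"]


def _tri_indices(n: int):
    return np.triu_indices(n)


def sym_to_vec(M: np.ndarray) -> np.ndarray:
    """Upper-triangular vectorization of a symmetric matrix."""
    return M[_tri_indices(M.shape[0])]


def vec_to_sym(m: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    iu = _tri_indices(n)
    M[iu] = m
    M = M + M.T - np.diag(np.diag(M))
    return M


def pair_coeffs(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Coefficient vector c with c . vec(M) == u' M w for symmetric M."""
    n = u.shape[0]
    C = 0.5 * (np.outer(u, w) + np.outer(w, u))
    iu = _tri_indices(n)
    off = np.ones((n, n)) * 2.0
    np.fill_diagonal(off, 1.0)
    return (C * off)[iu]


@dataclass
class AffineBlock:
    """PSD constraint ``C + sum_r (P_r M Q_r' + Q_r M P_r') >= margin*I``."""

    C: np.ndarray
    terms: list  # list of (P, Q) pairs
    margin: float = 0.0
    name: str = ""

    def evaluate(self, M: np.ndarray) -> np.ndarray:
        B = self.C.copy()
        for P, Q in self.terms:
            PMQ = P @ M @ Q.T
            B += PMQ + PMQ.T
        return B

    def cut(self, v: np.ndarray) -> tuple[np.ndarray, float]:
        """Linear cut ``coef . vec(M) >= margin - const`` from direction v."""
        const = float(v @ self.C @ v)
        n = self.terms[0][0].shape[1]
        coef = np.zeros(n * (n + 1) // 2)
        for P, Q in self.terms:
            coef += 2.0 * pair_coeffs(P.T @ v, Q.T @ v)
        return coef, const

    def min_eig(self, M: np.ndarray) -> tuple[float, np.ndarray]:
        w, V = np.linalg.eigh(self.evaluate(M))
        return float(w[0]), V


@dataclass
class LMIResult:
    status: str  # "feasible" | "infeasible" | "unknown"
    M: np.ndarray | None
    n_iterations: int
    message: str = ""
    block_margins: dict = field(default_factory=dict)


def solve_lmi_feasibility(
    n: int,
    blocks: list[AffineBlock],
    lin_A: np.ndarray | None = None,
    lin_b: np.ndarray | None = None,
    bounds: np.ndarray | None = None,
    max_iterations: int = 250,
    cuts_per_block: int = 2,
    max_block_cuts_per_iter: int = 60,
    t_cap: float = 1e3,
) -> LMIResult:
    """Run the cutting-plane loop.

    ``lin_A m <= lin_b`` are exact linear rows (kept in every LP);
    ``bounds`` is an elementwise bound matrix on ``|M_ij|`` that must be
    valid for every feasible ``M`` — it keeps the LP bounded and makes LP
    infeasibility a genuine infeasibility certificate.
    """
    nv = n * (n + 1) // 2
    iu = _tri_indices(n)
    if bounds is None:
        bvec = np.full(nv, 1e6)
    else:
        bvec = bounds[iu]

    # cut list: rows of [coef | -1] . [m; t] >= margin - const
    cut_rows: list[np.ndarray] = []
    cut_rhs: list[float] = []

    def add_cut(block: AffineBlock, v: np.ndarray) -> None:
        coef, const = block.cut(v)
        # coef.m + const >= margin + t  ->  -coef.m + t <= const - margin
        cut_rows.append(np.append(-coef, 1.0))
        cut_rhs.append(const - block.margin)

    # seed with coordinate-direction cuts
    eye = np.eye(max(b.C.shape[0] for b in blocks))
    for b in blocks:
        d = b.C.shape[0]
        for k in range(d):
            add_cut(b, eye[:d, k])

    n_lin = 0
    if lin_A is not None:
        lin_A = np.atleast_2d(lin_A)
        lin_b = np.atleast_1d(lin_b)
        n_lin = lin_A.shape[0]

    var_bounds = [(-bvec[i], bvec[i]) for i in range(nv)] + [(None, t_cap)]
    c_obj = np.zeros(nv + 1)
    c_obj[-1] = -1.0  # maximize t

    message = ""
    for it in range(1, max_iterations + 1):
        A_ub = np.array(cut_rows)
        b_ub = np.array(cut_rhs)
        if n_lin:
            A_ub = np.vstack([A_ub, np.hstack([lin_A, np.zeros((n_lin, 1))])])
            b_ub = np.concatenate([b_ub, lin_b])
        res = linprog(c_obj, A_ub=A_ub, b_ub=b_ub, bounds=var_bounds, method="highs")
        if res.status == 2:  # infeasible
            return LMIResult("infeasible", None, it, "cut LP infeasible within bounds")
        if res.status != 0:
            return LMIResult("unknown", None, it, f"LP solver: {res.message}")
        t_star = res.x[-1]
        if t_star < 0.0:
            return LMIResult(
                "infeasible", None, it,
                f"LP bound on worst constraint surplus is {t_star:.3e} < 0",
            )
        M = vec_to_sym(res.x[:nv], n)

        # independent eigenvalue check of every block
        viols = []
        margins = {}
        for bi, b in enumerate(blocks):
            lam, V = b.min_eig(M)
            margins[b.name or f"block{bi}"] = lam - b.margin
            if lam < b.margin:
                viols.append((lam - b.margin, bi, V))
        if lin_A is not None and np.any(lin_A @ res.x[:nv] > lin_b + 1e-9):
            viols.append((-1.0, None, None))  # should not happen: hard rows
        if not viols:
            return LMIResult("feasible", M, it, "all blocks verified", margins)

        viols.sort(key=lambda z: z[0])
        for _, bi, V in viols[:max_block_cuts_per_iter]:
            if bi is None:
                continue
            b = blocks[bi]
            for k in range(min(cuts_per_block, V.shape[1])):
                add_cut(b, V[:, k])
        message = f"worst violation {viols[0][0]:.3e} after {it} iterations"
    return LMIResult("unknown", None, max_iterations, message)
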