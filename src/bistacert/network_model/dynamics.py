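"""Evaluation of mass-action dynamics: rates, Jacobians, quadratic form.

The right-hand side of any mass-action network with molecularity <= 2 is
exactly quadratic in the state, so around an equilibrium ``xe`` it can be
written without error as ``zdot = A z + F(z)`` with ``z = x - xe``,
``F_i(z) = z' F_i z`` and constant symmetric matrices ``F_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .reactions import ReactionNetwork

__all__ = [
    "rate_vector",
    "rhs",
    "jacobian_x",
    "jacobian_p",
    "QuadraticSystem",
    "quadratic_decomposition",
    "simulate",
    "Trajectory",
]


def _params(network: ReactionNetwork, p) -> np.ndarray:
    if p is None:
        return network.nominal_parameters()
    p = np.asarray(p, dtype=float)
    if p.shape != (network.n_parameters,):
        raise ValueError(
            f"parameter vector has shape {p.shape}, "
            f"expected ({network.n_parameters},)"
        )
    return p


def _state(network: ReactionNetwork, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (network.n_species,):
        raise ValueError(
            f"state vector has shape {x.shape}, expected ({network.n_species},)"
        )
    return x


def rate_vector(network: ReactionNetwork, x, p=None) -> np.ndarray:
    """Reaction rates v(x, p); constant inputs are folded into each rate."""
    x = _state(network, x)
    p = _params(network, p)
    v = p[network._react_param] * network._const_factor
    ridx = network._reactant_idx
    for slot in range(2):
        mask = ridx[:, slot] >= 0
        v[mask] *= x[ridx[mask, slot]]
    return v


def rhs(network: ReactionNetwork, x, p=None) -> np.ndarray:
    """Time derivative N v(x, p) of the species concentrations."""
    return network._N @ rate_vector(network, x, p)


def jacobian_x(network: ReactionNetwork, x, p=None) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with respect to the state."""
    x = _state(network, x)
    p = _params(network, p)
    k = p[network._react_param] * network._const_factor
    nr, ns = network.n_reactions, network.n_species
    dv = np.zeros((nr, ns))
    ridx = network._reactant_idx
    for j in range(nr):
        a, b = ridx[j]
        if a < 0:
            continue
        if b < 0:
            dv[j, a] += k[j]
        else:
            dv[j, a] += k[j] * x[b]
            dv[j, b] += k[j] * x[a]
    return network._N @ dv


def jacobian_p(network: ReactionNetwork, x, p=None) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with respect to the parameters."""
    x = _state(network, x)
    _params(network, p)  # shape check only; rates are linear in p
    mono = network._const_factor.copy()
    ridx = network._reactant_idx
    for slot in range(2):
        mask = ridx[:, slot] >= 0
        mono[mask] *= x[ridx[mask, slot]]
    J = np.zeros((network.n_species, network.n_parameters))
    for j in range(network.n_reactions):
        J[:, network._react_param[j]] += network._N[:, j] * mono[j]
    return J


@dataclass
class QuadraticSystem:
    """Exact quadratic form of the dynamics shifted to an equilibrium."""

    A: np.ndarray
    F_list: list[np.ndarray]
    origin_state: np.ndarray

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def rhs_shifted(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        quad = np.array([z @ F @ z for F in self.F_list])
        return self.A @ z + quad

    def quad_row_matrix(self, z) -> np.ndarray:
        """Matrix G(z) with row i equal to z' F_i (linear in z)."""
        return np.array([F @ z for F in self.F_list])

    def is_hurwitz(self, margin: float = 0.0) -> bool:
        return bool(np.max(np.linalg.eigvals(self.A).real) < -margin)

    def rescaled(self, d: np.ndarray) -> "QuadraticSystem":
        """Diagonal change of coordinates y = z / d (componentwise)."""
        d = np.asarray(d, dtype=float)
        D = np.diag(d)
        A = (self.A * d[None, :]) / d[:, None]
        F = [D @ Fi @ D / d[i] for i, Fi in enumerate(self.F_list)]
        return QuadraticSystem(A, F, self.origin_state.copy())


def quadratic_decomposition(
    network: ReactionNetwork, p, equilibrium, residual_tol: float = 1e-6
) -> QuadraticSystem:
    """Shift coordinates to an equilibrium and split the RHS as A z + z'F_i z.

    Raises if the supplied point is not an equilibrium to ``residual_tol``
    (relative to the state scale): a constant term would otherwise remain.
    """
    xe = np.asarray(getattr(equilibrium, "state", equilibrium), dtype=float)
    p = _params(network, p)
    scale = max(1.0, float(np.max(np.abs(xe))))
    res = float(np.max(np.abs(rhs(network, xe, p))))
    if res > residual_tol * scale:
        raise ValueError(
            f"point is not an equilibrium: residual {res:.3e} exceeds "
            f"{residual_tol:.1e} * scale"
        )
    A = jacobian_x(network, xe, p)
    ns = network.n_species
    k = p[network._react_param] * network._const_factor
    F_list = [np.zeros((ns, ns)) for _ in range(ns)]
    ridx = network._reactant_idx
    for j in range(network.n_reactions):
        a, b = ridx[j]
        if a < 0 or b < 0:
            continue
        col = network._N[:, j] * k[j]
        for i in np.nonzero(col)[0]:
            if a == b:
                F_list[i][a, a] += col[i]
            else:
                F_list[i][a, b] += 0.5 * col[i]
                F_list[i][b, a] += 0.5 * col[i]
    return QuadraticSystem(A, F_list, xe)


@dataclass
class Trajectory:
    t: np.ndarray
    y: np.ndarray  # shape (n_species, n_times)

    @property
    def endpoint(self) -> np.ndarray:
        return self.y[:, -1]


def simulate(
    network: ReactionNetwork,
    p,
    x0,
    horizon: float,
    solver_tol: float = 1e-8,
    n_points: int = 200,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network ODEs over ``[0, horizon]`` hours.

    Uses a stiff-capable integrator with the analytic Jacobian; raises
    ``RuntimeError`` (with the failure time) if integration fails.
    """
    x0 = _state(network, x0)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    p = _params(network, p)
    sol = solve_ivp(
        lambda t, y: rhs(network, y, p),
        (0.0, float(horizon)),
        x0,
        method=method,
        jac=lambda t, y: jacobian_x(network, y, p),
        rtol=solver_tol,
        atol=solver_tol * max(1.0, float(np.max(np.abs(x0)))),
        t_eval=np.linspace(0.0, float(horizon), n_points),
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"integration failed at t = {t_fail:.4g} h: {sol.message}")
    return Trajectory(sol.t, sol.y)
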