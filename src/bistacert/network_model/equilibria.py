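"""Multistart equilibrium search and stability classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import jacobian_x, rhs
from .reactions import ReactionNetwork

__all__ = ["Equilibrium", "MultistartSpec", "newton_refine", "find_equilibria"]

#: eigenvalue real parts within this of zero are treated as marginal
_MARGINAL_TOL = 1e-8


@dataclass
class Equilibrium:
    """A Newton-converged steady state with its local stability data."""

    state: np.ndarray
    residual_norm: float
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool = False

    @property
    def classification(self) -> str:
        if self.marginal:
            return "marginal"
        return "stable" if self.stable else "unstable"

    def to_dict(self) -> dict:
        return {
            "state": self.state.tolist(),
            "residual_norm": self.residual_norm,
            "eigenvalues_real": self.eigenvalues.real.tolist(),
            "eigenvalues_imag": self.eigenvalues.imag.tolist(),
            "stable": self.stable,
            "marginal": self.marginal,
        }


@dataclass
class MultistartSpec:
    """Deterministic seeded start-point generator for the Newton search.

    Start points are a log-uniform random subsample over
    ``[lower, upper]`` per species, plus each user guess together with its
    0.5x / 1.5x corner rescalings and a few seeded multiplicative
    perturbations.
    """

    n_random: int = 500
    lower: float = 1e-2
    upper: float = 1e4
    seed: int = 0
    guesses: list = field(default_factory=list)
    n_guess_perturbations: int = 8

    def start_points(self, n_species: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        pts = []
        if self.n_random > 0:
            lo, hi = np.log10(self.lower), np.log10(self.upper)
            pts.append(10.0 ** rng.uniform(lo, hi, size=(self.n_random, n_species)))
        for g in self.guesses:
            g = np.asarray(g, dtype=float)
            pts.append(g[None, :])
            pts.append(0.5 * g[None, :])
            pts.append(1.5 * g[None, :])
            if self.n_guess_perturbations:
                fac = rng.uniform(0.5, 1.5, size=(self.n_guess_perturbations, n_species))
                pts.append(g[None, :] * fac)
        if not pts:
            raise ValueError("multistart spec generates no start points")
        return np.vstack(pts)


def newton_refine(
    network: ReactionNetwork,
    p,
    x0,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> tuple[np.ndarray, float, bool, int]:
    """Damped Newton iteration on ``rhs = 0`` from ``x0``.

    Returns ``(x, residual_norm, converged, n_iter)``.  Convergence is on
    the max-abs residual relative to ``max(1, |x|_inf)``.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = rhs(network, x, p)
    for it in range(1, max_iter + 1):
        scale = max(1.0, float(np.max(np.abs(x))))
        if np.max(np.abs(f)) <= tol * scale:
            return x, float(np.max(np.abs(f))), True, it - 1
        J = jacobian_x(network, x, p)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -f, rcond=None)
        lam = 1.0
        fn = float(np.max(np.abs(f)))
        for _ in range(30):
            x_new = x + lam * step
            f_new = rhs(network, x_new, p)
            if np.all(np.isfinite(f_new)) and float(np.max(np.abs(f_new))) < fn:
                x, f = x_new, f_new
                break
            lam *= 0.5
        else:
            return x, fn, False, it
    scale = max(1.0, float(np.max(np.abs(x))))
    fn = float(np.max(np.abs(f)))
    return x, fn, fn <= tol * scale, max_iter


def _classify(network: ReactionNetwork, p, x: np.ndarray, res: float) -> Equilibrium:
    eig = np.linalg.eigvals(jacobian_x(network, x, p))
    re = eig.real
    marginal = bool(np.any(np.abs(re) < _MARGINAL_TOL))
    stable = bool(np.all(re < 0)) and not marginal
    return Equilibrium(x, res, eig, stable, marginal)


def find_equilibria(
    network: ReactionNetwork,
    p=None,
    multistart: MultistartSpec | None = None,
    tol: float = 1e-10,
    merge_rtol: float = 1e-6,
    nonneg_tol: float = 1e-8,
) -> list[Equilibrium]:
    """Seeded multistart Newton search for all nonnegative equilibria.

    Non-convergent starts and negative-concentration solutions are
    discarded; converged points are merged when their relative distance is
    below ``merge_rtol``.  The result is sorted by the first state
    coordinate.
    """
    spec = multistart or MultistartSpec()
    found: list[tuple[np.ndarray, float]] = []
    for x0 in spec.start_points(network.n_species):
        x, res, ok, _ = newton_refine(network, p, x0, tol=tol)
        if not ok:
            continue
        scale = max(1.0, float(np.max(np.abs(x))))
        if np.min(x) < -nonneg_tol * scale:
            continue
        x = np.maximum(x, 0.0)
        res = float(np.max(np.abs(rhs(network, x, p))))
        if res > 10 * tol * scale:
            # clipping moved the point off the root
            continue
        for xk, rk in found:
            if np.max(np.abs(x - xk)) <= merge_rtol * max(
                1.0, float(np.max(np.abs(xk)))
            ):
                break
        else:
            found.append((x, res))
    eqs = [_classify(network, p, x, res) for x, res in found]
    eqs.sort(key=lambda e: tuple(e.state))
    return eqs
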