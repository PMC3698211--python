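"""Certification of boxes as subsets of a domain of attraction.

A box ``S`` (origin interior, shifted coordinates) is certified to lie in
the DA of the origin of ``zdot = A z + F(z)`` if for some ``gamma`` in
(0, 1) there is a symmetric ``M > 0`` (standing for P/c of the underlying
Lyapunov level set) with, writing ``a_k`` for the 2n face normals and
``x_(i)`` for the 2^n vertices:

* ``[[1, gamma a_k'], [gamma a_k, M]] >= 0``  (equivalently
  ``M >= gamma^2 a_k a_k'``),
* ``x_(i)' M x_(i) <= 1``,
* ``gamma (A'M + MA) + G_i' M + M G_i < 0`` where row j of ``G_i`` is
  ``x_(i)' F_j`` (this grouping is the one the Lyapunov-derivative
  expansion ``2 z'M F(z) = z'(G(z)'M + M G(z)) z`` produces; it is also
  the only one invariant under linear changes of coordinates).

For fixed ``gamma`` these are LMIs in ``M`` alone and are solved with the
cutting-plane engine.  Every returned certificate is re-verified by an
independent eigenvalue computation before being handed back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._cuttingplane import AffineBlock, pair_coeffs, solve_lmi_feasibility
from ..network_model.dynamics import QuadraticSystem, simulate
from .boxes import AxisBox, to_absolute

__all__ = [
    "DACertificate",
    "CertifyResult",
    "default_gamma_grid",
    "certify_box",
    "check_certificate",
    "grow_box",
    "GrowthSchedule",
    "verify_box_by_simulation",
    "sample_box",
]

#: required strict-definiteness margins (scaled coordinates)
PD_MARGIN = 1e-8
ND_MARGIN = 1e-7


def default_gamma_grid(n_points: int = 24) -> np.ndarray:
    """Uniform grid in (0.02, 0.98); scanned in order, first feasible wins."""
    return np.linspace(0.02, 0.98, n_points)


@dataclass
class DACertificate:
    """Witness ``(gamma, M)`` that ``box`` lies in the DA of the origin.

    ``M`` lives in diagonally rescaled coordinates ``y = z / scaling``
    (the certificate conditions are checked for the rescaled system, whose
    DA maps one-to-one onto the original one).
    """

    gamma: float
    M: np.ndarray
    box: AxisBox  # shifted frame, original (unscaled) coordinates
    scaling: np.ndarray
    margins: dict = field(default_factory=dict)
    solver_report: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "M": self.M.tolist(),
            "box": self.box.to_dict(),
            "scaling": self.scaling.tolist(),
            "margins": {k: float(v) for k, v in self.margins.items()},
            "solver_report": self.solver_report,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DACertificate":
        return cls(
            gamma=float(d["gamma"]),
            M=np.asarray(d["M"]),
            box=AxisBox.from_dict(d["box"]),
            scaling=np.asarray(d["scaling"]),
            margins=dict(d.get("margins", {})),
            solver_report=dict(d.get("solver_report", {})),
        )


@dataclass
class CertifyResult:
    certificate: DACertificate | None
    gamma_status: list  # (gamma, status, message) per attempted gamma

    @property
    def feasible(self) -> bool:
        return self.certificate is not None


def _scaling_for(quad: QuadraticSystem) -> np.ndarray:
    # divide each coordinate by its equilibrium value, floored at 1
    return np.maximum(np.abs(quad.origin_state), 1.0)


def _scaled_problem(quad: QuadraticSystem, box: AxisBox, scaling: np.ndarray):
    qs = quad.rescaled(scaling)
    bs = AxisBox(box.lower / scaling, box.upper / scaling, "shifted")
    return qs, bs


def _assemble(qs: QuadraticSystem, bs: AxisBox, gamma: float):
    n = qs.n
    eye = np.eye(n)
    half = 0.5 * eye
    blocks = [AffineBlock(np.zeros((n, n)), [(half, eye)], PD_MARGIN, "M_pd")]
    for k, a in enumerate(bs.face_normals()):
        blocks.append(
            AffineBlock(-gamma**2 * np.outer(a, a), [(half, eye)], 0.0, f"face{k}")
        )
    verts = bs.vertices()
    lin_A = []
    for i, x in enumerate(verts):
        G = qs.quad_row_matrix(x)
        blocks.append(
            AffineBlock(
                np.zeros((n, n)),
                [(-gamma * qs.A.T, eye), (-G.T, eye)],
                ND_MARGIN,
                f"vertex{i}",
            )
        )
        lin_A.append(pair_coeffs(x, x))
    lin_A = np.array(lin_A)
    lin_b = np.ones(len(verts))
    w = bs.widths
    bounds = 4.0 / np.outer(w, w)
    return blocks, lin_A, lin_b, bounds


def certify_box(
    quad: QuadraticSystem,
    box: AxisBox,
    gamma_grid=None,
    max_iterations: int = 250,
) -> CertifyResult:
    """Search the gamma grid for a feasible certificate for ``box``.

    ``box`` must be in the shifted frame.  Raises if the linearization is
    not Hurwitz (the origin must be asymptotically stable).
    """
    if box.frame != "shifted":
        raise ValueError("certify_box expects a shifted-frame box")
    if not quad.is_hurwitz():
        raise ValueError("A is not Hurwitz: origin is not asymptotically stable")
    gammas = default_gamma_grid() if gamma_grid is None else np.atleast_1d(gamma_grid)
    scaling = _scaling_for(quad)
    qs, bs = _scaled_problem(quad, box, scaling)
    status = []
    for gamma in gammas:
        blocks, lin_A, lin_b, bounds = _assemble(qs, bs, float(gamma))
        res = solve_lmi_feasibility(
            qs.n, blocks, lin_A, lin_b, bounds, max_iterations=max_iterations
        )
        status.append((float(gamma), res.status, res.message))
        if res.status == "feasible":
            cert = DACertificate(
                gamma=float(gamma),
                M=res.M,
                box=box,
                scaling=scaling,
                solver_report={
                    "iterations": res.n_iterations,
                    "engine": "cutting-plane-lp",
                    "gamma_status": status,
                },
            )
            cert.margins = check_certificate(quad, cert)
            # face/level-set conditions are non-strict; allow rounding slack
            if min(cert.margins.values()) >= -1e-9:
                return CertifyResult(cert, status)
            status[-1] = (float(gamma), "verify-failed", "independent recheck failed")
    return CertifyResult(None, status)


def check_certificate(quad: QuadraticSystem, cert: DACertificate) -> dict:
    """Independently re-check all three condition families with eigenvalue
    computations; returns the worst margin per family (>= 0 means valid)."""
    qs, bs = _scaled_problem(quad, cert.box, cert.scaling)
    M, gamma = cert.M, cert.gamma
    margins = {}
    margins["M_positive_definite"] = float(np.linalg.eigvalsh(M)[0]) - PD_MARGIN / 2
    worst = np.inf
    for a in bs.face_normals():
        n1 = bs.n + 1
        blk = np.zeros((n1, n1))
        blk[0, 0] = 1.0
        blk[0, 1:] = gamma * a
        blk[1:, 0] = gamma * a
        blk[1:, 1:] = M
        worst = min(worst, float(np.linalg.eigvalsh(blk)[0]))
    margins["face_lmi"] = worst
    verts = bs.vertices()
    margins["vertex_level_set"] = float(1.0 - np.max(np.einsum("ij,jk,ik->i", verts, M, verts)))
    worst = np.inf
    AtM = qs.A.T @ M
    for x in verts:
        G = qs.quad_row_matrix(x)
        GM = G.T @ M
        blk = gamma * (AtM + AtM.T) + GM + GM.T
        worst = min(worst, -float(np.linalg.eigvalsh(blk)[-1]))
    margins["vertex_derivative"] = worst - ND_MARGIN / 2
    return margins


@dataclass
class GrowthSchedule:
    """Deterministic round-robin stretching schedule."""

    factor: float = 1.1
    max_steps: int = 10_000
    nonneg_floor: bool = True  # clip lower bounds at zero concentration
    gamma_grid: np.ndarray | None = None


def grow_box(
    quad: QuadraticSystem,
    seed_box: AxisBox,
    schedule: GrowthSchedule | None = None,
    max_iterations: int = 250,
) -> tuple[AxisBox, DACertificate]:
    """Grow a certified box by round-robin face stretching.

    Faces are stretched multiplicatively one at a time (first the 2n upper
    faces, then lower); a face is frozen after its first rejected stretch;
    the loop ends when every face is frozen or ``max_steps`` trials were
    made.  The seed box must itself be certifiable.
    """
    sched = schedule or GrowthSchedule()
    res = certify_box(quad, seed_box, sched.gamma_grid, max_iterations)
    if not res.feasible:
        raise ValueError("seed box is not certifiable")
    cert = res.certificate
    box = seed_box
    n = box.n
    frozen = [False] * (2 * n)
    last_gamma = cert.gamma
    grid = default_gamma_grid() if sched.gamma_grid is None else np.atleast_1d(sched.gamma_grid)
    steps = 0
    while not all(frozen) and steps < sched.max_steps:
        for face in range(2 * n):
            if frozen[face] or steps >= sched.max_steps:
                continue
            lo, hi = box.lower.copy(), box.upper.copy()
            if face < n:
                hi[face] *= sched.factor
            else:
                k = face - n
                new_lo = lo[k] * sched.factor
                if sched.nonneg_floor:
                    floor = -quad.origin_state[k]
                    new_lo = max(new_lo, floor)
                if new_lo >= lo[k] - 1e-15:
                    frozen[face] = True
                    continue
                lo[k] = new_lo
            trial = AxisBox(lo, hi, "shifted")
            steps += 1
            order = np.concatenate(
                [[last_gamma], grid[~np.isclose(grid, last_gamma)]]
            )
            tres = certify_box(quad, trial, order, max_iterations)
            if tres.feasible:
                box = trial
                cert = tres.certificate
                last_gamma = cert.gamma
            else:
                frozen[face] = True
    return box, cert


def sample_box(box: AxisBox, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Latin-hypercube interior samples of a box."""
    n = box.n
    u = np.empty((n_samples, n))
    for j in range(n):
        strata = (rng.permutation(n_samples) + rng.uniform(size=n_samples)) / n_samples
        u[:, j] = strata
    return box.lower + u * box.widths


def verify_box_by_simulation(
    network,
    p,
    box: AxisBox,
    equilibrium,
    n_samples: int = 50,
    seed: int = 0,
    horizon: float = 200.0,
    tol: float = 0.01,
    include_vertices: bool = True,
    solver_tol: float = 1e-8,
) -> float:
    """Fraction of sampled initial conditions whose trajectories end within
    ``tol`` (relative) of the equilibrium.

    Samples are the box vertices plus seeded Latin-hypercube interior
    points.  For a sound DA certificate the fraction must be 1.0.
    """
    if box.frame != "absolute":
        raise ValueError("simulation verification expects an absolute-frame box")
    xe = np.asarray(getattr(equilibrium, "state", equilibrium), dtype=float)
    rng = np.random.default_rng(seed)
    pts = [sample_box(box, n_samples, rng)] if n_samples else []
    if include_vertices:
        pts.insert(0, box.vertices())
    pts = np.vstack(pts)
    denom = np.maximum(np.abs(xe), 1.0)
    ok = 0
    for x0 in pts:
        traj = simulate(network, p, np.maximum(x0, 0.0), horizon,
                        solver_tol=solver_tol, n_points=2)
        if np.max(np.abs(traj.endpoint - xe) / denom) <= tol:
            ok += 1
    return ok / len(pts)
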