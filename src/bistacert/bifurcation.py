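"""Equilibrium continuation, fold (limit point) and cusp detection.

One-parameter branches are traced with a secant-predictor /
Newton-corrector pseudo-arclength scheme; folds are flagged by a sign
change of ``det(J)`` along the branch and refined with the Moore-Spence
augmented system ``{f = 0, J v = 0, c'v = 1}``.  Two-parameter fold curves
continue that augmented system in both parameters; cusps are flagged where
the fold normal-form coefficient ``w' f_xx(v, v)`` changes sign and
refined by bisection in arclength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .network_model.dynamics import _params, jacobian_p, jacobian_x, rhs
from .network_model.equilibria import newton_refine
from .network_model.reactions import ReactionNetwork

__all__ = [
    "Branch",
    "FoldPoint",
    "CuspPoint",
    "StepControl",
    "continue_equilibria",
    "bistable_interval",
    "continue_fold_curve",
]


@dataclass
class FoldPoint:
    parameter: float | tuple
    state: np.ndarray
    null_vector: np.ndarray

    def to_dict(self) -> dict:
        par = self.parameter
        return {
            "parameter": list(par) if isinstance(par, tuple) else float(par),
            "state": self.state.tolist(),
            "null_vector": self.null_vector.tolist(),
        }


@dataclass
class CuspPoint:
    parameters: tuple  # (p_a, p_b)
    state: np.ndarray

    def to_dict(self) -> dict:
        return {"parameters": list(self.parameters), "state": self.state.tolist()}


@dataclass
class Branch:
    parameter_names: tuple
    points: list  # list of (param value or tuple, state vector)
    stability: list = field(default_factory=list)
    folds: list = field(default_factory=list)
    message: str = ""

    def parameter_values(self) -> np.ndarray:
        return np.array([pt[0] for pt in self.points])

    def states(self) -> np.ndarray:
        return np.array([pt[1] for pt in self.points])


@dataclass
class StepControl:
    initial: float = 0.01
    min_step: float = 1e-4
    max_step: float = 0.5
    grow: float = 1.3
    shrink: float = 0.5
    max_points: int = 5000
    newton_tol: float = 1e-10
    max_newton: int = 12


def _hessian_forms(network: ReactionNetwork, p) -> list[np.ndarray]:
    """Constant quadratic coefficient matrices Q_i of the RHS (f_i has
    Hessian 2 Q_i everywhere — mass action is exactly quadratic)."""
    p = _params(network, p)
    k = p[network._react_param] * network._const_factor
    ns = network.n_species
    Q = [np.zeros((ns, ns)) for _ in range(ns)]
    ridx = network._reactant_idx
    for j in range(network.n_reactions):
        a, b = ridx[j]
        if a < 0 or b < 0:
            continue
        col = network._N[:, j] * k[j]
        for i in np.nonzero(col)[0]:
            if a == b:
                Q[i][a, a] += col[i]
            else:
                Q[i][a, b] += 0.5 * col[i]
                Q[i][b, a] += 0.5 * col[i]
    return Q


def _corrector(network, pvec, pidx, y_pred, tangent, x_scale, p_scale, ctrl):
    """Newton-correct (x, theta) on {f = 0, tangent . (y - y_pred) = 0}.

    ``y`` is the scaled vector [x / x_scale; theta] with theta the scaled
    continuation parameter.
    """
    n = len(x_scale)
    y = y_pred.copy()
    for it in range(ctrl.max_newton):
        x = y[:n] * x_scale
        pvec[pidx] = y[n] * p_scale
        f = rhs(network, x, pvec)
        g = np.concatenate([f, [tangent @ (y - y_pred)]])
        if np.max(np.abs(f)) <= ctrl.newton_tol * max(1.0, np.max(np.abs(x))) and abs(
            g[-1]
        ) <= 1e-12:
            return y, True
        J = jacobian_x(network, x, pvec) * x_scale[None, :]
        fp = jacobian_p(network, x, pvec)[:, pidx] * p_scale
        Jful = np.zeros((n + 1, n + 1))
        Jful[:n, :n] = J
        Jful[:n, n] = fp
        Jful[n, :] = tangent
        try:
            step = np.linalg.solve(Jful, -g)
        except np.linalg.LinAlgError:
            return y, False
        y = y + step
        if not np.all(np.isfinite(y)):
            return y, False
    return y, False


def _refine_fold(network, pvec, pidx, x_guess, v_guess, ctrl):
    """Moore-Spence refinement: solve {f=0, Jv=0, c'v=1} for (x, v, p)."""
    n = network.n_species
    c = v_guess / (v_guess @ v_guess)
    Qs = _hessian_forms(network, pvec)
    e_q = np.zeros(network.n_parameters)
    e_q[pidx] = 1.0

    def fun(z):
        x, v, pv = z[:n], z[n : 2 * n], z[2 * n]
        pvec[pidx] = pv
        J = jacobian_x(network, x, pvec)
        return np.concatenate([rhs(network, x, pvec), J @ v, [c @ v - 1.0]])

    def jac(z):
        x, v, pv = z[:n], z[n : 2 * n], z[2 * n]
        pvec[pidx] = pv
        J = jacobian_x(network, x, pvec)
        Jp = jacobian_p(network, x, pvec)[:, pidx]
        dJv_dx = np.array([2.0 * (Q @ v) for Q in Qs])
        dJv_dp = jacobian_x(network, x, e_q) @ v
        M = np.zeros((2 * n + 1, 2 * n + 1))
        M[:n, :n] = J
        M[:n, 2 * n] = Jp
        M[n : 2 * n, :n] = dJv_dx
        M[n : 2 * n, n : 2 * n] = J
        M[n : 2 * n, 2 * n] = dJv_dp
        M[2 * n, n : 2 * n] = c
        return M

    z0 = np.concatenate([x_guess, v_guess, [pvec[pidx]]])
    sol = root(fun, z0, jac=jac, method="hybr", tol=1e-12)
    if not sol.success:
        return None
    x, v, pv = sol.x[:n], sol.x[n : 2 * n], sol.x[2 * n]
    return x, v / np.linalg.norm(v), pv


def continue_equilibria(
    network: ReactionNetwork,
    p,
    param: str,
    param_range: tuple,
    start_state=None,
    step_control: StepControl | None = None,
) -> Branch:
    """Trace the equilibrium branch through the nominal point across
    ``param_range``, detecting and refining folds.

    ``start_state`` defaults to a Newton solve from a positive guess; pass
    an equilibrium of the nominal system for reliability.
    """
    ctrl = step_control or StepControl()
    pvec = _params(network, p).copy()
    pidx = network.parameter_index(param)
    lo, hi = float(param_range[0]), float(param_range[1])
    if not (lo <= pvec[pidx] <= hi):
        raise ValueError("nominal parameter value must lie inside param_range")
    if start_state is None:
        start_state = np.ones(network.n_species)
    x0, res, ok, _ = newton_refine(network, pvec, start_state, tol=ctrl.newton_tol)
    if not ok:
        raise ValueError("failed to locate starting equilibrium")
    x_scale = np.maximum(np.abs(x0), 1.0)
    p_scale = max(abs(pvec[pidx]), 1e-6)
    n = network.n_species

    segments = []
    message = ""
    for direction in (+1.0, -1.0):
        pv = pvec.copy()
        y = np.concatenate([x0 / x_scale, [pv[pidx] / p_scale]])
        tangent = np.zeros(n + 1)
        tangent[n] = direction
        h = ctrl.initial
        pts = [(pv[pidx], x0.copy())]
        npts = 1
        while npts < ctrl.max_points:
            y_pred = y + h * tangent
            y_new, ok = _corrector(network, pv, pidx, y_pred, tangent, x_scale,
                                   p_scale, ctrl)
            if not ok:
                h *= ctrl.shrink
                if h < ctrl.min_step:
                    message = (
                        f"step underflow at {param}={y[n]*p_scale:.6g}; "
                        "branch truncated"
                    )
                    break
                continue
            tangent_new = y_new - y
            nrm = np.linalg.norm(tangent_new)
            if nrm > 0:
                tangent = tangent_new / nrm
            y = y_new
            pval = y[n] * p_scale
            pts.append((pval, y[:n] * x_scale))
            npts += 1
            h = min(h * ctrl.grow, ctrl.max_step)
            if pval > hi or pval < lo:
                break
        segments.append(pts)

    # merge: reverse the backward segment and append the forward one
    pts = segments[1][::-1] + segments[0][1:]
    branch = Branch((param,), pts, message=message)

    # stability and fold detection via det(J) sign change
    dets, stab = [], []
    for pval, x in pts:
        pvec[pidx] = pval
        J = jacobian_x(network, x, pvec)
        dets.append(np.linalg.det(J))
        stab.append(bool(np.max(np.linalg.eigvals(J).real) < 0))
    branch.stability = stab
    for i in range(len(pts) - 1):
        if dets[i] == 0 or np.sign(dets[i]) == np.sign(dets[i + 1]):
            continue
        pval, x = pts[i] if abs(dets[i]) < abs(dets[i + 1]) else pts[i + 1]
        pvec[pidx] = pval
        J = jacobian_x(network, x, pvec)
        w, V = np.linalg.eig(J)
        v0 = np.real(V[:, np.argmin(np.abs(w))])
        ref = _refine_fold(network, pvec.copy(), pidx, x, v0, ctrl)
        if ref is None:
            continue
        xf, vf, pf = ref
        if lo <= pf <= hi and not any(
            abs(pf - f.parameter) <= 1e-8 * max(1.0, abs(pf)) for f in branch.folds
        ):
            branch.folds.append(FoldPoint(float(pf), xf, vf))
    branch.folds.sort(key=lambda f: f.parameter)
    return branch


def bistable_interval(branch: Branch):
    """Parameter interval between the two folds of an S-shaped branch;
    ``None`` unless exactly two folds are present."""
    if len(branch.folds) != 2:
        return None
    a, b = (f.parameter for f in branch.folds)
    return (min(a, b), max(a, b))


def _fold_normal_form_b(network, pvec, x, v):
    """Coefficient b = w' f_xx(v,v) at a fold (w: left null vector)."""
    J = jacobian_x(network, x, pvec)
    wl, Vl = np.linalg.eig(J.T)
    w = np.real(Vl[:, np.argmin(np.abs(wl))])
    Qs = _hessian_forms(network, pvec)
    fvv = np.array([2.0 * (v @ Q @ v) for Q in Qs])
    b = w @ fvv
    # fix w's sign convention so b is continuous along the curve: normalize
    # by sign of w . v-independent reference (first nonzero component)
    k = np.argmax(np.abs(w))
    return b * np.sign(w[k]) * np.sign(v[np.argmax(np.abs(v))] or 1.0)


def continue_fold_curve(
    network: ReactionNetwork,
    p,
    params: tuple,
    start: FoldPoint,
    param_ranges: tuple,
    step_control: StepControl | None = None,
    cusp_rtol: float = 1e-4,
) -> tuple[Branch, list[CuspPoint]]:
    """Continue the Moore-Spence fold system in two parameters.

    ``start`` is a fold of the one-parameter branch in ``params[1]`` (with
    ``params[0]`` at nominal).  Both directions along the curve are traced
    until either parameter leaves its range.  Returns the fold curve (as a
    Branch whose points carry (p_a, p_b) tuples) and the refined cusps.
    """
    ctrl = step_control or StepControl()
    pvec = _params(network, p).copy()
    ia, ib = (network.parameter_index(q) for q in params)
    (a_lo, a_hi), (b_lo, b_hi) = param_ranges
    n = network.n_species
    v0 = start.null_vector / np.linalg.norm(start.null_vector)
    c = v0.copy()
    x_scale = np.maximum(np.abs(start.state), 1.0)
    a_scale = max(abs(pvec[ia]), 1e-6)
    b_scale = max(abs(start.parameter), 1e-6)
    e_a = np.zeros(network.n_parameters)
    e_a[ia] = 1.0
    e_b = np.zeros(network.n_parameters)
    e_b[ib] = 1.0

    def unpack(y):
        return y[:n] * x_scale, y[n : 2 * n], y[2 * n] * a_scale, y[2 * n + 1] * b_scale

    def residual(y, pv):
        x, v, pa, pb = unpack(y)
        pv[ia], pv[ib] = pa, pb
        J = jacobian_x(network, x, pv)
        return np.concatenate([rhs(network, x, pv), J @ v, [c @ v - 1.0]])

    def jac_aug(y, pv):
        x, v, pa, pb = unpack(y)
        pv[ia], pv[ib] = pa, pb
        J = jacobian_x(network, x, pv)
        Jp = jacobian_p(network, x, pv)
        Qs = _hessian_forms(network, pv)
        dJv_dx = np.array([2.0 * (Q @ v) for Q in Qs])
        M = np.zeros((2 * n + 1, 2 * n + 2))
        M[:n, :n] = J * x_scale[None, :]
        M[:n, 2 * n] = Jp[:, ia] * a_scale
        M[:n, 2 * n + 1] = Jp[:, ib] * b_scale
        M[n : 2 * n, :n] = dJv_dx * x_scale[None, :]
        M[n : 2 * n, n : 2 * n] = J
        M[n : 2 * n, 2 * n] = (jacobian_x(network, x, e_a) @ v) * a_scale
        M[n : 2 * n, 2 * n + 1] = (jacobian_x(network, x, e_b) @ v) * b_scale
        M[2 * n, n : 2 * n] = c
        return M

    def correct(y_pred, tangent, pv):
        y = y_pred.copy()
        for _ in range(ctrl.max_newton):
            g = np.concatenate([residual(y, pv), [tangent @ (y - y_pred)]])
            if np.max(np.abs(g[:-1])) <= 1e-9 and abs(g[-1]) <= 1e-12:
                return y, True
            M = np.vstack([jac_aug(y, pv), tangent])
            try:
                y = y + np.linalg.solve(M, -g)
            except np.linalg.LinAlgError:
                return y, False
            if not np.all(np.isfinite(y)):
                return y, False
        return y, False

    def b_coef(y, pv):
        x, v, pa, pb = unpack(y)
        pv[ia], pv[ib] = pa, pb
        return _fold_normal_form_b(network, pv, x, v / np.linalg.norm(v))

    y_start = np.concatenate(
        [start.state / x_scale, v0, [pvec[ia] / a_scale, start.parameter / b_scale]]
    )
    res0 = residual(y_start, pvec.copy())
    if np.max(np.abs(res0[:n])) > 1e-2 * max(1.0, float(np.max(np.abs(start.state)))):
        raise ValueError("starting point does not satisfy the fold system")
    # polish the start point on the augmented system
    tang0 = np.zeros(2 * n + 2)
    tang0[2 * n] = 1.0
    y_start, ok = correct(y_start, tang0, pvec.copy())
    if not ok:
        raise ValueError("starting fold point does not satisfy the fold system")

    curve_pts = []
    cusps: list[CuspPoint] = []
    message = ""
    for direction in (+1.0, -1.0):
        pv = pvec.copy()
        y = y_start.copy()
        tangent = tang0 * direction
        h = ctrl.initial
        prev_b = b_coef(y, pv)
        seg = []
        while len(seg) < ctrl.max_points:
            y_pred = y + h * tangent
            y_new, ok = correct(y_pred, tangent, pv)
            if not ok:
                h *= ctrl.shrink
                if h < ctrl.min_step:
                    message = "fold-curve step underflow; curve truncated"
                    break
                continue
            new_b = b_coef(y_new, pv)
            if np.sign(new_b) != np.sign(prev_b) and prev_b != 0:
                cusp = _bisect_cusp(y, y_new, tangent, correct, b_coef, unpack,
                                    pv, cusp_rtol)
                if cusp is not None:
                    cusps.append(cusp)
            prev_b = new_b
            t_new = y_new - y
            nrm = np.linalg.norm(t_new)
            if nrm > 0:
                tangent = t_new / nrm
            y = y_new
            x, v, pa, pb = unpack(y)
            seg.append(((pa, pb), x.copy()))
            h = min(h * ctrl.grow, ctrl.max_step)
            if not (a_lo <= pa <= a_hi and b_lo <= pb <= b_hi):
                break
        if direction > 0:
            curve_pts.extend(seg)
        else:
            curve_pts = seg[::-1] + curve_pts
    curve = Branch(tuple(params), curve_pts, message=message)
    # deduplicate cusps
    uniq = []
    for cp in cusps:
        if not any(
            np.allclose(cp.parameters, u.parameters, rtol=10 * cusp_rtol) for u in uniq
        ):
            uniq.append(cp)
    return curve, uniq


def _bisect_cusp(y_a, y_b, tangent, correct, b_coef, unpack, pv, rtol):
    """Bisection along the curve segment [y_a, y_b] for the b = 0 point."""
    b_a = b_coef(y_a, pv)
    for _ in range(80):
        y_mid_pred = 0.5 * (y_a + y_b)
        y_mid, ok = correct(y_mid_pred, tangent, pv)
        if not ok:
            return None
        b_mid = b_coef(y_mid, pv)
        if np.sign(b_mid) == np.sign(b_a):
            y_a, b_a = y_mid, b_mid
        else:
            y_b = y_mid
        _, _, pa_a, pb_a = unpack(y_a)
        _, _, pa_b, pb_b = unpack(y_b)
        if (
            abs(pa_a - pa_b) <= rtol * max(1e-3, abs(pa_a), abs(pa_b))
            and abs(pb_a - pb_b) <= rtol * max(1e-3, abs(pb_a), abs(pb_b))
        ):
            break
    x, v, pa, pb = unpack(y_b)
    return CuspPoint((float(pa), float(pb)), x.copy())
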