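"""Steady-state exclusion certificates and robust-bistability workflow.

The bilinear steady-state system ``{N v(x,p) = 0, x in X, p in B_p}`` is
relaxed to a linear program by lifting every reaction rate and every
bilinear monomial into its own variable constrained by interval bounds and
McCormick envelopes.  An infeasible relaxation — established by a phase-1
LP whose optimum is strictly positive, with an independently verified
Farkas-style dual witness — certifies that the state box contains no
steady state for ANY parameter in the box.  A second tier strengthens the
relaxation with cutting planes from the positive-semidefiniteness of the
lifted moment matrix ``[[1, z'], [z, Z]]``.

The two-box workflow shrinks outer approximations seeded from the
certified DA boxes and reports whether the resulting robust steady-state
boxes are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .domain_of_attraction.boxes import AxisBox
from .network_model.dynamics import _params, rhs
from .network_model.equilibria import newton_refine
from .network_model.fixtures import (
    GAL_DA_BOX_HIGH,
    GAL_DA_BOX_LOW,
    GAL_EQUILIBRIUM_HIGH,
    GAL_EQUILIBRIUM_LOW,
)
from .network_model.reactions import ReactionNetwork

__all__ = [
    "ParameterBox",
    "ExclusionCertificate",
    "RobustBoxResult",
    "exclusion_certificate",
    "shrink_robust_box",
    "robust_bistability",
    "printed_initial_boxes",
    "scale_outer_box",
    "DEFAULT_THETA",
]

DEFAULT_THETA = ("k1", "k2", "k5", "k7", "k8", "k9", "mu13", "mu16", "mu17")


@dataclass
class ParameterBox:
    """Per-parameter intervals; parameters outside ``free_set`` are pinned
    to their nominal value."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray
    free_set: frozenset

    def __post_init__(self) -> None:
        if np.any(self.lower <= 0) or np.any(self.lower > self.upper):
            raise ValueError("parameter intervals must be positive with lower <= upper")

    @classmethod
    def from_delta(
        cls, network: ReactionNetwork, p_nominal, theta, delta_percent: float
    ) -> "ParameterBox":
        """Box of +-delta_percent around nominal on the subset ``theta``."""
        p = _params(network, p_nominal)
        lo, hi = p.copy(), p.copy()
        f = delta_percent / 100.0
        for name in theta:
            i = network.parameter_index(name)
            lo[i] = p[i] * (1.0 - f)
            hi[i] = p[i] * (1.0 + f)
        return cls(network.parameter_names, lo, hi, frozenset(theta))

    @classmethod
    def point(cls, network: ReactionNetwork, p_nominal) -> "ParameterBox":
        p = _params(network, p_nominal)
        return cls(network.parameter_names, p.copy(), p.copy(), frozenset())

    def contains(self, p, rtol: float = 0.0) -> bool:
        p = np.asarray(p, dtype=float)
        pad = rtol * np.maximum(self.upper, 1.0)
        return bool(np.all(p >= self.lower - pad) and np.all(p <= self.upper + pad))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)


@dataclass
class ExclusionCertificate:
    state_box: AxisBox
    param_box: ParameterBox
    verdict: str  # "certified-empty" | "unknown"
    tier: int = 1
    witness: dict = field(default_factory=dict)
    diagnostic: str = ""

    @property
    def certified_empty(self) -> bool:
        return self.verdict == "certified-empty"


# ---------------------------------------------------------------------------
# relaxation assembly


def _mccormick_rows(iz, iu, iv, ul, uu, vl, vu, alpha, nvar):
    """Rows (A, b) encoding z = alpha * u * v relaxed over the rectangle."""
    rows, rhs_ = [], []

    def row(cz, cu, cv, b):  # cz*z + cu*u + cv*v <= b
        r = np.zeros(nvar)
        r[iz] += cz
        r[iu] += cu
        r[iv] += cv
        rows.append(r)
        rhs_.append(b)

    a = alpha
    # z >= a(ul v + vl u - ul vl)  ->  -z + a ul v + a vl u <= a ul vl
    row(-1.0, a * vl, a * ul, a * ul * vl)
    row(-1.0, a * vu, a * uu, a * uu * vu)
    # z <= a(ul v + vu u - ul vu)
    row(1.0, -a * vu, -a * ul, -a * ul * vu)
    row(1.0, -a * vl, -a * uu, -a * uu * vl)
    return rows, rhs_


class _Relaxation:
    """Variable layout and LP data for one (state box, parameter box)."""

    def __init__(self, network: ReactionNetwork, state_box: AxisBox,
                 param_box: ParameterBox, tier: int = 1):
        if state_box.frame != "absolute":
            raise ValueError("exclusion certificates use absolute-frame state boxes")
        self.network = network
        n, nr = network.n_species, network.n_reactions
        xl, xu = state_box.lower.copy(), state_box.upper.copy()
        if np.any(xl < 0):
            xl = np.maximum(xl, 0.0)

        free_idx = sorted(
            network.parameter_index(q) for q in param_box.free_set
        )
        self.free_idx = free_idx
        pos_of_free = {q: k for k, q in enumerate(free_idx)}

        # monomial pairs (a, b) with a <= b used by bimolecular reactions
        pairs = []
        pair_pos = {}
        ridx = network._reactant_idx
        for j in range(nr):
            a, b = ridx[j]
            if a >= 0 and b >= 0:
                key = (min(a, b), max(a, b))
                if key not in pair_pos:
                    pair_pos[key] = len(pairs)
                    pairs.append(key)
        self.pairs = pairs

        # variable layout: [x | pf | m | w | (Y)]
        self.ix = 0
        self.ipf = n
        self.im = n + len(free_idx)
        self.iw = self.im + len(pairs)
        nvar = self.iw + nr
        self.zeta_dim = self.iw  # moment vector is [x, pf, m]
        if tier >= 2:
            self.iY = nvar
            d = self.zeta_dim
            self.Y_index = {}
            for i in range(d):
                for j in range(i, d):
                    self.Y_index[(i, j)] = nvar
                    nvar += 1
        self.nvar = nvar
        self.tier = tier

        lb = np.full(nvar, -np.inf)
        ub = np.full(nvar, np.inf)
        lb[self.ix : self.ix + n] = xl
        ub[self.ix : self.ix + n] = xu
        pl = param_box.lower[free_idx] if free_idx else np.zeros(0)
        pu = param_box.upper[free_idx] if free_idx else np.zeros(0)
        lb[self.ipf : self.ipf + len(free_idx)] = pl
        ub[self.ipf : self.ipf + len(free_idx)] = pu

        A_ub_rows, b_ub = [], []
        A_eq_rows, b_eq = [], []

        def interval_mul(al, au, bl, bu):
            c = np.array([al * bl, al * bu, au * bl, au * bu])
            return c.min(), c.max()

        # pair monomials with McCormick envelopes
        for k, (a, b) in enumerate(pairs):
            iz = self.im + k
            ml, mu = interval_mul(xl[a], xu[a], xl[b], xu[b])
            lb[iz], ub[iz] = ml, mu
            if a == b:
                # z = x^2: secant above, tangents below
                r = np.zeros(nvar)
                r[iz] = 1.0
                r[a] = -(xl[a] + xu[a])
                A_ub_rows.append(r)
                b_ub.append(-xl[a] * xu[a])
                for t in (xl[a], xu[a]):
                    r = np.zeros(nvar)
                    r[iz] = -1.0
                    r[a] = 2.0 * t
                    A_ub_rows.append(r)
                    b_ub.append(t * t)
            else:
                rows, rr = _mccormick_rows(iz, a, b, xl[a], xu[a], xl[b], xu[b],
                                           1.0, nvar)
                A_ub_rows.extend(rows)
                b_ub.extend(rr)

        # reaction rates
        p_nom_lo = param_box.lower
        cfac = network._const_factor
        rp = network._react_param
        for j in range(nr):
            iw = self.iw + j
            a, b = ridx[j]
            q = rp[j]
            is_free = q in pos_of_free
            c = cfac[j]
            if a < 0:  # zero order
                if is_free:
                    ipq = self.ipf + pos_of_free[q]
                    r = np.zeros(nvar)
                    r[iw] = 1.0
                    r[ipq] = -c
                    A_eq_rows.append(r)
                    b_eq.append(0.0)
                    wl, wu = c * param_box.lower[q], c * param_box.upper[q]
                else:
                    wl = wu = c * p_nom_lo[q]
            elif b < 0:  # first order in species a
                if is_free:
                    ipq = self.ipf + pos_of_free[q]
                    rows, rr = _mccormick_rows(
                        iw, ipq, a, param_box.lower[q], param_box.upper[q],
                        xl[a], xu[a], c, nvar,
                    )
                    A_ub_rows.extend(rows)
                    b_ub.extend(rr)
                    wl, wu = (
                        c * param_box.lower[q] * xl[a],
                        c * param_box.upper[q] * xu[a],
                    )
                    if self.tier >= 2:
                        # Y[pf_q, x_a] * c == w_j
                        iy = self._y(self.ipf + pos_of_free[q] - 0, a)
                        r = np.zeros(nvar)
                        r[iw] = 1.0
                        r[iy] = -c
                        A_eq_rows.append(r)
                        b_eq.append(0.0)
                else:
                    kk = c * p_nom_lo[q]
                    r = np.zeros(nvar)
                    r[iw] = 1.0
                    r[a] = -kk
                    A_eq_rows.append(r)
                    b_eq.append(0.0)
                    wl, wu = sorted((kk * xl[a], kk * xu[a]))
            else:  # bimolecular via pair monomial
                key = (min(a, b), max(a, b))
                imono = self.im + pair_pos[key]
                ml, mu = lb[imono], ub[imono]
                if is_free:
                    ipq = self.ipf + pos_of_free[q]
                    rows, rr = _mccormick_rows(
                        iw, ipq, imono, param_box.lower[q], param_box.upper[q],
                        ml, mu, c, nvar,
                    )
                    A_ub_rows.extend(rows)
                    b_ub.extend(rr)
                    wl = min(c * param_box.lower[q] * ml, c * param_box.lower[q] * mu,
                             c * param_box.upper[q] * ml, c * param_box.upper[q] * mu)
                    wu = max(c * param_box.lower[q] * ml, c * param_box.upper[q] * mu)
                    if self.tier >= 2:
                        iy = self._y(ipq, imono)
                        r = np.zeros(nvar)
                        r[iw] = 1.0
                        r[iy] = -c
                        A_eq_rows.append(r)
                        b_eq.append(0.0)
                else:
                    kk = c * p_nom_lo[q]
                    r = np.zeros(nvar)
                    r[iw] = 1.0
                    r[imono] = -kk
                    A_eq_rows.append(r)
                    b_eq.append(0.0)
                    wl, wu = sorted((kk * ml, kk * mu))
            lb[iw], ub[iw] = wl, wu

        # tier-2 moment entries: bounds + McCormick against the factors,
        # and identification with existing lifted variables where possible
        if tier >= 2:
            zl = lb[: self.zeta_dim].copy()
            zu = ub[: self.zeta_dim].copy()
            for (i, j), iy in self.Y_index.items():
                yl, yu = interval_mul(zl[i], zu[i], zl[j], zu[j])
                lb[iy], ub[iy] = yl, yu
                known = self._known_product(i, j, pair_pos, n)
                if known is not None:
                    r = np.zeros(nvar)
                    r[iy] = 1.0
                    r[known] = -1.0
                    A_eq_rows.append(r)
                    b_eq.append(0.0)
                elif i == j:
                    r = np.zeros(nvar)
                    r[iy] = 1.0
                    r[i] = -(zl[i] + zu[i])
                    A_ub_rows.append(r)
                    b_ub.append(-zl[i] * zu[i])
                    for t in (zl[i], zu[i]):
                        r = np.zeros(nvar)
                        r[iy] = -1.0
                        r[i] = 2.0 * t
                        A_ub_rows.append(r)
                        b_ub.append(t * t)
                else:
                    rows, rr = _mccormick_rows(iy, i, j, zl[i], zu[i], zl[j],
                                               zu[j], 1.0, nvar)
                    A_ub_rows.extend(rows)
                    b_ub.extend(rr)

        # steady-state rows N w = 0 (these are the slacked rows)
        N = network._N
        self.A_ss = np.zeros((n, nvar))
        self.A_ss[:, self.iw : self.iw + nr] = N
        self.A_ub = np.array(A_ub_rows) if A_ub_rows else np.zeros((0, nvar))
        self.b_ub = np.array(b_ub)
        self.A_eq = np.array(A_eq_rows) if A_eq_rows else np.zeros((0, nvar))
        self.b_eq = np.array(b_eq)
        self.lb, self.ub_v = lb, ub
        # scale of the steady-state rows for tolerance decisions
        wmax = np.maximum(np.abs(lb[self.iw:self.iw+nr]), np.abs(ub[self.iw:self.iw+nr]))
        self.ss_scale = max(1.0, float(np.max(wmax)))

    def _y(self, i, j):
        return self.Y_index[(min(i, j), max(i, j))]

    def _known_product(self, i, j, pair_pos, n):
        """Index of an existing variable equal to zeta_i * zeta_j, if any."""
        if i < n and j < n:
            key = (min(i, j), max(i, j))
            if key in pair_pos:
                return self.im + pair_pos[key]
        return None

    def moment_block(self, z):
        d = self.zeta_dim
        B = np.empty((d + 1, d + 1))
        B[0, 0] = 1.0
        B[0, 1:] = z[:d]
        B[1:, 0] = z[:d]
        for (i, j), iy in self.Y_index.items():
            B[1 + i, 1 + j] = z[iy]
            B[1 + j, 1 + i] = z[iy]
        return B

    def moment_cut(self, v):
        """Row (r, b) with r . z <= b encoding v' [[1, z'],[z, Y]] v >= 0."""
        r = np.zeros(self.nvar)
        d = self.zeta_dim
        r[:d] -= 2.0 * v[0] * v[1:]
        for (i, j), iy in self.Y_index.items():
            r[iy] -= v[1 + i] * v[1 + j] * (2.0 if i != j else 1.0)
        return r, v[0] * v[0]


def _phase1(relax: _Relaxation, extra_ub=None, extra_b=None):
    """Minimize the l1 slack of the steady-state rows; returns
    (optimum, solution, duals) or (None, None, None) on solver failure."""
    nvar, n = relax.nvar, relax.A_ss.shape[0]
    # variables [z, s+, s-]; A_ss z + s+ - s- = 0
    c = np.concatenate([np.zeros(nvar), np.ones(2 * n)])
    A_eq = np.vstack(
        [
            np.hstack([relax.A_ss, np.eye(n), -np.eye(n)]),
            np.hstack([relax.A_eq, np.zeros((relax.A_eq.shape[0], 2 * n))]),
        ]
    )
    b_eq = np.concatenate([np.zeros(n), relax.b_eq])
    A_ub = relax.A_ub
    b_ub = relax.b_ub
    if extra_ub is not None and len(extra_ub):
        A_ub = np.vstack([A_ub, np.array(extra_ub)])
        b_ub = np.concatenate([b_ub, np.array(extra_b)])
    A_ub = np.hstack([A_ub, np.zeros((A_ub.shape[0], 2 * n))])
    bounds = [(relax.lb[i], relax.ub_v[i]) for i in range(nvar)] + [(0, None)] * (
        2 * n
    )
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    if res.status != 0:
        return None, None, None
    duals = {
        "eq": res.eqlin.marginals,
        "ub": res.ineqlin.marginals,
        "lower": res.lower.marginals[:nvar],
        "upper": res.upper.marginals[:nvar],
    }
    return float(res.fun), res.x[:nvar], duals


def _witness_bound(relax, y_ss, y_def, y_ub, A_ub, b_ub) -> float:
    """Rigorous lower bound on min ||A_ss z||_1 over the hard-feasible set.

    For any multipliers with ``||y_ss||_inf <= 1`` and ``y_ub <= 0``:
    ``||A_ss z||_1 >= y_ss'A_ss z
                   = phi'z + y_def'(A_eq z) + y_ub'(A_ub z)
                  >= min_bounds phi'z + y_def'b_eq + y_ub'b_ub``
    with ``phi = A_ss'y_ss - A_eq'y_def - A_ub'y_ub``; a strictly positive
    bound proves that no steady state exists in the boxes.
    """
    y_ss = np.clip(y_ss, -1.0, 1.0)
    y_ub = np.minimum(y_ub, 0.0)
    phi = y_ss @ relax.A_ss - y_def @ relax.A_eq - y_ub @ A_ub
    zmin = np.where(phi > 0, relax.lb, relax.ub_v)
    return float(phi @ zmin + y_def @ relax.b_eq + y_ub @ b_ub)


def _verify_witness(relax, duals, extra_ub, extra_b, tol):
    """Independent re-check of an infeasibility witness via weak duality.

    The LP solver's multiplier sign conventions are not relied upon: all
    sign combinations are clipped into the valid dual cone and the best
    resulting bound is used, so a ``True`` here is sound regardless of the
    solver's conventions.
    """
    n = relax.A_ss.shape[0]
    y_eq = np.asarray(duals["eq"], dtype=float)
    y_ub0 = np.asarray(duals["ub"], dtype=float)
    A_ub = relax.A_ub
    b_ub = relax.b_ub
    if extra_ub is not None and len(extra_ub):
        A_ub = np.vstack([A_ub, np.array(extra_ub)])
        b_ub = np.concatenate([b_ub, np.array(extra_b)])
    best = -np.inf
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            best = max(
                best,
                _witness_bound(relax, s1 * y_eq[:n], s1 * y_eq[n:],
                               s2 * y_ub0, A_ub, b_ub),
            )
    return best > tol


def exclusion_certificate(
    network: ReactionNetwork,
    state_box: AxisBox,
    param_box: ParameterBox,
    tier: str | int = "auto",
    max_psd_iterations: int = 40,
) -> ExclusionCertificate:
    """Try to certify that ``state_box`` contains no steady state for any
    parameter in ``param_box``.

    ``tier`` 1 uses the pure McCormick LP; 2 adds lifted moment-matrix
    cutting planes; "auto" escalates to 2 only when tier 1 is inconclusive.
    Solver failures yield "unknown" — never a certificate.
    """
    tiers = [1, 2] if tier == "auto" else [int(tier)]
    last_diag = ""
    for t in tiers:
        relax = _Relaxation(network, state_box, param_box, tier=t)
        tol = 1e-7 * relax.ss_scale
        cuts_A: list = []
        cuts_b: list = []
        for it in range(max_psd_iterations if t >= 2 else 1):
            opt, z, duals = _phase1(relax, cuts_A, cuts_b)
            if opt is None:
                last_diag = "phase-1 LP solver failure"
                break
            if opt > tol:
                if _verify_witness(relax, duals, cuts_A, cuts_b, 0.5 * tol):
                    return ExclusionCertificate(
                        state_box, param_box, "certified-empty", t,
                        witness={
                            "phase1_optimum": opt,
                            "duals_eq": np.asarray(duals["eq"]).tolist(),
                            "duals_ub": np.asarray(duals["ub"]).tolist(),
                            "n_psd_cuts": len(cuts_A),
                        },
                        diagnostic=f"phase-1 optimum {opt:.3e}",
                    )
                last_diag = "witness verification failed"
                break
            if t < 2:
                last_diag = f"relaxation feasible (slack {opt:.2e})"
                break
            B = relax.moment_block(z)
            w, V = np.linalg.eigh(B)
            if w[0] >= -1e-9 * max(1.0, np.max(np.abs(B))):
                last_diag = f"moment relaxation feasible (slack {opt:.2e})"
                break
            for k in range(min(3, len(w))):
                if w[k] < 0:
                    r, b = relax.moment_cut(V[:, k])
                    cuts_A.append(r)
                    cuts_b.append(b)
        else:
            last_diag = "PSD cut budget exhausted"
    return ExclusionCertificate(state_box, param_box, "unknown", tiers[-1],
                                diagnostic=last_diag)


# ---------------------------------------------------------------------------
# shrinkage and the two-box workflow


def shrink_robust_box(
    network: ReactionNetwork,
    initial_box: AxisBox,
    param_box: ParameterBox,
    slab_fraction: float = 0.1,
    max_rounds: int = 60,
    tier: str | int = "auto",
) -> tuple[AxisBox, list]:
    """Shrink a box by cutting certified-empty boundary slabs.

    Per round, every face is probed round-robin with a slab of width
    ``slab_fraction`` of the current interval; certified-empty slabs are
    removed.  Stops when a round makes no progress or after
    ``max_rounds``.  Soundness is inherited from the certificates: no
    steady state inside the initial box is ever cut away.
    """
    if not 0.0 <= slab_fraction < 1.0:
        raise ValueError("slab_fraction must be in [0, 1)")
    lo = initial_box.lower.copy()
    hi = initial_box.upper.copy()
    n = initial_box.n
    log = []
    if slab_fraction == 0.0:
        return AxisBox(lo, hi, "absolute"), log

    if tier == "auto":
        phases = [1, 2]
    else:
        phases = [int(tier)]

    def one_round(rnd, t):
        progress = False
        for face in range(2 * n):
            k = face % n
            width = (hi[k] - lo[k]) * slab_fraction
            if width <= 0:
                continue
            slo, shi = lo.copy(), hi.copy()
            if face < n:  # upper slab
                slo[k] = hi[k] - width
            else:
                shi[k] = lo[k] + width
            cert = exclusion_certificate(
                network, AxisBox(slo, shi, "absolute"), param_box, tier=t,
                max_psd_iterations=15,
            )
            log.append(
                {
                    "round": rnd,
                    "face": face,
                    "slab": [float(slo[k]), float(shi[k])],
                    "verdict": cert.verdict,
                    "tier": cert.tier,
                }
            )
            if cert.certified_empty:
                if face < n:
                    hi[k] -= width
                else:
                    lo[k] += width
                progress = True
        return progress

    # alternate phases: run the cheap relaxation until it stalls, then one
    # strengthened pass; return to the cheap tier whenever progress resumes
    rnd = 0
    phase = 0
    while rnd < max_rounds:
        progress = one_round(rnd, phases[phase])
        rnd += 1
        if progress:
            phase = 0
        else:
            phase += 1
            if phase >= len(phases):
                break
    return AxisBox(lo, hi, "absolute"), log


@dataclass
class RobustBoxResult:
    delta: float
    S1: AxisBox | None
    S2: AxisBox | None
    rho_1: float | None
    rho_2: float | None
    disjoint: bool | None
    separating_coordinates: list = field(default_factory=list)
    status: str = "ok"  # "ok" | "indeterminate"
    log: dict = field(default_factory=dict)

    def to_dict(self, names=None) -> dict:
        return {
            "delta": self.delta,
            "S1": self.S1.to_dict(names) if self.S1 is not None else None,
            "S2": self.S2.to_dict(names) if self.S2 is not None else None,
            "rho_1": self.rho_1,
            "rho_2": self.rho_2,
            "disjoint": self.disjoint,
            "separating_coordinates": self.separating_coordinates,
            "status": self.status,
        }


def scale_outer_box(box: AxisBox, rho: float) -> AxisBox:
    """Initial outer approximation ``[l / rho, u * rho]`` componentwise."""
    return AxisBox(box.lower / rho, box.upper * rho, "absolute")


def _tracked_equilibrium(network, p, x_ref):
    x, _, ok, _ = newton_refine(network, p, x_ref)
    return x if ok else None


def robust_bistability(
    network: ReactionNetwork,
    D1: AxisBox,
    D2: AxisBox,
    theta=DEFAULT_THETA,
    delta: float = 2.0,
    rho_grid=(1.0, 2.0, 4.0, 8.0),
    p_nominal=None,
    equilibria=None,
    slab_fraction: float = 0.1,
    max_rounds: int = 60,
    tier: str | int = "auto",
    n_rho_checks: int = 12,
    seed: int = 0,
) -> RobustBoxResult:
    """Two-box robust-bistability certificate at one uncertainty level.

    Builds the +-delta% parameter box on ``theta``, scales each DA box
    outward by the first ``rho`` in ``rho_grid`` whose scaled box contains
    the tracked equilibrium for a seeded sample of parameter draws, then
    shrinks both boxes by exclusion certificates and tests per-coordinate
    disjointness.
    """
    p = _params(network, p_nominal)
    pbox = ParameterBox.from_delta(network, p, theta, delta)
    if equilibria is None:
        x1 = _tracked_equilibrium(network, p, GAL_EQUILIBRIUM_LOW)
        x2 = _tracked_equilibrium(network, p, GAL_EQUILIBRIUM_HIGH)
    else:
        x1, x2 = (np.asarray(getattr(e, "state", e), dtype=float) for e in equilibria)
    rng = np.random.default_rng(seed)
    draws = [pbox.sample(rng) for _ in range(n_rho_checks)]

    def stays_local(xq, x_ref, x_other):
        # a tracked solution that lands nearer the other operating point
        # has jumped branches (e.g. past a fold) and does not constrain rho
        num = np.maximum(np.abs(xq), 1e-3)
        d_ref = np.max(np.abs(np.log(num / np.maximum(np.abs(x_ref), 1e-3))))
        d_oth = np.max(np.abs(np.log(num / np.maximum(np.abs(x_other), 1e-3))))
        return d_ref <= d_oth

    results = []
    for D, x_ref, x_other in ((D1, x1, x2), (D2, x2, x1)):
        chosen = None
        for rho in rho_grid:
            outer = scale_outer_box(D, rho)
            ok = outer.strictly_contains(x_ref)
            if ok:
                for pd in draws:
                    xq = _tracked_equilibrium(network, pd, x_ref)
                    if xq is None:
                        continue
                    if stays_local(xq, x_ref, x_other) and not outer.contains(xq):
                        ok = False
                        break
            if ok:
                chosen = (rho, outer)
                break
        results.append(chosen)
    if results[0] is None or results[1] is None:
        return RobustBoxResult(delta, None, None, None, None, None,
                               status="indeterminate",
                               log={"reason": "no rho yields a containing outer box"})
    (rho1, S10), (rho2, S20) = results
    S1, log1 = shrink_robust_box(network, S10, pbox, slab_fraction, max_rounds, tier)
    S2, log2 = shrink_robust_box(network, S20, pbox, slab_fraction, max_rounds, tier)
    sep = [
        int(k)
        for k in range(S1.n)
        if S1.upper[k] < S2.lower[k] or S2.upper[k] < S1.lower[k]
    ]
    return RobustBoxResult(
        delta, S1, S2, rho1, rho2, bool(sep), sep,
        log={"S1_cuts": log1, "S2_cuts": log2,
             "n_exclusion_calls": len(log1) + len(log2)},
    )


def printed_initial_boxes() -> tuple[AxisBox, AxisBox]:
    """The published initial outer approximations (rho = 4 scaling of the
    published DA boxes, as printed)."""
    S10 = AxisBox(
        np.array([25.214, 25.214, 0.0, 0.0, 0.175, 4.515, 0.648, 0.0, 0.0]),
        np.array([1251.211, 1331.199, 15.991, 16.0, 12.001, 96.242, 110.404,
                  12.001, 12.001]),
        "absolute",
    )
    S20 = AxisBox(
        np.array([52.898, 52.326, 4.619, 2.236, 0.0, 0.278, 22.269, 1.737, 1.987]),
        np.array([20852.800, 22664.821, 2701.988, 123.599, 2.80, 12.400,
                  6112.385, 235.601, 1283.6]),
        "absolute",
    )
    return S10, S20
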