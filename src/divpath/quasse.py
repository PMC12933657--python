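"""Trait-dependent diversification over a discretized continuous trait.

The model couples a diffusing trait x (Brownian motion, optionally with
mean-reverting drift toward an optimum) with trait-dependent speciation
lambda(x) and extinction mu(x) drawn from four functional families
(constant, linear, sigmoid, hump/unimodal).  Along each branch the clade
likelihood D(x, t) and extinction probability E(x, t) satisfy

    dD/dt = -(lambda + mu) D + 2 lambda E D   (+ trait operator)
    dE/dt = mu - (lambda + mu) E + lambda E^2 (+ trait operator)

which are integrated backward in time on a regular trait grid by operator
splitting: an RK4 reaction step and a Crank--Nicolson diffusion step with
reflecting boundaries (mean-reverting drift enters as an upwinded advection
term).  At internal nodes D <- D_left * D_right * lambda(x); at the root D
is integrated against a weighting (flat or D-weighted) and optionally
conditioned on the survival of the two root lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.optimize import minimize

from .phylo import PhyloTree

try:  # compiled time-stepping kernel; plain numpy path works without it
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@njit(cache=True)
def _steps_kernel(E, D, lam, mu, dt, nsteps, r, mainB, cp, denom, vel, cfl,
                  use_adv):
    """nsteps of (RK4 reaction, Crank-Nicolson diffusion, upwind advection)
    applied in place to E and D.  cp/denom are the precomputed Thomas-solver
    sweeps of the CN left-hand matrix."""
    n = E.shape[0]
    k_e = np.empty((4, n))
    k_d = np.empty((4, n))
    rhs = np.empty(n)
    work = np.empty(n)
    for _ in range(nsteps):
        # --- RK4 on the reaction terms
        for stage in range(4):
            if stage == 0:
                fe, fd = E, D
            elif stage == 1:
                fe, fd = E + 0.5 * dt * k_e[0], D + 0.5 * dt * k_d[0]
            elif stage == 2:
                fe, fd = E + 0.5 * dt * k_e[1], D + 0.5 * dt * k_d[1]
            else:
                fe, fd = E + dt * k_e[2], D + dt * k_d[2]
            for i in range(n):
                k_e[stage, i] = mu[i] - (lam[i] + mu[i]) * fe[i] \
                    + lam[i] * fe[i] * fe[i]
                k_d[stage, i] = -(lam[i] + mu[i]) * fd[i] \
                    + 2.0 * lam[i] * fe[i] * fd[i]
        for i in range(n):
            e = E[i] + dt / 6.0 * (k_e[0, i] + 2 * k_e[1, i]
                                   + 2 * k_e[2, i] + k_e[3, i])
            d = D[i] + dt / 6.0 * (k_d[0, i] + 2 * k_d[1, i]
                                   + 2 * k_d[2, i] + k_d[3, i])
            E[i] = min(max(e, 0.0), 1.0)
            D[i] = max(d, 0.0)
        # --- CN diffusion (Thomas solve) for E then D
        for which in range(2):
            u = E if which == 0 else D
            rhs[0] = mainB[0] * u[0] + r * u[1]
            for i in range(1, n - 1):
                rhs[i] = mainB[i] * u[i] + r * (u[i - 1] + u[i + 1])
            rhs[n - 1] = mainB[n - 1] * u[n - 1] + r * u[n - 2]
            work[0] = rhs[0] / denom[0]
            for i in range(1, n):
                work[i] = (rhs[i] + r * work[i - 1]) / denom[i]
            u[n - 1] = work[n - 1]
            for i in range(n - 2, -1, -1):
                u[i] = work[i] - cp[i] * u[i + 1]
            if which == 0:
                for i in range(n):
                    u[i] = min(max(u[i], 0.0), 1.0)
            else:
                for i in range(n):
                    u[i] = max(u[i], 0.0)
        # --- upwind advection for mean reversion
        if use_adv:
            for which in range(2):
                u = E if which == 0 else D
                for i in range(n):
                    work[i] = u[i]
                for i in range(n):
                    if vel[i] > 0:
                        dx_u = work[i + 1] - work[i] if i < n - 1 else 0.0
                    else:
                        dx_u = work[i] - work[i - 1] if i > 0 else 0.0
                    u[i] = work[i] + cfl * vel[i] * dx_u
                if which == 0:
                    for i in range(n):
                        u[i] = min(max(u[i], 0.0), 1.0)

__all__ = [
    "RateFn",
    "QuasseModel",
    "TraitGrid",
    "eval_rate_fn",
    "quasse_loglik",
    "fit_quasse",
]

FAMILIES = ("constant", "linear", "sigmoid", "hump")


def eval_rate_fn(family: str, params: dict, x):
    """Evaluate one rate family at trait values ``x`` (clamped at zero).

    constant: ``c``; linear: ``max(0, a + b x)``; sigmoid:
    ``y0 + (y1-y0)/(1+exp((xmid-x)/r))``; hump:
    ``y0 + (y1-y0) exp(-(x-xmid)^2/(2 s^2))``.
    """
    x = np.asarray(x, dtype=float)
    if family == "constant":
        out = np.full_like(x, float(params["c"]))
    elif family == "linear":
        out = params["a"] + params["b"] * x
    elif family == "sigmoid":
        y0, y1 = params["y0"], params["y1"]
        out = y0 + (y1 - y0) / (1.0 + np.exp((params["xmid"] - x) / params["r"]))
    elif family == "hump":
        y0, y1 = params["y0"], params["y1"]
        out = y0 + (y1 - y0) * np.exp(-((x - params["xmid"]) ** 2)
                                      / (2.0 * params["s"] ** 2))
    else:
        raise ValueError(f"unknown rate family {family!r}")
    return np.maximum(out, 0.0)


@dataclass
class RateFn:
    family: str
    params: dict

    def __call__(self, x):
        return eval_rate_fn(self.family, self.params, x)

    @property
    def n_params(self):
        return {"constant": 1, "linear": 2, "sigmoid": 4, "hump": 4}[self.family]


@dataclass
class QuasseModel:
    """lambda(x), mu(x), trait diffusion rate and optional mean reversion."""

    lam: RateFn
    mu: RateFn
    sigma2: float                      # trait-units^2 Myr^-1
    drift: tuple = None                # None (BM) or (alpha, theta) (OU-like)

    @property
    def n_params(self):
        k = self.lam.n_params + self.mu.n_params + 1
        if self.drift is not None:
            k += 2
        return k


@dataclass
class TraitGrid:
    n_bins: int
    x_min: float
    x_max: float

    def __post_init__(self):
        if self.n_bins < 64:
            raise ValueError("need at least 64 bins")
        if not self.x_max > self.x_min:
            raise ValueError("empty trait range")

    @property
    def xs(self):
        return np.linspace(self.x_min, self.x_max, self.n_bins)

    @property
    def dx(self):
        return (self.x_max - self.x_min) / (self.n_bins - 1)

    @classmethod
    def from_data(cls, values, sigma2: float, depth: float,
                  n_bins: int = 1024, pad_sd: float = 4.0) -> "TraitGrid":
        """Span the observed range padded by ``pad_sd`` diffusion standard
        deviations over the tree depth."""
        pad = pad_sd * np.sqrt(max(sigma2, 1e-12) * depth)
        lo, hi = float(np.min(values)), float(np.max(values))
        return cls(n_bins, lo - pad, hi + pad)


class _Stepper:
    """One operator-split time step on the grid (shared by E and D)."""

    def __init__(self, model: QuasseModel, grid: TraitGrid, dt: float):
        self.lam = model.lam(grid.xs)
        self.mu = model.mu(grid.xs)
        self.dt = dt
        n, dx = grid.n_bins, grid.dx
        # CN coefficient for u_t = (sigma^2/2) u_xx
        r = model.sigma2 * dt / (4.0 * dx * dx)
        # tridiagonal CN matrices with reflecting (Neumann) boundaries
        main_A = np.full(n, 1.0 + 2.0 * r)
        main_B = np.full(n, 1.0 - 2.0 * r)
        off = np.full(n - 1, -r)
        main_A[0] = main_A[-1] = 1.0 + r
        main_B[0] = main_B[-1] = 1.0 - r
        self.ab = np.zeros((3, n))
        self.ab[0, 1:] = off
        self.ab[1, :] = main_A
        self.ab[2, :-1] = off
        self.r = r
        self.main_B = main_B
        # precomputed Thomas sweep of the constant CN matrix
        self.denom = np.empty(n)
        self.cp = np.empty(n)
        self.denom[0] = main_A[0]
        self.cp[0] = -r / self.denom[0]
        for i in range(1, n):
            self.denom[i] = main_A[i] + r * self.cp[i - 1]
            self.cp[i] = -r / self.denom[i]
        # upwinded advection for mean reversion
        if model.drift is not None:
            alpha, theta = model.drift
            self.vel = alpha * (theta - grid.xs)
            self.cfl = dt / dx
            if np.abs(self.vel).max() * self.cfl > 0.9:
                raise ValueError("advection unstable: shrink dt or widen grid")
        else:
            self.vel = None

    def _diffuse(self, u):
        n = len(u)
        rhs = self.main_B * u
        rhs[1:] += self.r * u[:-1]
        rhs[:-1] += self.r * u[1:]
        out = solve_banded((1, 1), self.ab, rhs, check_finite=False)
        if self.vel is not None:
            dx_u = np.zeros_like(out)
            fwd = np.empty_like(out)
            fwd[:-1] = out[1:] - out[:-1]
            fwd[-1] = 0.0
            bwd = np.empty_like(out)
            bwd[1:] = out[1:] - out[:-1]
            bwd[0] = 0.0
            dx_u = np.where(self.vel > 0, fwd, bwd)
            out = out + self.cfl * self.vel * dx_u
        return out

    def _react(self, E, D):
        lam, mu, dt = self.lam, self.mu, self.dt

        def fE(e):
            return mu - (lam + mu) * e + lam * e * e

        def fD(e, d):
            return -(lam + mu) * d + 2.0 * lam * e * d

        k1e, k1d = fE(E), fD(E, D)
        k2e, k2d = fE(E + 0.5 * dt * k1e), fD(E + 0.5 * dt * k1e, D + 0.5 * dt * k1d)
        k3e, k3d = fE(E + 0.5 * dt * k2e), fD(E + 0.5 * dt * k2e, D + 0.5 * dt * k2d)
        k4e, k4d = fE(E + dt * k3e), fD(E + dt * k3e, D + dt * k3d)
        E2 = E + dt / 6.0 * (k1e + 2 * k2e + 2 * k3e + k4e)
        D2 = D + dt / 6.0 * (k1d + 2 * k2d + 2 * k3d + k4d)
        return np.clip(E2, 0.0, 1.0), np.maximum(D2, 0.0)

    def step(self, E, D):
        E, D = self._react(E, D)
        return np.clip(self._diffuse(E), 0.0, 1.0), np.maximum(self._diffuse(D), 0.0)

    def step_many(self, E, D, nsteps):
        if _HAVE_NUMBA:
            E = np.ascontiguousarray(E, dtype=float)
            D = np.ascontiguousarray(D, dtype=float)
            vel = self.vel if self.vel is not None else np.zeros(1)
            cfl = self.cfl if self.vel is not None else 0.0
            _steps_kernel(E, D, self.lam, self.mu, self.dt, nsteps, self.r,
                          self.main_B, self.cp, self.denom, vel, cfl,
                          self.vel is not None)
            return E, D
        for _ in range(nsteps):
            E, D = self.step(E, D)
        return E, D


def _propagate_branch(model, grid, E, D, t_total, dt_target):
    nsteps = max(1, int(np.ceil(t_total / dt_target)))
    stepper = _Stepper(model, grid, t_total / nsteps)
    return stepper.step_many(E, D, nsteps)


def quasse_loglik(tree: PhyloTree, tip_values: pd.Series, model: QuasseModel,
                  grid: TraitGrid = None, tip_sd: float = None,
                  root: str = "obs", condition_on_survival: bool = True,
                  dt_target: float = None, n_bins: int = 1024,
                  boundary_tol: float = 5e-3) -> float:
    """Pruning log-likelihood of the tree plus tip trait values.

    Tip states enter as Gaussian densities with standard deviation
    ``tip_sd`` (default: one grid cell).  ``root`` chooses the root
    weighting: ``"obs"`` weights by the normalized root D (the observed
    weighting) and ``"flat"`` uses an improper flat prior (weight one per
    trait unit).  Conditioning on survival divides by the weighted
    ``lambda(x) (1 - E(x))^2``.
    """
    if not tree.is_ultrametric(rtol=1e-3):
        raise ValueError("QuaSSE requires an ultrametric tree")
    y = tip_values.reindex(tree.tip_labels)
    if y.isna().any():
        raise ValueError(f"missing trait values for {list(y.index[y.isna()])}")
    depth = float(tree.tip_depths().mean())
    if grid is None:
        grid = TraitGrid.from_data(y.to_numpy(), model.sigma2, depth, n_bins)
    xs, dx = grid.xs, grid.dx
    if tip_sd is None:
        tip_sd = dx
    if dt_target is None:
        # resolve the shortest branch when affordable, but never take more
        # than ~1000 steps across the tree depth (short branches get at
        # least one step of their own either way)
        pos = tree.lengths[tree.lengths > 0]
        dt_target = max(min(pos.min() / 10.0, depth / 100.0), depth / 1000.0)

    lam_x = model.lam(xs)
    logcomp = 0.0
    states = {}
    for v in tree.postorder:
        kids = tree.children(v)
        if not kids:
            mu_ = float(y[tree.labels[v]])
            D = np.exp(-0.5 * ((xs - mu_) / tip_sd) ** 2) / (tip_sd * np.sqrt(2 * np.pi))
            E = np.zeros_like(xs)
            states[v] = (E, D)
        else:
            Es, Ds = [], []
            for c in kids:
                E, D = states.pop(c)
                E, D = _propagate_branch(model, grid, E, D, tree.lengths[c], dt_target)
                mass = np.trapezoid(D, dx=dx)
                if mass <= 0:
                    return -np.inf
                edge = (D[0] + D[-1]) * dx / mass
                if edge > boundary_tol:
                    raise ValueError(
                        "probability mass reached the trait-grid boundary; "
                        "widen the grid padding")
                logcomp += np.log(mass)
                Es.append(E)
                Ds.append(D / mass)
            D = Ds[0]
            for Dk in Ds[1:]:
                D = D * Dk * lam_x
            E = np.mean(Es, axis=0)
            states[v] = (E, D)
    E, D = states[tree.root]
    if root == "obs":
        w = D / max(np.trapezoid(D, dx=dx), 1e-300)
    elif root == "flat":
        w = np.ones_like(D)
    else:
        raise ValueError(f"unknown root weighting {root!r}")
    lik = np.trapezoid(w * D, dx=dx)
    if condition_on_survival:
        denom = np.trapezoid(w * lam_x * (1.0 - E) ** 2, dx=dx)
        if root == "flat":
            denom /= (grid.x_max - grid.x_min)
        lik /= max(denom, 1e-300)
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logcomp)


# ---------------------------------------------------------------------- fitting

def _pack(model_spec, values, tree):
    """Initial parameter vector and unpacker for one candidate spec."""
    lam_f, mu_f, drift = model_spec
    y = np.asarray(values, dtype=float)
    depth = tree.tip_depths().mean()
    lam0 = max(np.log(tree.n_tips) / depth, 0.05)
    mu0 = lam0 / 5.0
    s2_0 = max(np.var(y) / depth, 1e-4)
    xm, xs_ = float(np.mean(y)), float(np.std(y) + 1e-6)

    def family_init(fam, level):
        if fam == "constant":
            return [np.log(level)]
        if fam == "linear":
            return [level, 0.0]
        if fam == "sigmoid":
            return [np.log(level / 2), np.log(level), xm, np.log(xs_)]
        return [np.log(level / 2), np.log(level), xm, np.log(xs_)]  # hump

    def family_unpack(fam, vec):
        if fam == "constant":
            return {"c": np.exp(vec[0])}, 1
        if fam == "linear":
            return {"a": vec[0], "b": vec[1]}, 2
        if fam == "sigmoid":
            return {"y0": np.exp(vec[0]), "y1": np.exp(vec[1]),
                    "xmid": vec[2], "r": np.exp(vec[3])}, 4
        return {"y0": np.exp(vec[0]), "y1": np.exp(vec[1]),
                "xmid": vec[2], "s": np.exp(vec[3])}, 4

    theta0 = family_init(lam_f, lam0) + family_init(mu_f, mu0) + [np.log(s2_0)]
    if drift == "ou":
        theta0 += [np.log(0.1), xm]

    def unpack(theta):
        lam_p, k1 = family_unpack(lam_f, theta)
        mu_p, k2 = family_unpack(mu_f, theta[k1:])
        s2 = np.exp(theta[k1 + k2])
        dr = None
        if drift == "ou":
            dr = (np.exp(theta[k1 + k2 + 1]), theta[k1 + k2 + 2])
        return QuasseModel(RateFn(lam_f, lam_p), RateFn(mu_f, mu_p), s2, dr)

    return np.array(theta0, dtype=float), unpack


def fit_quasse(tree: PhyloTree, tip_values: pd.Series, candidates=None,
               n_bins: int = 128, maxiter: int = 200, **loglik_kw) -> pd.DataFrame:
    """Fit candidate (lambda family, mu family, drift) combinations by ML and
    rank them by AIC.

    ``candidates`` defaults to all 4 x 4 x {bm, ou} combinations; pass a
    subset (e.g. ``[("constant", "constant", "bm")]``) to restrict.  Returns
    a ranked table with columns model, logL, k, AIC, dAIC and the fitted
    QuasseModel objects.
    """
    if tree.n_tips < 50:
        import warnings

        warnings.warn("QuaSSE fits are unreliable below ~50 tips")
    if candidates is None:
        candidates = [(l, m, d) for l in FAMILIES for m in FAMILIES
                      for d in ("bm", "ou")]
    y = tip_values.reindex(tree.tip_labels)
    rows = []
    for spec in candidates:
        theta0, unpack = _pack(spec, y.to_numpy(), tree)

        def nll(theta):
            try:
                model = unpack(theta)
                ll = quasse_loglik(tree, y, model, n_bins=n_bins, **loglik_kw)
            except (ValueError, FloatingPointError):
                return 1e10
            return 1e10 if not np.isfinite(ll) else -ll

        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3})
        model = unpack(res.x)
        ll = -float(res.fun)
        k = model.n_params
        rows.append({
            "model": ".".join([spec[2], spec[0], spec[1]]),
            "lambda_family": spec[0], "mu_family": spec[1], "drift": spec[2],
            "logL": ll, "k": k, "AIC": -2 * ll + 2 * k,
            "converged": bool(res.success) or ll > -1e9,
            "fit": model,
        })
    out = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    out["dAIC"] = out["AIC"] - out["AIC"].iloc[0]
    return out
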