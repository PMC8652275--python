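"""Stationary diffusions with a prescribed Gaussian steady state.

Any smooth volatility field ``sigma(x)`` and antisymmetric field ``Q(x)``
define a diffusion whose time-marginal is the target density
``p = N(mean, Pi^{-1})`` at every time:

    dx = (Gamma + Q)(x) grad log p(x) dt + div(Gamma + Q)(x) dt + sigma(x) dW,

with ``Gamma = sigma sigma^T / 2`` the diffusion tensor (dissipative
flow) and ``Q`` driving solenoidal, density-preserving circulation.  The
divergence of a matrix field is taken row-wise,
``(div M)_i = sum_j d/dx_j M_ij``; it vanishes for constant fields.

For constant fields the process is an Ornstein–Uhlenbeck process with
drift matrix ``B = -(Gamma + Q) Pi``; stationarity is then equivalent to
the Lyapunov identity ``B Sigma + Sigma B^T + sigma sigma^T = 0``, which
holds exactly by construction and is exposed as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import linalg

from .gaussian_world import StationaryDensity

__all__ = [
    "DiffusionModel",
    "TrajectoryEnsemble",
    "drift_field",
    "divergence_term",
    "simulate",
    "stationarity_residual",
    "ou_transition_moments",
]

MatrixField = Callable[[np.ndarray], np.ndarray]

#: Relative central-difference step for numeric divergences.
FD_STEP = 1e-5


@dataclass(frozen=True)
class DiffusionModel:
    """A diffusion of the form above, at steady state ``density``.

    ``sigma_field`` and ``q_field`` may be constant matrices (arrays) or
    callables of the state.  ``divergence_mode`` selects how the
    divergence correction is computed for state-dependent fields:
    ``"zero"`` (constant fields, exact), ``"analytic"`` (user-supplied
    ``divergence_fn``), or ``"finite_difference"``.
    """

    density: StationaryDensity
    sigma_field: np.ndarray | MatrixField = None  # type: ignore[assignment]
    q_field: np.ndarray | MatrixField = None  # type: ignore[assignment]
    divergence_mode: str = "zero"
    divergence_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        d = self.density.d
        sig = self.sigma_field
        if sig is None:
            sig = np.eye(d)
        q = self.q_field
        if q is None:
            q = np.zeros((d, d))
        if isinstance(sig, np.ndarray):
            sig = np.asarray(sig, dtype=float)
            if sig.ndim != 2 or sig.shape[0] != d:
                raise ValueError(f"sigma must have {d} rows")
        if isinstance(q, np.ndarray):
            q = np.asarray(q, dtype=float)
            if q.shape != (d, d):
                raise ValueError(f"Q must be {d}x{d}")
            if not np.allclose(q, -q.T, atol=1e-10 * max(1.0, np.abs(q).max())):
                raise ValueError("Q must be antisymmetric")
        object.__setattr__(self, "sigma_field", sig)
        object.__setattr__(self, "q_field", q)
        if self.divergence_mode not in ("zero", "analytic", "finite_difference"):
            raise ValueError(f"unknown divergence_mode {self.divergence_mode!r}")
        if self.divergence_mode == "analytic" and self.divergence_fn is None:
            raise ValueError("analytic divergence_mode requires divergence_fn")
        if self.divergence_mode == "zero" and not self.constant_fields:
            raise ValueError(
                "divergence_mode='zero' is only exact for constant fields; "
                "use 'analytic' or 'finite_difference'"
            )

    @property
    def constant_fields(self) -> bool:
        return isinstance(self.sigma_field, np.ndarray) and isinstance(
            self.q_field, np.ndarray
        )

    # -- field evaluation --------------------------------------------------
    def sigma_at(self, x: np.ndarray) -> np.ndarray:
        s = self.sigma_field
        out = s if isinstance(s, np.ndarray) else np.asarray(s(x), dtype=float)
        return out

    def q_at(self, x: np.ndarray) -> np.ndarray:
        q = self.q_field
        out = q if isinstance(q, np.ndarray) else np.asarray(q(x), dtype=float)
        if not np.allclose(out, -out.T, atol=1e-8 * max(1.0, np.abs(out).max())):
            raise ValueError("Q(x) is not antisymmetric at the probed state")
        return out

    def gamma_at(self, x: np.ndarray) -> np.ndarray:
        s = self.sigma_at(x)
        return s @ s.T / 2.0

    def flow_matrix_at(self, x: np.ndarray) -> np.ndarray:
        """Gamma(x) + Q(x)."""
        return self.gamma_at(x) + self.q_at(x)

    def drift_matrix(self) -> np.ndarray:
        """Constant-coefficient drift matrix ``B = -(Gamma + Q) Pi``."""
        if not self.constant_fields:
            raise ValueError("drift_matrix is defined for constant fields only")
        x0 = self.density.mean
        return -self.flow_matrix_at(x0) @ self.density.precision


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Simulated sample paths on a uniform time grid.

    ``paths`` has shape (n_paths, n_times, d); ``times[k] = k * dt``.
    """

    times: np.ndarray
    paths: np.ndarray
    dt: float
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.paths, dtype=float)
        if p.ndim != 3 or p.shape[1] != t.size:
            raise ValueError("paths must be (n_paths, n_times, d)")
        if t.size > 1 and not np.allclose(np.diff(t), self.dt, rtol=1e-9):
            raise ValueError("times must be uniformly spaced by dt")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "paths", p)

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]

    @property
    def d(self) -> int:
        return self.paths.shape[2]


# ---------------------------------------------------------------------------
# Drift and divergence
# ---------------------------------------------------------------------------

def divergence_term(model: DiffusionModel, x: np.ndarray) -> np.ndarray:
    """Row-wise divergence of the matrix field Gamma + Q at x.

    Exactly zero for constant fields; otherwise analytic (user-supplied)
    or central finite differences with step ``1e-5 * (1 + |x_j|)`` in
    coordinate j.
    """
    x = np.asarray(x, dtype=float).reshape(model.density.d)
    if model.constant_fields or model.divergence_mode == "zero":
        return np.zeros_like(x)
    if model.divergence_mode == "analytic":
        return np.asarray(model.divergence_fn(x), dtype=float).reshape(x.shape)
    d = x.size
    div = np.zeros(d)
    for j in range(d):
        h = FD_STEP * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        dM = (model.flow_matrix_at(xp) - model.flow_matrix_at(xm)) / (2.0 * h)
        div += dM[:, j]
    return div


def drift_field(model: DiffusionModel, x: np.ndarray) -> np.ndarray:
    """Full drift ``-(Gamma+Q)(x) Pi (x - mean) + div(Gamma+Q)(x)``."""
    x = np.asarray(x, dtype=float).reshape(model.density.d)
    grad_logp = -model.density.precision @ (x - model.density.mean)
    return model.flow_matrix_at(x) @ grad_logp + divergence_term(model, x)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _resolve_init(
    model: DiffusionModel, init, n_paths: int, rng: np.random.Generator
) -> np.ndarray:
    d = model.density.d
    if init is None or (isinstance(init, str) and init == "stationary"):
        L = np.linalg.cholesky(model.density.covariance)
        return model.density.mean + rng.standard_normal((n_paths, d)) @ L.T
    if callable(init):
        out = np.asarray(init(rng, n_paths), dtype=float)
        if out.shape != (n_paths, d):
            raise ValueError(f"init sampler must return ({n_paths}, {d})")
        return out
    x0 = np.asarray(init, dtype=float).reshape(d)
    return np.tile(x0, (n_paths, 1))


def simulate(
    model: DiffusionModel,
    init,
    dt: float,
    t_end: float,
    n_paths: int = 1,
    seed: int = 0,
    record_every: int = 1,
    method: str = "euler",
) -> TrajectoryEnsemble:
    """Integrate the diffusion with fixed-step Euler–Maruyama.

    ``init`` may be a state vector (shared by all paths), a callable
    ``(rng, n) -> (n, d)`` array, or ``"stationary"``/None to draw from
    the steady state.  Noise uses one substream per path derived from
    ``(seed, path_index)``, so results are independent of ``n_paths``
    batching.  ``method="rk4"`` gives a 4th-order deterministic
    integrator for noise-free (``sigma = 0``) conservative runs.
    ``record_every`` thins the stored grid (the integration step is
    always ``dt``).

    Raises ``FloatingPointError`` naming the step at which the state
    stopped being finite (blow-up detection).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < dt:
        raise ValueError("t_end must be at least dt")
    if n_paths <= 0:
        raise ValueError("n_paths must be positive")
    if method not in ("euler", "rk4"):
        raise ValueError(f"unknown method {method!r}")
    n_steps = int(round(t_end / dt))
    d = model.density.d

    init_rng = np.random.default_rng([seed, 0xA5EED])
    x = _resolve_init(model, init, n_paths, init_rng)
    rngs = [np.random.default_rng([seed, i]) for i in range(n_paths)]

    sigma_const = model.constant_fields
    if sigma_const:
        B = model.drift_matrix()
        sig = model.sigma_at(model.density.mean)
        noisy = np.abs(sig).max() > 0
    else:
        sig = None
        noisy = True

    n_rec = n_steps // record_every + 1
    out = np.empty((n_paths, n_rec, d))
    out[:, 0, :] = x
    times = np.arange(n_rec) * (dt * record_every)
    sqdt = np.sqrt(dt)
    mean = model.density.mean

    def check_finite(x_now: np.ndarray, k: int) -> None:
        if not np.all(np.isfinite(x_now)):
            bad = int(np.argwhere(~np.isfinite(x_now))[0][0])
            raise FloatingPointError(
                f"non-finite state in path {bad} at step {k} (t={k * dt:g})"
            )

    # overflow in a diverging path is reported via the finite check,
    # not as a numpy warning
    old_err = np.seterr(over="ignore", invalid="ignore")
    try:
        return _integrate(
            model, x, rngs, n_steps, dt, sqdt, record_every, method,
            sigma_const, noisy, B if sigma_const else None, sig, mean,
            out, times, seed, check_finite,
        )
    finally:
        np.seterr(**old_err)


def _integrate(model, x, rngs, n_steps, dt, sqdt, record_every, method,
               sigma_const, noisy, B, sig, mean, out, times, seed,
               check_finite):
    n_paths = x.shape[0]
    rec = 1
    if sigma_const:
        # noise drawn in chunks, one substream per path, order-independent
        chunk = 1024
        k = 0
        while k < n_steps:
            m = min(chunk, n_steps - k)
            if noisy:
                dW = np.empty((n_paths, m, sig.shape[1]))
                for i in range(n_paths):
                    dW[i] = rngs[i].standard_normal((m, sig.shape[1]))
                noise = sqdt * (dW @ sig.T)
            for j in range(m):
                k += 1
                if method == "rk4":
                    f = lambda y: (y - mean) @ B.T
                    k1 = f(x)
                    k2 = f(x + 0.5 * dt * k1)
                    k3 = f(x + 0.5 * dt * k2)
                    k4 = f(x + dt * k3)
                    x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                else:
                    x = x + dt * ((x - mean) @ B.T)
                if noisy:
                    x = x + noise[:, j]
                if k % record_every == 0:
                    check_finite(x, k)
                    out[:, rec, :] = x
                    rec += 1
    else:
        Pi = model.density.precision
        for k in range(1, n_steps + 1):
            for i in range(n_paths):
                xi = x[i]
                s = model.sigma_at(xi)
                gq = s @ s.T / 2.0 + model.q_at(xi)
                step = dt * (-gq @ (Pi @ (xi - mean)) + divergence_term(model, xi))
                step += sqdt * (s @ rngs[i].standard_normal(s.shape[1]))
                x[i] = xi + step
            if k % record_every == 0:
                check_finite(x, k)
                out[:, rec, :] = x
                rec += 1
    return TrajectoryEnsemble(times, out[:, :rec, :], dt * record_every, seed)


# ---------------------------------------------------------------------------
# Stationarity diagnostics and OU closed forms
# ---------------------------------------------------------------------------

def stationarity_residual(model: DiffusionModel) -> np.ndarray:
    """Lyapunov residual ``B Sigma + Sigma B^T + sigma sigma^T`` for a
    constant-coefficient model; identically zero when the drift has the
    dissipative-plus-solenoidal form."""
    if not model.constant_fields:
        raise ValueError("stationarity_residual requires constant fields")
    B = model.drift_matrix()
    Sigma = model.density.covariance
    sig = model.sigma_at(model.density.mean)
    return B @ Sigma + Sigma @ B.T + sig @ sig.T


def ou_transition_moments(
    model: DiffusionModel, x0: np.ndarray, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact transition moments of the constant-coefficient (OU) case:
    ``mean = mean_inf + e^{Bt}(x0 - mean_inf)`` and
    ``cov = Sigma - e^{Bt} Sigma e^{B^T t}``."""
    if not model.constant_fields:
        raise ValueError("transition moments require constant fields")
    if t < 0:
        raise ValueError("t must be nonnegative")
    x0 = np.asarray(x0, dtype=float).reshape(model.density.d)
    B = model.drift_matrix()
    E = linalg.expm(B * t)
    Sigma = model.density.covariance
    mean = model.density.mean + E @ (x0 - model.density.mean)
    cov = Sigma - E @ Sigma @ E.T
    return mean, (cov + cov.T) / 2.0
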