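"""Linear stochastic realization: integrator chains and PID-like gains.

A stationary Gaussian process with exponentially decaying autocovariance
is an Ornstein–Uhlenbeck process (Doob's characterization), so a
sensory signal with a finite sum of exponentially decaying
autocovariance components can be written as a linear output of a nested
chain of OU processes — an integrator chain encoding the signal's
orders of motion (integral, position, velocity, ...):

    ds(i) = (A_i s(i) + B_i s(i+1)) dt + sigma_i dW(i),   i < n
    ds(n) = A_n s(n) dt + sigma_n dW(n),
    s_t   = sum_i F_i s(i)_t.

Replacing the sensory coordinate of the quadratic control objective by
this output turns the stationary gain matrix K into per-order feedback
gains: the closed-form minimizer over (a, mu) is linear in each s(i),
and for a three-level chain (n = 2) the coefficients are integral,
proportional and derivative gains.  The gains here are defined as
exactly those per-order coefficients (validated against a numeric
argmin); no other extraction rule is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .control import ControlSpec, optimal_autonomous

__all__ = [
    "IntegratorChain",
    "AutocovarianceTable",
    "build_chain",
    "chain_autocovariance",
    "extended_control_objective",
    "pid_gains",
    "simulate_chain",
]

PID_LABELS = ("integral", "proportional", "derivative")


@dataclass(frozen=True)
class IntegratorChain:
    """A stacked linear diffusion on the extended state
    ``s~ = (s(0), ..., s(n))``.

    ``level_drifts`` holds per-level pairs (A_i, B_i): A_i is the self
    drift of level i and B_i couples it to level i+1 (B_n is None).
    ``level_volatilities`` are the sigma_i.  ``output_map`` is the list
    of F_i with ``s = sum_i F_i s(i)``.

    Derived: the stacked drift ``drift`` (block upper-bidiagonal, stable),
    stacked volatility ``volatility`` (block diagonal) and the stationary
    covariance ``stationary_cov`` solving the continuous Lyapunov
    equation ``A Sigma + Sigma A^T + sigma sigma^T = 0``.
    """

    order: int
    level_dims: tuple[int, ...]
    level_drifts: tuple
    level_volatilities: tuple
    output_map: tuple
    drift: np.ndarray = field(init=False, default=None)  # type: ignore[assignment]
    volatility: np.ndarray = field(init=False, default=None)  # type: ignore[assignment]
    stationary_cov: np.ndarray = field(init=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.order
        dims = self.level_dims
        if len(dims) != n + 1:
            raise ValueError("need one dimension per level 0..n")
        offsets = np.concatenate([[0], np.cumsum(dims)])
        D = int(offsets[-1])
        A = np.zeros((D, D))
        for i, (A_i, B_i) in enumerate(self.level_drifts):
            r = slice(offsets[i], offsets[i + 1])
            A[r, r] = np.asarray(A_i, dtype=float).reshape(dims[i], dims[i])
            if i < n:
                c = slice(offsets[i + 1], offsets[i + 2])
                if B_i is None:
                    raise ValueError(f"level {i} < n must couple to level {i + 1}")
                A[r, c] = np.asarray(B_i, dtype=float).reshape(dims[i], dims[i + 1])
            elif B_i is not None:
                raise ValueError("top level has no upward coupling")
        vol_blocks = [
            np.atleast_2d(np.asarray(v, dtype=float)) for v in self.level_volatilities
        ]
        S = linalg.block_diag(*vol_blocks)
        eigs = np.linalg.eigvals(A)
        if eigs.real.max() >= 0:
            raise ValueError(
                f"stacked drift is not stable; eigenvalue real parts "
                f"{np.sort(eigs.real)[::-1][:3]}"
            )
        Sigma = linalg.solve_continuous_lyapunov(A, -S @ S.T)
        Sigma = (Sigma + Sigma.T) / 2.0
        object.__setattr__(self, "drift", A)
        object.__setattr__(self, "volatility", S)
        object.__setattr__(self, "stationary_cov", Sigma)
        Fs = tuple(np.atleast_2d(np.asarray(F, dtype=float)) for F in self.output_map)
        if len(Fs) != n + 1:
            raise ValueError("output_map needs one F_i per level")
        object.__setattr__(self, "output_map", Fs)

    @property
    def d_extended(self) -> int:
        return self.drift.shape[0]

    @property
    def d_out(self) -> int:
        return self.output_map[0].shape[0]

    def level_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.level_dims)])

    def output_matrix(self) -> np.ndarray:
        """The full row block [F_0 ... F_n] so that s = F s~."""
        return np.concatenate(self.output_map, axis=1)

    def output(self, s_tilde: np.ndarray) -> np.ndarray:
        return self.output_matrix() @ np.atleast_1d(np.asarray(s_tilde, dtype=float))


@dataclass(frozen=True)
class AutocovarianceTable:
    """Output-process autocovariance C(tau) on a lag grid.

    ``values[k]`` is the (d_out, d_out) matrix at ``lags[k]``; negative
    lags follow from ``C(-tau) = C(tau)^T``.
    """

    lags: np.ndarray
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if np.any(lags < 0):
            raise ValueError("lags must be nonnegative; use C(-tau) = C(tau)^T")
        if vals.shape[0] != lags.size:
            raise ValueError("one matrix per lag required")
        if self.source not in ("analytic", "empirical"):
            raise ValueError("source must be 'analytic' or 'empirical'")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", vals)


def build_chain(order: int, spec: dict) -> IntegratorChain:
    """Build an integrator chain from a coefficient spec.

    ``spec`` keys: ``dims`` (per-level dimensions, default all 1),
    ``self_drifts`` (A_i), ``couplings`` (B_i for i < n),
    ``volatilities`` (sigma_i) and optional ``output_map`` (F_i; default
    selects level min(1, n), the proportional output).
    Rejects unstable stacked drifts with an eigenvalue report.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    dims = tuple(int(v) for v in spec.get("dims", [1] * (order + 1)))
    self_drifts = spec["self_drifts"]
    couplings = list(spec.get("couplings", []))
    if len(couplings) != order:
        raise ValueError(f"need {order} couplings for order {order}")
    vols = spec["volatilities"]
    drifts = tuple(
        (self_drifts[i], couplings[i] if i < order else None)
        for i in range(order + 1)
    )
    out = spec.get("output_map")
    if out is None:
        sel = min(1, order)
        out = [
            np.eye(dims[sel])[:, :] if i == sel else np.zeros((dims[sel], dims[i]))
            for i in range(order + 1)
        ]
    return IntegratorChain(order, dims, drifts, tuple(vols), tuple(out))


def simulate_chain(
    chain: IntegratorChain,
    dt: float,
    n_steps: int,
    seed: int = 0,
    init: np.ndarray | None = None,
    method: str = "exact",
) -> np.ndarray:
    """Sample path of the extended state, (n_steps + 1, D).

    The stacked system is linear, so ``method="exact"`` (default) uses
    the exact Gaussian transition ``x' = e^{A dt} x + w`` with
    ``cov(w) = Sigma~ - e^{A dt} Sigma~ e^{A^T dt}`` — no discretization
    bias.  ``method="euler"`` is fixed-step Euler–Maruyama.  Initialized
    from the stationary density when ``init`` is None.
    """
    if dt <= 0 or n_steps < 1:
        raise ValueError("dt must be > 0 and n_steps >= 1")
    if method not in ("exact", "euler"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng([seed, 0xC4A1])
    D = chain.d_extended
    if init is None:
        L = np.linalg.cholesky(chain.stationary_cov)
        x = L @ rng.standard_normal(D)
    else:
        x = np.asarray(init, dtype=float).reshape(D).copy()
    A, S = chain.drift, chain.volatility
    out = np.empty((n_steps + 1, D))
    out[0] = x
    if method == "exact":
        E = linalg.expm(A * dt)
        W = chain.stationary_cov - E @ chain.stationary_cov @ E.T
        Lw = np.linalg.cholesky((W + W.T) / 2.0 + 1e-15 * np.eye(D))
        noise = rng.standard_normal((n_steps, D)) @ Lw.T
        for k in range(n_steps):
            x = E @ x + noise[k]
            out[k + 1] = x
    else:
        m = S.shape[1]
        noise = rng.standard_normal((n_steps, m)) @ S.T * np.sqrt(dt)
        for k in range(n_steps):
            x = x + dt * (A @ x) + noise[k]
            out[k + 1] = x
    return out


def chain_autocovariance(
    chain: IntegratorChain,
    lags: np.ndarray,
    mode: str = "analytic",
    dt: float = 1e-2,
    n_steps: int = 100_000,
    seed: int = 0,
) -> AutocovarianceTable:
    """Autocovariance of the output process s_t = F s~_t.

    Analytic: ``C(tau) = F e^{A tau} Sigma~ F^T`` (tau >= 0).  Empirical:
    lagged time averages over a single stationary path of ``n_steps``
    Euler steps; requested lags are rounded to the step grid.
    """
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    if np.any(lags < 0):
        raise ValueError("lags must be nonnegative; C(-tau) = C(tau)^T")
    F = chain.output_matrix()
    if mode == "analytic":
        vals = np.stack(
            [F @ linalg.expm(chain.drift * t) @ chain.stationary_cov @ F.T for t in lags]
        )
        return AutocovarianceTable(lags, vals, "analytic")
    if mode != "empirical":
        raise ValueError("mode must be 'analytic' or 'empirical'")
    path = simulate_chain(chain, dt, n_steps, seed)
    s = path @ F.T  # (n_steps + 1, d_out)
    vals = []
    grid_lags = []
    for t in lags:
        k = int(round(t / dt))
        if k >= s.shape[0]:
            raise ValueError(f"lag {t} exceeds the simulated span")
        a, b = s[: s.shape[0] - k], s[k:]
        vals.append(b.T @ a / a.shape[0])
        grid_lags.append(k * dt)
    return AutocovarianceTable(np.asarray(grid_lags), np.stack(vals), "empirical")


def extended_control_objective(
    spec: ControlSpec,
    chain: IntegratorChain,
    s_tilde: np.ndarray,
    a: np.ndarray,
    mu: np.ndarray,
) -> float:
    """The extended-state cost ``[f(s~), a, mu] K [f(s~), a, mu]^T``."""
    from .control import control_objective

    s = chain.output(s_tilde)
    if s.size != spec.partition.d_s:
        raise ValueError(
            f"chain output dimension {s.size} does not match d_s="
            f"{spec.partition.d_s}"
        )
    return control_objective(spec, s, a, mu)


def pid_gains(spec: ControlSpec, chain: IntegratorChain) -> list[dict]:
    """Per-order feedback gains of the extended-objective minimizer.

    The minimizer over (a, mu) at fixed s~ is
    ``z*(s~) = -(K_zz)^{-1} K_zs sum_i F_i s(i)``; restricting to the
    active rows and collecting per-level coefficients gives
    ``a*(s~) = -sum_i L_i s(i)`` with ``L_i = [ (K_zz)^{-1} K_zs F_i ]_a``.
    For n = 2 the three levels are labelled integral, proportional and
    derivative.  Returns dicts with keys level, label, gain.
    """
    p = spec.partition
    if p.d_a < 1:
        raise ValueError("pid gains need d_a >= 1")
    K = spec.gain
    K_zz = K[spec.sl_au, spec.sl_au]
    K_zs = K[spec.sl_au, spec.sl_s]
    M = linalg.solve(K_zz, K_zs, assume_a="pos")[: p.d_a]  # a-rows of K_zz^{-1} K_zs
    gains = []
    for i, F_i in enumerate(chain.output_map):
        if chain.order == 2 and i < len(PID_LABELS):
            label = PID_LABELS[i]
        else:
            label = f"order_{i}"
        gains.append({"level": i, "label": label, "gain": M @ F_i})
    return gains


def reconstruct_action(gains: list[dict], chain: IntegratorChain, s_tilde: np.ndarray) -> np.ndarray:
    """Evaluate ``a*(s~) = -sum_i L_i s(i)`` from extracted gains."""
    s_tilde = np.atleast_1d(np.asarray(s_tilde, dtype=float))
    off = chain.level_offsets()
    a = None
    for g in gains:
        i = g["level"]
        part = s_tilde[off[i] : off[i + 1]]
        term = -np.atleast_2d(g["gain"]) @ part
        a = term if a is None else a + term
    return a
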