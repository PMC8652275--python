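"""Active states as stochastic controllers.

Splitting the blanket into sensory and active coordinates, b = (s, a),
the expected active state given sensation is the conditional mean
``a(s) = Sigma_{a,s} Sigma_s^{-1} s``, and the expected autonomous
states (a, mu) jointly minimize the quadratic control objective

    (a, mu)  ->  [s, a, mu] K [s, a, mu]^T,      K = Sigma_{b:mu}^{-1},

i.e. the precision matrix of the particular-state marginal acts as a
gain matrix penalizing departures of (s, a, mu) from the set-point (the
steady-state mean).  Minimizing the quadratic form over (a, mu) at fixed
s is the same linear feedback as Gaussian conditioning, which is what
licenses reading stationarity as homeostatic control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .diffusion import DiffusionModel, simulate
from .gaussian_world import BlanketPartition, StationaryDensity
from .inference import _batch_free_energy, _internal_states
from .sync_map import build_sync_map

__all__ = [
    "ControlSpec",
    "expected_action",
    "control_gain_matrix",
    "control_objective",
    "optimal_autonomous",
    "active_relaxation_experiment",
]


@dataclass(frozen=True)
class ControlSpec:
    """Gain matrix ``K = Sigma_{b:mu}^{-1}`` over (s, a, mu) coordinates,
    with the partition it refers to."""

    gain: np.ndarray
    partition: BlanketPartition

    def __post_init__(self) -> None:
        K = np.asarray(self.gain, dtype=float)
        n = self.partition.d_b + self.partition.d_mu
        if K.shape != (n, n):
            raise ValueError(f"gain must be {n}x{n}")
        if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
            raise ValueError("gain must be symmetric")
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("gain must be positive-definite")
        object.__setattr__(self, "gain", (K + K.T) / 2.0)

    # index ranges within the (s, a, mu) ordering of K
    @property
    def sl_s(self) -> slice:
        return slice(0, self.partition.d_s)

    @property
    def sl_a(self) -> slice:
        p = self.partition
        return slice(p.d_s, p.d_s + p.d_a)

    @property
    def sl_mu(self) -> slice:
        p = self.partition
        return slice(p.d_s + p.d_a, p.d_s + p.d_a + p.d_mu)

    @property
    def sl_au(self) -> slice:
        """Autonomous block (a, mu)."""
        p = self.partition
        return slice(p.d_s, p.d_s + p.d_a + p.d_mu)


def expected_action(density: StationaryDensity, s: np.ndarray) -> np.ndarray:
    """Expected active state given sensation:
    ``a(s) = Sigma_{a,s} Sigma_s^{-1} s`` (centered coordinates)."""
    part = density.partition
    if part.d_a < 1 or part.d_s < 1:
        raise ValueError("expected_action needs d_a >= 1 and d_s >= 1")
    s = np.atleast_1d(np.asarray(s, dtype=float)).reshape(part.d_s)
    sc = s - density.mean_of("s")
    w = linalg.solve(density.S("s"), sc, assume_a="pos")
    return density.mean_of("a") + density.S("a", "s") @ w


def control_gain_matrix(density: StationaryDensity) -> ControlSpec:
    """K = Sigma_{b:mu}^{-1}, the particular-state precision."""
    S = density.S("b:mu")
    try:
        K = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"particular-state covariance is singular: {exc}"
        ) from exc
    return ControlSpec((K + K.T) / 2.0, density.partition)


def control_objective(
    spec: ControlSpec, s: np.ndarray, a: np.ndarray, mu: np.ndarray
) -> float:
    """The quadratic cost ``[s, a, mu] K [s, a, mu]^T`` (nonnegative)."""
    p = spec.partition
    z = np.concatenate(
        [
            np.atleast_1d(np.asarray(s, dtype=float)).reshape(p.d_s),
            np.atleast_1d(np.asarray(a, dtype=float)).reshape(p.d_a)
            if p.d_a
            else np.empty(0),
            np.atleast_1d(np.asarray(mu, dtype=float)).reshape(p.d_mu),
        ]
    )
    return float(z @ spec.gain @ z)


def optimal_autonomous(
    spec: ControlSpec, s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form minimizer of the control objective over (a, mu) at
    fixed s: the block solve ``-(K_zz)^{-1} K_zs s`` with z = (a, mu).
    Equals the Gaussian conditional mean E[(a, mu) | s]."""
    p = spec.partition
    if p.d_a < 1:
        raise ValueError("optimal_autonomous needs d_a >= 1")
    s = np.atleast_1d(np.asarray(s, dtype=float)).reshape(p.d_s)
    K = spec.gain
    K_zz = K[spec.sl_au, spec.sl_au]
    K_zs = K[spec.sl_au, spec.sl_s]
    z = linalg.solve(K_zz, -K_zs @ s, assume_a="pos")
    return z[: p.d_a], z[p.d_a :]


# ---------------------------------------------------------------------------
# Active relaxation (perturb the senses, watch the actions)
# ---------------------------------------------------------------------------

def _sample_conditional_on_sensory(
    density: StationaryDensity, s0: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from p(x | s = s0) by generic Gaussian conditioning of
    (eta, a, mu) on the sensory block."""
    part = density.partition
    sl = part.slices()
    d = part.d
    s_idx = np.arange(sl["s"].start, sl["s"].stop)
    rest_idx = np.setdiff1d(np.arange(d), s_idx)
    s0 = np.atleast_1d(np.asarray(s0, dtype=float)).reshape(part.d_s)
    Sigma = density.covariance
    S_ss = Sigma[np.ix_(s_idx, s_idx)]
    S_rs = Sigma[np.ix_(rest_idx, s_idx)]
    S_rr = Sigma[np.ix_(rest_idx, rest_idx)]
    W = linalg.solve(S_ss, S_rs.T, assume_a="pos")
    mean_rest = density.mean[rest_idx] + W.T @ (s0 - density.mean[s_idx])
    cov_rest = S_rr - S_rs @ W
    L = np.linalg.cholesky((cov_rest + cov_rest.T) / 2.0)
    rest = mean_rest + rng.standard_normal((n, rest_idx.size)) @ L.T
    X = np.empty((n, d))
    X[:, s_idx] = s0
    X[:, rest_idx] = rest
    return X


def active_relaxation_experiment(
    model: DiffusionModel,
    s0: np.ndarray,
    n_paths: int = 500,
    dt: float = 0.01,
    t_end: float = 10.0,
    seed: int = 0,
    record_every: int = 10,
) -> pd.DataFrame:
    """Active-inference protocol: initialize from p(x0 | s0), integrate,
    and compare realized active states with the optimal action a(s_t).

    Per-time columns: ensemble means of s and a, the mean optimal action,
    mean distance ``||a_t - a(s_t)||``, and the free energy of the
    expected internal state.  Also keeps the first sample path's s and a
    coordinates for trajectory-level inspection.
    """
    if not model.constant_fields:
        raise ValueError("active relaxation expects a constant-coefficient model")
    density = model.density
    part = density.partition
    if part.d_a < 1:
        raise ValueError("active relaxation needs d_a >= 1")
    sync = build_sync_map(density)
    rng = np.random.default_rng([seed, 0x5EA])

    def init(rng_unused, n):
        return _sample_conditional_on_sensory(density, s0, n, rng)

    ens = simulate(
        model, init, dt, t_end, n_paths=n_paths, seed=seed, record_every=record_every
    )
    sl = part.slices()
    W_as = linalg.solve(density.S("s"), density.S("s", "a"), assume_a="pos")
    rows = []
    for k, t in enumerate(ens.times):
        X = ens.paths[:, k, :]
        S = X[:, sl["s"]]
        A = X[:, sl["a"]]
        A_opt = density.mean_of("a") + (S - density.mean_of("s")) @ W_as
        dist = np.linalg.norm(A - A_opt, axis=1)
        mu_used = _internal_states(X, density, "expected")
        F = _batch_free_energy(X, density, sync, mu_used)
        row = {
            "time": float(t),
            "mean_dist_a": float(dist.mean()),
            "se_dist_a": float(dist.std(ddof=1) / np.sqrt(n_paths)),
            "mean_F_expected": float(F.mean()),
            "se_F_expected": float(F.std(ddof=1) / np.sqrt(n_paths)),
        }
        for i in range(part.d_s):
            row[f"mean_s_{i}"] = float(S[:, i].mean())
            row[f"path0_s_{i}"] = float(S[0, i])
        for i in range(part.d_a):
            row[f"mean_a_{i}"] = float(A[:, i].mean())
            row[f"mean_a_opt_{i}"] = float(A_opt[:, i].mean())
            row[f"path0_a_{i}"] = float(A[0, i])
        rows.append(row)
    return pd.DataFrame(rows)
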