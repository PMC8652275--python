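"""Variational inference quantities across a Markov blanket.

Each internal state mu encodes a Gaussian belief about external states,

    q_mu(eta) = N(eta; sigma(mu), Pi_eta^{-1}),

whose mean is the synchronization-map prediction and whose precision is
that of the true posterior p(eta|b).  The variational free energy of a
particular state (b, mu),

    F(b, mu) = KL[q_mu || p(eta|b)] - log p(b, mu)
             = E_q[-log p(x)] - H[q_mu],

carries full normalization constants, so both decompositions are exact
identities.  Because the belief covariance is fixed, the KL term reduces
to half a precision-weighted squared prediction error,
``0.5 (sigma(mu) - eta(b))^T Pi_eta (sigma(mu) - eta(b))``, and the
unique free-energy minimizer over mu is the expected internal state
mu(b) — inference and prediction-error minimization coincide.

The relaxation experiment reproduces the perturbation protocol used to
illustrate self-organization: initialize an ensemble from the steady
state conditioned on an improbable blanket state, integrate the
diffusion, and track mean free energy and prediction-error statistics as
the ensemble relaxes back to stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .diffusion import DiffusionModel, simulate
from .gaussian_world import (
    StationaryDensity,
    conditional_given_blanket,
)
from .sync_map import SyncMap, build_sync_map

__all__ = [
    "Belief",
    "FreeEnergyBreakdown",
    "belief_of",
    "kl_to_posterior",
    "free_energy",
    "minimize_free_energy",
    "prediction_error",
    "stationary_free_energy",
    "relaxation_experiment",
]

LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Belief:
    """Gaussian belief over external states held by an internal state:
    mean ``sigma(mu)``, precision ``Pi_eta`` (the true posterior's)."""

    mean: np.ndarray
    precision: np.ndarray


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """F(b, mu) and its two exact decompositions (all in nats).

    ``total = kl + neg_log_joint_particular`` and
    ``total = energy - entropy`` hold to machine tolerance.
    """

    total: float
    kl: float
    neg_log_joint_particular: float
    energy: float
    entropy: float


def belief_of(
    mu: np.ndarray, sync: SyncMap, density: StationaryDensity
) -> Belief:
    """The belief q_mu(eta) = N(sigma(mu), Pi_eta^{-1})."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if mu.size != density.partition.d_mu:
        raise ValueError(
            f"mu has dimension {mu.size}, expected {density.partition.d_mu}"
        )
    mu_c = mu - density.mean_of("mu")
    return Belief(density.mean_of("eta") + sync.matrix @ mu_c, density.P("eta"))


def kl_to_posterior(
    mu: np.ndarray,
    b: np.ndarray,
    density: StationaryDensity,
    sync: SyncMap,
) -> float:
    """KL[q_mu(eta) || p(eta|b)] for equal-covariance Gaussians:
    ``0.5 (sigma(mu) - eta(b))^T Pi_eta (sigma(mu) - eta(b))``;
    zero iff the prediction matches the expected external state."""
    cond_eta, _ = conditional_given_blanket(density, b)
    delta = belief_of(mu, sync, density).mean - cond_eta.mean
    return float(0.5 * delta @ density.P("eta") @ delta)


def _neg_log_gaussian(x_c: np.ndarray, precision: np.ndarray) -> float:
    """-log N(x; 0, precision^{-1}) with full constants."""
    d = x_c.size
    sign, logdet_prec = np.linalg.slogdet(precision)
    if sign <= 0:
        raise np.linalg.LinAlgError("precision must be positive-definite")
    return float(0.5 * (x_c @ precision @ x_c + d * LOG_2PI - logdet_prec))


def free_energy(
    b: np.ndarray,
    mu: np.ndarray,
    density: StationaryDensity,
    sync: SyncMap,
) -> FreeEnergyBreakdown:
    """F(b, mu) with both exact decompositions.

    KL + (-log p(b, mu)) is the evidence-bound form; energy - entropy is
    the thermodynamic form, with
    ``energy = E_q[-log p(x)]`` (expected under the belief over eta, with
    b and mu fixed) and ``entropy = H[q_mu]``.
    """
    part = density.partition
    b = np.atleast_1d(np.asarray(b, dtype=float)).reshape(part.d_b)
    mu = np.atleast_1d(np.asarray(mu, dtype=float)).reshape(part.d_mu)

    kl = kl_to_posterior(mu, b, density, sync)

    # -log p(b, mu): marginal of the (b, mu) coordinates
    S_bm = density.S("b:mu")
    K_bm = np.linalg.inv(S_bm)
    z = np.concatenate([b, mu]) - density.mean[part.slices()["b:mu"]]
    neg_log_joint = _neg_log_gaussian(z, (K_bm + K_bm.T) / 2.0)

    # energy: E_q[-log p(x)] with eta ~ q_mu, (b, mu) clamped
    belief = belief_of(mu, sync, density)
    xbar = np.concatenate([belief.mean, b, mu]) - density.mean
    Pi = density.precision
    trace_term = density.partition.d_eta  # tr(Pi_eta Pi_eta^{-1})
    sign, logdet_Pi = np.linalg.slogdet(Pi)
    energy = float(
        0.5 * (xbar @ Pi @ xbar + trace_term + part.d * LOG_2PI - logdet_Pi)
    )

    # entropy of q_mu
    sign_e, logdet_Pe = np.linalg.slogdet(density.P("eta"))
    entropy = float(0.5 * (part.d_eta * (1.0 + LOG_2PI) - logdet_Pe))

    total = kl + neg_log_joint
    return FreeEnergyBreakdown(total, kl, neg_log_joint, energy, entropy)


def minimize_free_energy(
    b: np.ndarray,
    density: StationaryDensity,
    sync: SyncMap,
    solver_tol: float = 1e-8,
) -> np.ndarray:
    """Minimizer of mu -> F(b, mu), by the closed-form convex quadratic
    solve.  F is quadratic in mu with Hessian
    ``sigma^T Pi_eta sigma + K_mu`` (K the (b,mu)-marginal precision),
    so the stationary point is the global minimum; it coincides with the
    expected internal state mu(b).  Raises if the residual gradient
    exceeds ``solver_tol``."""
    part = density.partition
    b = np.atleast_1d(np.asarray(b, dtype=float)).reshape(part.d_b)
    bc = b - density.mean_of("b")
    Pe = density.P("eta")
    Sm = sync.matrix
    K = np.linalg.inv(density.S("b:mu"))
    K = (K + K.T) / 2.0
    db = part.d_b
    K_mb, K_m = K[db:, :db], K[db:, db:]
    cond_eta, _ = conditional_given_blanket(density, b)
    eta_c = cond_eta.mean - density.mean_of("eta")
    H = Sm.T @ Pe @ Sm + K_m
    rhs = Sm.T @ Pe @ eta_c - K_mb @ bc
    mu_c = linalg.solve(H, rhs, assume_a="pos")
    grad = H @ mu_c - rhs
    if np.abs(grad).max() > solver_tol * max(1.0, np.abs(rhs).max()):
        raise RuntimeError("free-energy minimization did not converge")
    return density.mean_of("mu") + mu_c


def prediction_error(
    eta: np.ndarray,
    mu: np.ndarray,
    density: StationaryDensity,
    sync: SyncMap,
) -> np.ndarray:
    """Precision-weighted prediction error ``xi = Pi_eta (eta - sigma(mu))``.

    The caller chooses whether eta is a realized external sample or an
    expected state, and likewise for mu; with realized eta and
    mu = mu(b) at steady state, xi is N(0, Pi_eta)-distributed.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    pred = belief_of(mu, sync, density).mean
    return density.P("eta") @ (eta - pred)


# ---------------------------------------------------------------------------
# Relaxation experiment (perturb-and-relax protocol)
# ---------------------------------------------------------------------------

def _batch_free_energy(
    X: np.ndarray, density: StationaryDensity, sync: SyncMap, mu_used: np.ndarray
) -> np.ndarray:
    """Vectorized F(b_i, mu_i) over rows; mu_used is (n, d_mu)."""
    part = density.partition
    sl = part.slices()
    B = X[:, sl["b"]] - density.mean_of("b")
    MU = mu_used - density.mean_of("mu")

    Pe = density.P("eta")
    W = linalg.solve(density.S("b"), density.S("b", "eta"), assume_a="pos")
    ETA_B = B @ W  # eta(b), centered
    PRED = MU @ sync.matrix.T
    D = PRED - ETA_B
    kl = 0.5 * np.einsum("ni,ij,nj->n", D, Pe, D)

    K = np.linalg.inv(density.S("b:mu"))
    K = (K + K.T) / 2.0
    Z = np.concatenate([B, MU], axis=1)
    sign, logdet_K = np.linalg.slogdet(K)
    dbm = part.d_b + part.d_mu
    neg_log_joint = 0.5 * (
        np.einsum("ni,ij,nj->n", Z, K, Z) + dbm * LOG_2PI - logdet_K
    )
    return kl + neg_log_joint


def stationary_free_energy(
    density: StationaryDensity,
    sync: SyncMap,
    n: int = 100_000,
    seed: int = 0,
    internal_mode: str = "expected",
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of E_p[F(b, mu)] at
    steady state, with mu either realized or replaced by mu(b)."""
    from .gaussian_world import sample_stationary

    X = sample_stationary(density, n, seed)
    mu_used = _internal_states(X, density, internal_mode)
    F = _batch_free_energy(X, density, sync, mu_used)
    return float(F.mean()), float(F.std(ddof=1) / np.sqrt(n))


def _internal_states(
    X: np.ndarray, density: StationaryDensity, internal_mode: str
) -> np.ndarray:
    sl = density.partition.slices()
    if internal_mode == "realized":
        return X[:, sl["mu"]]
    if internal_mode == "expected":
        B = X[:, sl["b"]] - density.mean_of("b")
        W = linalg.solve(density.S("b"), density.S("b", "mu"), assume_a="pos")
        return density.mean_of("mu") + B @ W
    raise ValueError(f"unknown internal_mode {internal_mode!r}")


def sample_conditional_on_blanket(
    density: StationaryDensity, b0: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n states from p(x | b = b0): blanket clamped, eta and mu drawn
    independently from their conditionals (legal under the blanket)."""
    part = density.partition
    b0 = np.atleast_1d(np.asarray(b0, dtype=float)).reshape(part.d_b)
    cond_eta, cond_mu = conditional_given_blanket(density, b0)
    Le = np.linalg.cholesky(cond_eta.covariance)
    Lm = np.linalg.cholesky(cond_mu.covariance)
    eta = cond_eta.mean + rng.standard_normal((n, part.d_eta)) @ Le.T
    mu = cond_mu.mean + rng.standard_normal((n, part.d_mu)) @ Lm.T
    X = np.empty((n, part.d))
    sl = part.slices()
    X[:, sl["eta"]] = eta
    X[:, sl["b"]] = b0
    X[:, sl["mu"]] = mu
    return X


def relaxation_experiment(
    model: DiffusionModel,
    b0: np.ndarray,
    n_paths: int = 500,
    dt: float = 0.01,
    t_end: float = 10.0,
    seed: int = 0,
    internal_mode: str = "expected",
    record_every: int = 10,
) -> pd.DataFrame:
    """Perturb-and-relax protocol: initialize from p(x0 | b0), integrate,
    and track the ensemble mean free energy and prediction errors.

    ``internal_mode="expected"`` evaluates F(b_t, mu(b_t)) (event-average
    protocol); ``"realized"`` uses the simulated internal coordinates.
    Prediction errors use realized eta against sigma of the chosen
    internal state.  Returns a tidy per-time table with columns
    time, mean_F, se_F, mean_xi_<i>, and xi second moments.
    """
    if not model.constant_fields:
        raise ValueError("relaxation experiment expects a constant-coefficient model")
    density = model.density
    part = density.partition
    sync = build_sync_map(density)
    rng = np.random.default_rng([seed, 0x1217])

    def init(rng_unused, n):
        return sample_conditional_on_blanket(density, b0, n, rng)

    ens = simulate(
        model, init, dt, t_end, n_paths=n_paths, seed=seed, record_every=record_every
    )
    sl = part.slices()
    rows = []
    Pe = density.P("eta")
    for k, t in enumerate(ens.times):
        X = ens.paths[:, k, :]
        mu_used = _internal_states(X, density, internal_mode)
        F = _batch_free_energy(X, density, sync, mu_used)
        PRED = density.mean_of("eta") + (mu_used - density.mean_of("mu")) @ sync.matrix.T
        XI = (X[:, sl["eta"]] - PRED) @ Pe.T
        row = {
            "time": float(t),
            "mean_F": float(F.mean()),
            "se_F": float(F.std(ddof=1) / np.sqrt(n_paths)),
        }
        for i in range(part.d_eta):
            row[f"mean_xi_{i}"] = float(XI[:, i].mean())
        cov = XI.T @ XI / n_paths
        for i in range(part.d_eta):
            for j in range(i, part.d_eta):
                row[f"xi2_{i}{j}"] = float(cov[i, j])
        rows.append(row)
    return pd.DataFrame(rows)
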