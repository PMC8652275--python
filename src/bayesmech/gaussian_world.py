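"""Partitioned Gaussian steady states with Markov-blanket structure.

The world state ``x = (eta, s, a, mu)`` is split into external (eta),
sensory (s), active (a) and internal (mu) coordinates; ``b = (s, a)`` is
the blanket.  A Markov blanket means ``eta`` and ``mu`` are conditionally
independent given ``b``, which for a zero-mean Gaussian
``p(x) = N(x; 0, Pi^{-1})`` is equivalent to a zero (eta, mu) block of the
precision matrix ``Pi``.

This module provides the bookkeeping (:class:`BlanketPartition`), the
density container (:class:`StationaryDensity`) with named block views of
``Pi`` and ``Sigma = Pi^{-1}``, blanket detection, conditional densities
given the blanket, and seeded generators for blanket-structured fixtures
and i.i.d. samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "BlanketPartition",
    "StationaryDensity",
    "ConditionalGaussian",
    "NoMarkovBlanketError",
    "is_markov_blanket",
    "conditional_independence_residual",
    "conditional_given_blanket",
    "expected_states",
    "sample_blanket_precision",
    "sample_stationary",
]

#: Default relative tolerance for zero-block and inverse checks.
DEFAULT_TOL = 1e-8


class NoMarkovBlanketError(ValueError):
    """Raised when an operation requires the Markov-blanket sparsity and
    the (eta, mu) precision block is not (numerically) zero."""


@dataclass(frozen=True)
class BlanketPartition:
    """Index bookkeeping for the ordered state decomposition
    ``x = (eta, s, a, mu)``.

    Canonical coordinate order is always [eta, s, a, mu]; blanket-only
    analyses (no sensory/active split) use ``d_a = 0``.
    """

    d_eta: int
    d_s: int
    d_a: int
    d_mu: int

    def __post_init__(self) -> None:
        for name in ("d_eta", "d_s", "d_a", "d_mu"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.d_eta < 1:
            raise ValueError("need at least one external coordinate (d_eta >= 1)")
        if self.d_mu < 1:
            raise ValueError("need at least one internal coordinate (d_mu >= 1)")
        if self.d_s + self.d_a < 1:
            raise ValueError("need at least one blanket coordinate (d_s + d_a >= 1)")

    @property
    def d_b(self) -> int:
        return self.d_s + self.d_a

    @property
    def d(self) -> int:
        return self.d_eta + self.d_b + self.d_mu

    def slices(self) -> dict[str, slice]:
        """Named index slices into the canonical coordinate order."""
        e, s, a, m = self.d_eta, self.d_s, self.d_a, self.d_mu
        return {
            "eta": slice(0, e),
            "s": slice(e, e + s),
            "a": slice(e + s, e + s + a),
            "b": slice(e, e + s + a),
            "mu": slice(e + s + a, e + s + a + m),
            "b:mu": slice(e, e + s + a + m),
            "eta:b": slice(0, e + s + a),
            "a:mu": slice(e + s, e + s + a + m),
            "x": slice(0, self.d),
        }


def _block(M: np.ndarray, part: BlanketPartition, rows: str, cols: str) -> np.ndarray:
    sl = part.slices()
    return M[sl[rows], sl[cols]]


@dataclass(frozen=True)
class ConditionalGaussian:
    """A Gaussian in mean/precision form, e.g. ``p(eta | b)``."""

    mean: np.ndarray
    precision: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.precision, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("precision must be square")
        if not np.allclose(P, P.T, atol=1e-10 * max(1.0, np.abs(P).max())):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(P).min() <= 0:
            raise ValueError("precision must be positive-definite")

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass(frozen=True)
class StationaryDensity:
    """The Gaussian steady state ``p = N(mean, Pi^{-1})`` with a blanket
    partition and cached covariance.

    Block views of ``Pi`` and ``Sigma`` follow the sub-matrix convention
    where a single index denotes a principal block (``Pi_eta`` for the
    (eta, eta) block) and a colon denotes a contiguous range
    (``Sigma_{b:mu}``).  Access them through :meth:`P` and :meth:`S`.
    """

    precision: np.ndarray
    partition: BlanketPartition
    mean: np.ndarray = None  # type: ignore[assignment]
    tol: float = DEFAULT_TOL
    covariance: np.ndarray = field(init=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        Pi = np.asarray(self.precision, dtype=float)
        d = self.partition.d
        if Pi.shape != (d, d):
            raise ValueError(
                f"precision shape {Pi.shape} does not match partition dimension {d}"
            )
        scale = max(1.0, np.abs(Pi).max())
        if not np.allclose(Pi, Pi.T, atol=self.tol * scale):
            raise ValueError("precision must be symmetric")
        Pi = (Pi + Pi.T) / 2.0
        if np.linalg.eigvalsh(Pi).min() <= 0:
            raise ValueError("precision must be positive-definite")
        mean = self.mean
        if mean is None:
            mean = np.zeros(d)
        mean = np.asarray(mean, dtype=float).reshape(d)
        Sigma = np.linalg.inv(Pi)
        Sigma = (Sigma + Sigma.T) / 2.0
        resid = np.abs(Pi @ Sigma - np.eye(d)).max()
        if resid > max(self.tol * scale, 1e-6):
            raise ValueError(f"Pi @ Sigma deviates from identity by {resid:.3e}")
        object.__setattr__(self, "precision", Pi)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", Sigma)

    # -- named block views ------------------------------------------------
    def P(self, rows: str, cols: str | None = None) -> np.ndarray:
        """Precision block, e.g. ``P('eta','mu')`` or principal ``P('b:mu')``."""
        return _block(self.precision, self.partition, rows, cols or rows)

    def S(self, rows: str, cols: str | None = None) -> np.ndarray:
        """Covariance block, same naming as :meth:`P`."""
        return _block(self.covariance, self.partition, rows, cols or rows)

    def mean_of(self, which: str) -> np.ndarray:
        return self.mean[self.partition.slices()[which]]

    @property
    def d(self) -> int:
        return self.partition.d


# ---------------------------------------------------------------------------
# Blanket detection and conditionals
# ---------------------------------------------------------------------------

def is_markov_blanket(density: StationaryDensity, tol: float = DEFAULT_TOL) -> bool:
    """True iff the (eta, mu) precision block vanishes, i.e. eta and mu are
    conditionally independent given the blanket b.

    The zero test is relative to the largest entry of Pi.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    block = density.P("eta", "mu")
    scale = max(1.0, np.abs(density.precision).max())
    return bool(np.abs(block).max(initial=0.0) <= tol * scale)


def conditional_independence_residual(density: StationaryDensity) -> np.ndarray:
    """Conditional cross-covariance of (eta, mu) given b:
    ``Sigma_{eta,mu} - Sigma_{eta,b} Sigma_b^{-1} Sigma_{b,mu}``.

    All entries are ~0 exactly when the blanket condition holds; otherwise
    the matrix quantifies the residual coupling between external and
    internal coordinates once the blanket is known.
    """
    S_b = density.S("b")
    try:
        solve_b = linalg.solve(S_b, density.S("b", "mu"), assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"blanket covariance block is singular: {exc}"
        ) from exc
    return density.S("eta", "mu") - density.S("eta", "b") @ solve_b


def conditional_given_blanket(
    density: StationaryDensity, b: np.ndarray, tol: float = DEFAULT_TOL
) -> tuple[ConditionalGaussian, ConditionalGaussian]:
    """The conditionals ``p(eta|b) = N(Sigma_{eta,b} Sigma_b^{-1} b, Pi_eta^{-1})``
    and ``p(mu|b) = N(Sigma_{mu,b} Sigma_b^{-1} b, Pi_mu^{-1})``.

    Requires the Markov blanket: only then are the principal precision
    blocks ``Pi_eta``, ``Pi_mu`` the conditional precisions.
    Means are computed in centered coordinates and shifted back.
    """
    if not is_markov_blanket(density, tol):
        raise NoMarkovBlanketError(
            "the (eta, mu) precision block is nonzero; p(eta|b), p(mu|b) do "
            "not take the blanket form"
        )
    b = np.asarray(b, dtype=float).reshape(density.partition.d_b)
    bc = b - density.mean_of("b")
    w = linalg.solve(density.S("b"), bc, assume_a="pos")
    eta_mean = density.mean_of("eta") + density.S("eta", "b") @ w
    mu_mean = density.mean_of("mu") + density.S("mu", "b") @ w
    return (
        ConditionalGaussian(eta_mean, density.P("eta")),
        ConditionalGaussian(mu_mean, density.P("mu")),
    )


def expected_states(
    density: StationaryDensity, b: np.ndarray, tol: float = DEFAULT_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Expected external and internal states given a blanket state:
    ``eta(b) = Sigma_{eta,b} Sigma_b^{-1} b`` and
    ``mu(b) = Sigma_{mu,b} Sigma_b^{-1} b`` (centered coordinates)."""
    cond_eta, cond_mu = conditional_given_blanket(density, b, tol)
    return cond_eta.mean, cond_mu.mean


# ---------------------------------------------------------------------------
# Fixture generation and sampling
# ---------------------------------------------------------------------------

def sample_blanket_precision(
    partition: BlanketPartition, seed: int, scale: float = 1.0
) -> StationaryDensity:
    """Seeded random precision matrix with an exact Markov blanket.

    Draws a dense symmetric matrix with standard-normal entries, zeroes the
    (eta, mu) block, then shifts by ``lambda * I`` with
    ``lambda = max(0, -lambda_min) + scale`` to force positive-definiteness.
    The diagonal shift cannot reintroduce (eta, mu) coupling, so the
    blanket sparsity is exact by construction.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    d = partition.d
    A = rng.standard_normal((d, d))
    Pi = (A + A.T) / 2.0
    sl = partition.slices()
    Pi[sl["eta"], sl["mu"]] = 0.0
    Pi[sl["mu"], sl["eta"]] = 0.0
    lam_min = np.linalg.eigvalsh(Pi).min()
    Pi += (max(0.0, -lam_min) + scale) * np.eye(d)
    return StationaryDensity(Pi, partition)


def sample_stationary(
    density: StationaryDensity, n: int, seed: int
) -> np.ndarray:
    """``n`` i.i.d. draws from ``N(mean, Sigma)`` as an (n, d) matrix,
    deterministic given ``seed`` (Cholesky transform of standard normals)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(density.covariance)
    Z = rng.standard_normal((n, density.d))
    return density.mean + Z @ L.T
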