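"""The synchronization map from internal to external coordinates.

When a Markov blanket holds, every blanket state b has an expected
external state ``eta(b)`` and an expected internal state ``mu(b)``.  The
synchronization map ``sigma`` sends ``mu(b)`` to ``eta(b)`` — internal
states then encode (predict) external states.  Existence requires a
kernel inclusion between cross-covariance blocks,
``ker Sigma_{mu,b} ⊆ ker Sigma_{eta,b}`` (equivalently on the precision
blocks); generically this holds whenever the blanket is no larger than
the internal space.

``sigma`` is always definable via pseudo-inverses,

    sigma = Sigma_{eta,b} Sigma_{mu,b}^-  =  Pi_eta^{-1} Pi_{eta,b} Pi_{mu,b}^- Pi_mu,

but it only maps expected internal to expected external states when the
kernel inclusion holds.  Both construction forms are kept and compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaussian_world import (
    NoMarkovBlanketError,
    StationaryDensity,
    is_markov_blanket,
)

__all__ = [
    "SyncMap",
    "sync_exists",
    "build_sync_map",
    "predict_external",
    "empirical_sync_table",
]

#: Relative singular-value cutoff for rank decisions / pseudo-inverses.
DEFAULT_RANK_TOL = 1e-10


def _pinv(M: np.ndarray, rank_tol: float) -> np.ndarray:
    return np.linalg.pinv(M, rcond=rank_tol)


def _require_blanket(density: StationaryDensity) -> None:
    if not is_markov_blanket(density):
        raise NoMarkovBlanketError("synchronization analysis requires a Markov blanket")


def sync_exists(
    density: StationaryDensity, rank_tol: float = DEFAULT_RANK_TOL
) -> tuple[bool, dict]:
    """Kernel-inclusion test for the existence of the synchronization map.

    Covariance form: exists iff
    ``|| Sigma_{eta,b} (I - Sigma_{mu,b}^- Sigma_{mu,b}) ||_max <= tol``,
    i.e. Sigma_{eta,b} annihilates the orthogonal projector onto
    ker Sigma_{mu,b}.  The same test on the precision blocks is an
    equivalent criterion; both verdicts are computed and returned in the
    diagnostics (they agree up to the rank tolerance).
    """
    if rank_tol < 0:
        raise ValueError("rank_tol must be nonnegative")
    _require_blanket(density)
    d_b = density.partition.d_b

    def kernel_residual(cross_eta: np.ndarray, cross_mu: np.ndarray) -> float:
        proj_ker = np.eye(d_b) - _pinv(cross_mu, rank_tol) @ cross_mu
        resid = cross_eta @ proj_ker
        scale = max(1.0, np.abs(cross_eta).max(initial=0.0))
        return float(np.abs(resid).max(initial=0.0) / scale)

    tol = max(rank_tol, 1e-12) * 1e3  # headroom over the SVD cutoff
    r_cov = kernel_residual(density.S("eta", "b"), density.S("mu", "b"))
    r_prec = kernel_residual(density.P("eta", "b"), density.P("mu", "b"))
    verdict_cov = r_cov <= tol
    verdict_prec = r_prec <= tol
    diagnostics = {
        "covariance_residual": r_cov,
        "precision_residual": r_prec,
        "covariance_verdict": verdict_cov,
        "precision_verdict": verdict_prec,
        "tolerance": tol,
    }
    return verdict_cov, diagnostics


@dataclass(frozen=True)
class SyncMap:
    """Linear map sigma from internal to external coordinates.

    ``matrix`` is the covariance-form construction (the default used for
    prediction); ``matrix_precision_form`` is the equivalent expression in
    precision blocks.  ``exists`` records the kernel-inclusion verdict:
    only then is ``sigma(mu(b)) = eta(b)`` guaranteed, and only then do
    the two forms agree on the map's domain Image(mu) (spanned by the
    columns of ``image_basis``).
    """

    matrix: np.ndarray
    matrix_precision_form: np.ndarray
    exists: bool
    diagnostics: dict
    image_basis: np.ndarray = None  # type: ignore[assignment]

    @property
    def d_eta(self) -> int:
        return self.matrix.shape[0]

    @property
    def d_mu(self) -> int:
        return self.matrix.shape[1]


def build_sync_map(
    density: StationaryDensity, rank_tol: float = DEFAULT_RANK_TOL
) -> SyncMap:
    """Construct sigma in both covariance and precision forms.

    The map is returned even when the existence test fails (it is always
    definable); ``exists`` flags whether it faithfully sends expected
    internal to expected external states.

    The domain of sigma is Image(mu) = range(Sigma_{mu,b}), recorded in
    ``image_basis`` (columns).  When the internal space is strictly
    larger than the blanket, the two matrix representations are free to
    differ off that image; as maps on Image(mu) they coincide whenever
    the existence conditions hold.
    """
    exists, diagnostics = sync_exists(density, rank_tol)
    cov_form = density.S("eta", "b") @ _pinv(density.S("mu", "b"), rank_tol)
    prec_form = (
        np.linalg.inv(density.P("eta"))
        @ density.P("eta", "b")
        @ _pinv(density.P("mu", "b"), rank_tol)
        @ density.P("mu")
    )
    return SyncMap(cov_form, prec_form, exists, diagnostics, density.S("mu", "b"))


def predict_external(sync: SyncMap, mu: np.ndarray) -> np.ndarray:
    """Apply sigma: predicted external state for internal state mu."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if mu.shape[-1] != sync.d_mu:
        raise ValueError(
            f"internal vector has dimension {mu.shape[-1]}, map expects {sync.d_mu}"
        )
    return mu @ sync.matrix.T if mu.ndim > 1 else sync.matrix @ mu


def empirical_sync_table(
    samples: np.ndarray,
    density: StationaryDensity,
    n_bins: int = 20,
    min_per_bin: int = 100,
    rank_tol: float = DEFAULT_RANK_TOL,
) -> pd.DataFrame:
    """Binned empirical check that internal states predict external states.

    Partitions the (one-dimensional) blanket coordinate of the samples
    into ``n_bins`` equal-probability (quantile) bins, averages external
    and internal coordinates within each bin, and applies sigma to the
    empirical internal mean.  Under the existence conditions,
    ``sigma_of_mu_bar`` tracks ``empirical_eta_bar`` bin by bin; in the
    degenerate case the predictions collapse to zero.

    Bins with fewer than ``min_per_bin`` samples are dropped.  Columns:
    bin_center, mean_b, empirical_eta_bar, empirical_mu_bar,
    sigma_of_mu_bar (suffixed ``_i`` when eta or mu is multi-dimensional),
    se_eta_bar, se_mu_bar, bin_count.
    """
    part = density.partition
    if part.d_b != 1:
        raise ValueError(
            f"binning requires a one-dimensional blanket, got d_b={part.d_b}"
        )
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != part.d:
        raise ValueError(f"samples must be (n, {part.d})")
    sync = build_sync_map(density, rank_tol)
    sl = part.slices()
    b = samples[:, sl["b"]].ravel()
    eta = samples[:, sl["eta"]]
    mu = samples[:, sl["mu"]]

    edges = np.quantile(b, np.linspace(0.0, 1.0, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    idx = np.searchsorted(edges, b, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)

    rows = []
    for k in range(n_bins):
        mask = idx == k
        count = int(mask.sum())
        if count < min_per_bin:
            continue
        eta_bar = eta[mask].mean(axis=0)
        mu_bar = mu[mask].mean(axis=0)
        pred = sync.matrix @ mu_bar
        se = eta[mask].std(axis=0, ddof=1) / np.sqrt(count)
        se_mu = mu[mask].std(axis=0, ddof=1) / np.sqrt(count)
        row: dict[str, float] = {
            "bin_center": float(b[mask].mean()),
            "mean_b": float(b[mask].mean()),
            "bin_count": count,
        }

        def put(name: str, vec: np.ndarray) -> None:
            if vec.size == 1:
                row[name] = float(vec[0])
            else:
                for i, v in enumerate(vec):
                    row[f"{name}_{i}"] = float(v)

        put("empirical_eta_bar", eta_bar)
        put("empirical_mu_bar", mu_bar)
        put("sigma_of_mu_bar", pred)
        put("se_eta_bar", se)
        put("se_mu_bar", se_mu)
        rows.append(row)
    return pd.DataFrame(rows)
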