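"""Named model presets for the worked examples and figure-style protocols.

Two presets ship the exact matrices printed in the worked examples
(`example_2_2`, `remark_3_2`).  The figure-style presets are seeded
fixtures at the stated dimensionalities — the reference simulations do
not publish their precision matrices, so these reproduce the protocol,
not the exact curves.
"""

from __future__ import annotations

import numpy as np

from .diffusion import DiffusionModel
from .gaussian_world import (
    BlanketPartition,
    StationaryDensity,
    sample_blanket_precision,
)

__all__ = ["PRESETS", "get_preset", "preset_names"]

#: Precision of the three-variable worked example (eta, b, mu each 1-D).
EXAMPLE_2_2_PRECISION = np.array(
    [[2.0, 1.0, 0.0], [1.0, 2.0, 1.0], [0.0, 1.0, 2.0]]
)

#: Solenoidal field of the worked diffusion example (antisymmetric).
REMARK_3_2_Q = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])


def example_2_2_density() -> StationaryDensity:
    return StationaryDensity(
        EXAMPLE_2_2_PRECISION, BlanketPartition(d_eta=1, d_s=1, d_a=0, d_mu=1)
    )


def remark_3_2_model() -> DiffusionModel:
    """The worked stationary diffusion: printed precision, solenoidal Q,
    identity volatility."""
    return DiffusionModel(
        density=example_2_2_density(),
        sigma_field=np.eye(3),
        q_field=REMARK_3_2_Q,
    )


def fig2_degenerate_density() -> StationaryDensity:
    """Blanket fixture where the synchronization map does not exist:
    Pi_mu_b = 0 while Pi_eta_b != 0, so internal states carry no
    information about the blanket and predictions collapse to zero."""
    Pi = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
    return StationaryDensity(Pi, BlanketPartition(d_eta=1, d_s=1, d_a=0, d_mu=1))


def _solenoidal(d: int, seed: int, strength: float = 1.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d, d))
    return strength * (A - A.T) / 2.0


def _seeded_ou_model(
    partition: BlanketPartition, seed: int, solenoidal_strength: float = 1.0
) -> DiffusionModel:
    density = sample_blanket_precision(partition, seed=seed, scale=1.0)
    Q = _solenoidal(partition.d, seed + 1, solenoidal_strength)
    return DiffusionModel(density=density, sigma_field=np.eye(partition.d), q_field=Q)


def fig5_like_model() -> DiffusionModel:
    """Perturb-and-relax OU protocol at 2 external + 2 blanket + 2
    internal dimensions, with moderate solenoidal flow (seeded fixture)."""
    return _seeded_ou_model(BlanketPartition(2, 2, 0, 2), seed=11, solenoidal_strength=1.0)


def fig6_like_model() -> DiffusionModel:
    """One-dimensional eta/b/mu relaxation protocol (seeded fixture)."""
    return _seeded_ou_model(BlanketPartition(1, 1, 0, 1), seed=23, solenoidal_strength=1.0)


def fig8_like_model() -> DiffusionModel:
    """Active-inference protocol: 2 external, 1 sensory, 1 active, 2
    internal.  The solenoidal field carries a strong antisymmetric
    sensory-active circulation on top of a weak random component: that
    circulation is what makes realized actions track the optimal action
    with a delay (the 'reaction time' signature)."""
    part = BlanketPartition(2, 1, 1, 2)
    density = sample_blanket_precision(part, seed=37, scale=1.0)
    Q = _solenoidal(part.d, seed=38, strength=0.5)
    sl = part.slices()
    i_s, i_a = sl["s"].start, sl["a"].start
    Q[i_s, i_a] += 1.5
    Q[i_a, i_s] -= 1.5
    return DiffusionModel(density=density, sigma_field=np.eye(part.d), q_field=Q)


def transition_model() -> DiffusionModel:
    """State-dependent volatility at the worked-example steady state.

    sigma(x) = sqrt(2 c(x)) I with c(x) = 0.05 + 2 tanh(x_0)^2, so
    Gamma(x) = c(x) I and the analytic divergence is grad c.  The noise
    amplitude varies ~40x across typical states: the time-marginal stays
    N(0, Sigma) by construction, but transition densities from a point
    mass become strongly non-Gaussian (heavy-tailed mixtures over noise
    histories) — the demonstration that Gaussian steady state does not
    mean Gaussian process.
    """
    density = example_2_2_density()

    def c(x: np.ndarray) -> float:
        return 0.05 + 2.0 * np.tanh(x[0]) ** 2

    def sigma_field(x: np.ndarray) -> np.ndarray:
        return np.sqrt(2.0 * c(x)) * np.eye(3)

    def q_field(x: np.ndarray) -> np.ndarray:
        return np.zeros((3, 3))

    def divergence_fn(x: np.ndarray) -> np.ndarray:
        t = np.tanh(x[0])
        grad_c = np.array([4.0 * t * (1.0 - t**2), 0.0, 0.0])
        return grad_c

    return DiffusionModel(
        density=density,
        sigma_field=sigma_field,
        q_field=q_field,
        divergence_mode="analytic",
        divergence_fn=divergence_fn,
    )


def chain_pid_spec() -> dict:
    """Order-2 scalar integrator chain (integral, proportional,
    derivative levels), unit damping and coupling, unit noise."""
    return {
        "order": 2,
        "dims": [1, 1, 1],
        "self_drifts": [[[-1.0]], [[-1.0]], [[-1.0]]],
        "couplings": [[[1.0]], [[1.0]]],
        "volatilities": [[[1.0]], [[1.0]], [[1.0]]],
    }


PRESETS: dict[str, dict] = {
    "example_2_2": {
        "kind": "density",
        "factory": example_2_2_density,
        "description": "printed 3x3 precision with a 1-D blanket",
    },
    "remark_3_2": {
        "kind": "model",
        "factory": remark_3_2_model,
        "description": "printed stationary diffusion (solenoidal Q, unit noise)",
    },
    "fig2_degenerate": {
        "kind": "density",
        "factory": fig2_degenerate_density,
        "description": "blanket without a synchronization map (Pi_mu_b = 0)",
    },
    "fig5_like": {
        "kind": "model",
        "factory": fig5_like_model,
        "description": "2+2+2 OU relaxation fixture with solenoidal flow",
    },
    "fig6_like": {
        "kind": "model",
        "factory": fig6_like_model,
        "description": "1+1+1 OU relaxation fixture",
    },
    "fig8_like": {
        "kind": "model",
        "factory": fig8_like_model,
        "description": "2+1+1+2 active-inference fixture",
    },
    "transition_nongaussian": {
        "kind": "model",
        "factory": transition_model,
        "description": "state-dependent volatility, non-Gaussian transitions",
    },
    "chain_pid": {
        "kind": "chain",
        "factory": chain_pid_spec,
        "description": "order-2 scalar integrator chain (PID levels)",
    },
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str):
    """Instantiate a preset by name (density, model, or chain spec)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    return PRESETS[name]["factory"]()
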