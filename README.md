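# bayesmech

Simulation and analysis of stationary stochastic processes with a
Gaussian Markov blanket — the mathematical skeleton behind "Bayesian
mechanics" descriptions of adaptive systems: cells, brains and
controllers that persist by maintaining a steady state with their
environment.

## The model

The world state is a vector `x = (η, s, a, μ)` split into **external**
(η), **sensory** (s), **active** (a) and **internal** (μ) coordinates;
`b = (s, a)` is the **blanket**. The steady state is a Gaussian
`p(x) = N(0, Π⁻¹)` with precision Π. A **Markov blanket** — conditional
independence η ⊥ μ | b — is equivalent to a zero (η, μ) block of Π.

Given the blanket, the package computes:

- **Conditionals and expected states.** `p(η|b) = N(Σ_ηb Σ_b⁻¹ b, Π_η⁻¹)`
  and its internal counterpart; `η(b)` and `μ(b)` are the conditional
  means.
- **The synchronization map** `σ = Σ_ηb Σ_μb⁻ = Π_η⁻¹ Π_ηb Π_μb⁻ Π_μ`,
  sending expected internal to expected external states,
  `σ(μ(b)) = η(b)`, when the kernel inclusion `ker Σ_μb ⊆ ker Σ_ηb`
  holds. Internal states then *predict* external states.
- **Stationary diffusions.** Any volatility field ς and antisymmetric
  field Q define `dx = (Γ+Q)∇log p dt + ∇·(Γ+Q) dt + ς dW` with
  `Γ = ςςᵀ/2`, which keeps `p` invariant — dissipative flow plus
  solenoidal circulation. For constant fields this is an
  Ornstein–Uhlenbeck process with drift `B = −(Γ+Q)Π` satisfying the
  Lyapunov identity `BΣ + ΣBᵀ + ςςᵀ = 0` exactly.
- **Variational free energy.** Each internal state holds a belief
  `q_μ(η) = N(σ(μ), Π_η⁻¹)`;
  `F(b, μ) = KL[q_μ ‖ p(η|b)] − log p(b, μ) = Energy − Entropy`, with all
  constants kept so both decompositions are exact. The unique minimizer
  over μ is `μ(b)` — inference and precision-weighted prediction-error
  minimization (`ξ = Π_η(η − σ(μ))`) coincide.
- **Stochastic control.** The expected autonomous states `(a, μ)`
  minimize the quadratic cost `[s,a,μ] K [s,a,μ]ᵀ` with gain
  `K = Σ_{b:μ}⁻¹` — homeostatic feedback toward the steady-state
  set-point.
- **Integrator chains and PID-like gains.** A sensory signal with
  exponentially decaying autocovariance is realizable as the linear
  output of nested Ornstein–Uhlenbeck processes (orders of motion);
  the extended control objective then yields per-order feedback gains —
  integral, proportional, derivative for a three-level chain.

## Worked example

The 3-variable steady state with precision

```
Π = [[2, 1, 0],
     [1, 2, 1],
     [0, 1, 2]]
```

(one external, one blanket, one internal coordinate) has an exact Markov
blanket — the (η, μ) entry of Π is zero.

```python
import numpy as np
import bayesmech as bm

Pi = np.array([[2.0, 1.0, 0.0],
               [1.0, 2.0, 1.0],
               [0.0, 1.0, 2.0]])
density = bm.StationaryDensity(Pi, bm.BlanketPartition(d_eta=1, d_s=1, d_a=0, d_mu=1))
print("Markov blanket:", bm.is_markov_blanket(density))
sync = bm.build_sync_map(density)
print("sync map sigma:", sync.matrix)
eta_bar, mu_bar = bm.expected_states(density, b=[2.0])
print("eta(b), mu(b) at b=2:", eta_bar, mu_bar)
F = bm.free_energy(b=[2.0], mu=[0.0], density=density, sync=sync)
print("F(b=2, mu=0) = %.4f  (KL = %.4f, -log p(b,mu) = %.4f)"
      % (F.total, F.kl, F.neg_log_joint_particular))
print("argmin_mu F:", bm.minimize_free_energy([2.0], density, sync))
print("gain K:", bm.control_gain_matrix(density).gain)
```

prints

```
Markov blanket: True
sync map sigma: [[1.]]
eta(b), mu(b) at b=2: [-1.] [-1.]
F(b=2, mu=0) = 5.4913  (KL = 1.0000, -log p(b,mu) = 4.4913)
argmin_mu F: [-1.]
gain K: [[1.5 1. ]
 [1.  2. ]]
```

Reading: observing the blanket state b = 2, the expected external and
internal states are both −1; the synchronization map is the identity, so
the internal state's prediction of the environment is exact at μ(b). An
internal state μ = 0 carries one nat of KL inaccuracy; minimizing free
energy over μ recovers μ(b) = −1. The gain matrix `K = Σ_{b:μ}⁻¹` is the
particular-state precision `[[1.5, 1], [1, 2]]`.

## Command line

```sh
bayesmech presets                       # list named model presets
bayesmech fixture --d-eta 1 --d-s 1 --d-mu 1 --seed 7
bayesmech validate --config run.yaml
bayesmech run --config run.yaml --out results/
```

A config names an experiment (`syncmap`, `transition`, `relax`,
`active`, `chain`), a preset or explicit matrices, and a mandatory seed;
outputs are CSV tables plus a JSON manifest, byte-identical across
re-runs of the same config.

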