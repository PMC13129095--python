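# predinet

Recurrent rate-network models of **multimodal, high-dimensional predictive
processing**, for computational neuroscientists studying prediction-error
signalling, excitation/inhibition balance, and mixed selectivity in sensory
cortex.

When an animal learns that two signals go together — a lever press and a
tone, running and visual flow — cortical responses to the *predicted*
stimulus are suppressed, while violations of the prediction (mismatches)
evoke amplified responses.  `predinet` implements a recurrent network model
of this computation: `N` neurons receive `P` pairs of stimuli `(x_k, y_k)`
through Gaussian weight vectors `(w^k, v^k)` whose within-pair correlation
`μ` tracks learning, with dynamics

    dh/dt = −h + b ( J φ(h) + Wx + Vy ),      J = −(1/N)(WWᵀ + VVᵀ),

whose fixed point minimizes squared multimodal prediction errors
`Σ_k (x_k − x̂_k)² + (y_k − ŷ_k)²` (with internal predictions
`x̂_k = w^k·r/N`) plus an encoding cost controlled by the gain `b`.  On top
of the core simulator the package provides:

* **balance observables** — per-neuron ratio `B = |I^F/(I^F − I^R)|` of
  feedforward to net input, the closed-form mismatch/match voltage-variance
  ratio and its inversion for `b`, and the constrained optimal-gain search;
* **functional cell types** — representation (R) vs prediction-error (PE)
  classification, mixed-representation and dedicated-PE fractions,
  segregation index and representation similarity;
* **decoders** — match/mismatch readout from stimuli vs network responses,
  max-margin vs population-mean-rate;
* **E/I decompositions** — a Dale-compliant family indexed by `λ_EI`
  (private inhibition → inhibitory prediction units) whose excitatory
  population reproduces the original network exactly;
* **a three-module hierarchical variant** with bidirectional predictions and
  a unidirectional control;
* **transient protocols** — pulse and step stimulation, decay timescales,
  time-resolved balance and cell types;
* **synthetic recordings** — trial-based voltage- and rate-style datasets
  with serialized ground truth, and fits that recover `b` and `λ_EI`.

See `docs/methods.md` for the model conventions, numerical choices and known
limitations, and `examples/` for one narrative script per capability.

## Worked example

```python
import numpy as np
from predinet import (calibrate_gain_to_balance, make_network,
                      mixed_fraction, pair_geometry)
from predinet.celltypes import pair_voltages

# gain calibrated so the median match-condition balance equals the
# intracellular estimate B* = 162
b_star = calibrate_gain_to_balance(target=162.0, mu=0.97, N=2000, seed=0)
print(round(b_star, 1))                      # 174.1

# learning suppresses match responses and amplifies mismatches
geo = pair_geometry(make_network(N=3000, P=1, mu=0.9, b=20.0, seed=0))
print(round(geo.rate_ratio, 2))              # 1.24  (mismatch/match mean rate)
print(round(geo.cos_xy, 2))                  # -0.37 (anti-aligned mismatch responses)

# two learned pairs: a quarter of dually-responsive neurons carry
# different functional types for the two associations
net = make_network(N=4000, P=2, mu=0.97, b=b_star, seed=0)
sigma = float(np.std(pair_voltages(net, 0)[0]))
res = mixed_fraction(net, sigma=sigma, center=False)
print(round(100 * res.fraction, 1))          # 26.0  (% mixed, this instance)
```

The first number is the gain at which the model's match-condition balance
reproduces the voltage-clamp estimate from an overtrained animal; the last
is the headline desegregation result — stimulus and prediction-error coding
share neurons instead of segregating into dedicated populations
(about 25% mixed when averaged over instances).

## Command line

A thin CLI drives the same library from YAML configs:

```bash
predinet steady config.yaml        # steady states -> CSV + manifest
predinet balance config.yaml
predinet decode config.yaml
predinet ei-decompose config.yaml
```

with subcommands `steady, simulate, balance, optimal-gain, classify, mixed,
decode, ei-decompose, hier, gen-synthetic, fit-recordings, segregation`.  A
minimal config:

```yaml
model:            # network
  N: 1000         # neurons
  P: 2            # stimulus-pairs
  mu: 0.97        # learning stage (0 = untrained)
  b: 20.0         # gain
  theta: 0.0      # ReLU threshold
  seed: 0
stimuli:
  pair: 0
  conditions: [x_only, y_only, match]
solver:
  tol: 1.0e-10
output:
  dir: runs/demo
```

Optional per-command blocks (`decode`, `ei`, `hier`, `recording`,
`optimal_gain`) are validated with explicit error messages; every run
writes a `manifest.json` with the config, seeds and output list, and reruns
are bit-identical.

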