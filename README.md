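# rulesrnn

Excitatory–inhibitory **spiking recurrent neural networks** (SRNNs) for
rule-dependent working-memory tasks: task synthesis, surrogate-gradient
training, single-unit and population analysis, and test-time perturbation
experiments — in NumPy, with compiled (numba) inner loops.

## The scientific problem

Prefrontal circuits hold a task rule in working memory across a delay and
use it to gate conflicting sensory evidence. `rulesrnn` models this with a
two-alternative forced-choice (2AFC) task: a 100-ms cue signals the rule
("attend vision" vs. "attend audition"), a 400-ms delay follows, then
visual and auditory targets appear on (possibly different) sides and the
network must choose the side of the attended modality. The model is a
recurrent network of leaky integrate-and-fire neurons with

* **Dale's principle** — 80% excitatory / 20% inhibitory units with a fixed
  sign mask `W_rec = M ⊙ D` (`d_exc = 1`, `d_inh = −φ/(1−φ) = −4`,
  normalized and balanced so Σd = 0), magnitudes `M ≥ 0` at all times;
* **spike-frequency adaptation (SFA)** — a random 25% of units carry an
  adaptive threshold `V_th(t) = v_th + ψ A(t)`, `A ← φA + (1−φ)S`,
  `τ_a = 400 ms`, which extends the network's memory timescale;
* **SuperSpike training** — backpropagation through time over the discrete
  spiking dynamics, with the fast-sigmoid pseudo-derivative
  `σ'(V) = 1/(1+β|V−V_th|)²` replacing the Heaviside threshold's derivative,
  Adam updates, and a zero-clip on `M` after every step (Dale projection);
* a **firing-rate penalty** `λ Σ_b (mean population rate in bin b)²` that
  keeps population activity sparse.

After training, the package quantifies what emerged: rule-specific tuning
peaks in z-scored PSTHs, peak-to-noise ratios, neural sequences (the
sequentiality index: peak-time entropy + mean log ridge-to-background),
PCA state-space trajectories with kinetic energy `½‖ẋ‖²`, spike
correlograms, beta-band (15–30 Hz) rhythmicity of inhibitory units, an LFP
proxy (summed synaptic currents), and LSTM population decoding. Test-time
perturbations probe the trained network: cue-ambiguity psychometrics, delay
elongation, weight sparsification, E/I block scaling and distractor pulses.

## A worked example

A two-minute version (80 units, 10 short epochs; this is
`examples/03_train_small.py`):

```python
import numpy as np
from rulesrnn import SimulationParams, TrainingConfig, evaluate, init_network, train

params = SimulationParams(n_rec=80)
tcfg = TrainingConfig(batch_size=16, batches_per_epoch=15, max_epochs=10,
                      val_trials=32, seed=0)
weights = init_network(params, np.random.default_rng(0))
result = train(weights, params, tcfg, verbose=True)
print(evaluate(result.weights, params, 100, seed=123))
```

which prints (abridged):

```
epoch 7: L_mse=0.2675 val_acc=0.719
epoch 9: L_mse=0.2334 val_acc=0.906

held-out accuracy after 10 short epochs: 0.76 (95% CI 0.66-0.84)
congruent (side readable without the rule) vs incongruent: 1.00 vs 0.54
```

`L_mse` is the readout loss on the final five steps of the trial; `val_acc`
is choice accuracy on held-out balanced trials. The numbers show the
characteristic learning order: congruent trials (both targets on the same
side, solvable without the rule) are perfect after a few epochs while
incongruent trials sit at chance, so overall accuracy plateaus near 0.75.
The full scaled-down preset (`scaled_down_params()` /
`scaled_down_training()`: 128E+32I, up to 120 epochs, ~15 minutes on one
CPU) pushes through that plateau — the rule is latched across the delay and
held-out accuracy reaches 0.97-1.00 depending on the initialization seed.

The `examples/` directory contains short narrative scripts, one per
capability: task + encoder, network simulation, training, tuning/sequence/
trajectory analysis, and perturbation sweeps. The `rulesrnn` console
command exposes `train`, `simulate`, `evaluate` and `perturb` for shell
use; checkpoints are HDF5 files that round-trip all weights bit-exactly.

See `docs/methods.md` for the full model description, unit conventions,
the discretization, and the design of each analysis statistic.

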