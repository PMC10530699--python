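"""Test-time perturbations of a (quickly pre-trained) network.

Sweeps cue ambiguity and recurrent-weight sparsity and prints the accuracy
curves. With a fully trained network (see the training preset) the
psychometric curve falls to 0.5 at q = 0.5 and accuracy degrades with
sparsity; this abbreviated run shows the mechanics on a partially trained
network in about two minutes.
"""

import numpy as np

from rulesrnn import SimulationParams, TrainingConfig, init_network, train
from rulesrnn.perturb import sweep_mixture, sweep_sparsity

params = SimulationParams(n_rec=40)
tcfg = TrainingConfig(batch_size=16, batches_per_epoch=10, max_epochs=3,
                      val_trials=16, seed=1)
weights = train(init_network(params, np.random.default_rng(1)),
                params, tcfg).weights

print("cue-ambiguity sweep (q = fraction of the trial's own rule in the cue):")
print(sweep_mixture(weights, params, grid=(0.5, 0.75, 1.0), n_trials=60)
      .to_string(index=False))
print("\nrecurrent sparsification sweep:")
print(sweep_sparsity(weights, params, fractions=(0.0, 0.3), n_trials=60)
      .to_string(index=False))
print("\naccuracy at q=0.5 sits at chance by construction; the sparsity "
      "column shows how robust the readout is to deleted synapses.")
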