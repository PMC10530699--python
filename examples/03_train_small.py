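"""Train a small network on the 2AFC task (abbreviated schedule).

Runs a short surrogate-gradient training on an 80-unit network so the
example finishes in a couple of minutes; the full scaled-down preset
(scaled_down_params / scaled_down_training) trains a 160-unit network to
criterion in ~15 minutes. Watch the readout loss fall and the congruent
trials (solvable from the stimulus alone) be learned first, while the
incongruent trials — which require the rule — stay near chance on this
abbreviated budget.
"""

import numpy as np

from rulesrnn import SimulationParams, TrainingConfig, evaluate, init_network, train

params = SimulationParams(n_rec=80)
tcfg = TrainingConfig(batch_size=16, batches_per_epoch=15, max_epochs=10,
                      val_trials=32, seed=0)
weights = init_network(params, np.random.default_rng(0))

result = train(weights, params, tcfg, verbose=True)
ev = evaluate(result.weights, params, 100, seed=123)
print(f"\nheld-out accuracy after {result.epochs_run} short epochs: "
      f"{ev['accuracy']:.2f} (95% CI {ev['ci_low']:.2f}-{ev['ci_high']:.2f})")
print("congruent (side readable without the rule) vs incongruent:",
      f"{ev['by_condition']['congruent']:.2f} vs "
      f"{ev['by_condition']['incongruent']:.2f}")
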