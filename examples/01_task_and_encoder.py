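"""Build one task trial and encode it into spikes.

A trial is 200 ms fixation, 100 ms rule cue, 400 ms delay, 100 ms stimulus.
Five LIF encoder neurons turn the analog channel currents into spike trains;
the two rule cues differ in amplitude and therefore in encoder firing rate.
"""

import numpy as np

from rulesrnn import SimulationParams, TrialSpec, build_trial_inputs, encode_to_spikes

params = SimulationParams(n_rec=5)
spec = TrialSpec(rule=1, visual_side="L", auditory_side="R")
inputs = build_trial_inputs(spec, params, rng=np.random.default_rng(0))
spikes = encode_to_spikes(inputs)

print(f"trial: rule {spec.rule}, correct choice {spec.correct_choice}")
print(f"steps: {inputs.n_step} (fixation ends {inputs.fixation_end}, "
      f"cue ends {inputs.cue_end}, delay ends {inputs.delay_end})")
cue_window = slice(inputs.fixation_end, inputs.cue_end)
stim_window = slice(inputs.delay_end, None)
print(f"cue-channel rate during cue: "
      f"{spikes[0, cue_window].mean() / 0.002:.0f} Hz "
      f"(rule 2 would give ~100 Hz; the rate encodes the rule)")
print(f"active sensory channels during stimulus: "
      f"{[i for i in range(1, 5) if spikes[i, stim_window].sum() > 0]} "
      f"(1=vision L, 4=audition R)")
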