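"""Trial synthesis for the rule-dependent forced-choice task.

A trial is: 200 ms fixation (white noise only), 100 ms rule cue, a delay
(400 ms by default, white noise only), and a 100 ms presentation of
conflicting visual and auditory targets. Five input channels carry the trial
as analog currents -- channel 0 the rule cue, channels 1-4 the four sensory
streams (Vision/L, Vision/R, Audition/L, Audition/R) -- and a bank of five
LIF encoder neurons converts the currents to spike trains. Rule 1 means
"attend vision", rule 2 "attend audition"; the rewarded side is the side of
the attended modality, so only incongruent trials reveal which rule was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .params import EncoderParams, SimulationParams

FIXATION_MS = 200.0
CUE_MS = 100.0
STIMULUS_MS = 100.0
DEFAULT_DELAY_MS = 400.0

#: Constant cue currents for the two rules, and for an active sensory channel.
#: Chosen so both rule cues drive the encoder above threshold at distinct rates.
CUE_AMP_RULE1 = 2.0
CUE_AMP_RULE2 = 1.2
SENSORY_AMP = 2.0

#: SD of the zero-mean white-noise background current during fixation/delay.
NOISE_SD = 0.05

CHANNEL_NAMES = ("cue", "vision_L", "vision_R", "audition_L", "audition_R")


@dataclass(frozen=True)
class Distractor:
    """A square current pulse injected on the cue channel during the delay."""

    onset_ms: float          # relative to delay start
    duration_ms: float = 50.0
    amplitude: float = 1.0


@dataclass(frozen=True)
class TrialSpec:
    rule: int = 1                       # 1 = attend vision, 2 = attend audition
    visual_side: str = "L"
    auditory_side: str = "R"
    mixture_q: float = 1.0              # fraction of rule-1 signal in the cue
    delay_ms: float = DEFAULT_DELAY_MS
    distractor: Optional[Distractor] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in (1, 2):
            raise ValueError("rule must be 1 or 2")
        if self.visual_side not in ("L", "R") or self.auditory_side not in ("L", "R"):
            raise ValueError("sides must be 'L' or 'R'")
        if not 0.0 <= self.mixture_q <= 1.0:
            raise ValueError("mixture_q must lie in [0, 1]")
        if self.delay_ms <= 0:
            raise ValueError("delay_ms must be positive")

    @property
    def correct_choice(self) -> str:
        return self.visual_side if self.rule == 1 else self.auditory_side

    @property
    def total_ms(self) -> float:
        return FIXATION_MS + CUE_MS + self.delay_ms + STIMULUS_MS

    @property
    def congruent(self) -> bool:
        return self.visual_side == self.auditory_side


@dataclass
class AnalogInputs:
    """5 x n_step matrix of input currents plus the period boundaries (steps)."""

    currents: np.ndarray
    dt: float
    fixation_end: int
    cue_end: int
    delay_end: int

    @property
    def n_step(self) -> int:
        return self.currents.shape[1]


def _n_steps(duration_ms: float, dt: float) -> int:
    n = duration_ms / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"period of {duration_ms} ms is not divisible by dt={dt} ms")
    return round(n)


def cue_waveform(mixture_q: float, n_step: int) -> np.ndarray:
    """Cue-channel current: the convex mixture q*rule1 + (1-q)*rule2.

    ``mixture_q`` is the fraction of the rule-1 waveform in the cue; q=1 is a
    clean rule-1 cue, q=0 a clean rule-2 cue, q=0.5 maximally ambiguous.
    """
    amp = mixture_q * CUE_AMP_RULE1 + (1.0 - mixture_q) * CUE_AMP_RULE2
    return np.full(n_step, amp)


def own_rule_fraction_to_q(rule: int, own_fraction: float) -> float:
    """Map 'fraction of the trial's own rule in the cue' onto mixture_q."""
    return own_fraction if rule == 1 else 1.0 - own_fraction


def build_trial_inputs(
    spec: TrialSpec,
    params: SimulationParams,
    noise_sd: float = NOISE_SD,
    rng: Optional[np.random.Generator] = None,
) -> AnalogInputs:
    """Render a trial specification into the 5-channel current matrix."""
    dt = params.dt
    n_fix = _n_steps(FIXATION_MS, dt)
    n_cue = _n_steps(CUE_MS, dt)
    n_delay = _n_steps(spec.delay_ms, dt)
    n_stim = _n_steps(STIMULUS_MS, dt)
    n_step = n_fix + n_cue + n_delay + n_stim

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    cur = np.zeros((5, n_step))
    # white-noise background on all channels during fixation and delay
    if noise_sd > 0:
        cur[:, :n_fix] = rng.normal(0.0, noise_sd, size=(5, n_fix))
        cur[:, n_fix + n_cue : n_fix + n_cue + n_delay] = rng.normal(
            0.0, noise_sd, size=(5, n_delay)
        )

    cur[0, n_fix : n_fix + n_cue] = cue_waveform(spec.mixture_q, n_cue)

    stim0 = n_fix + n_cue + n_delay
    vis_ch = 1 if spec.visual_side == "L" else 2
    aud_ch = 3 if spec.auditory_side == "L" else 4
    cur[vis_ch, stim0:] = SENSORY_AMP
    cur[aud_ch, stim0:] = SENSORY_AMP

    if spec.distractor is not None:
        d = spec.distractor
        on = n_fix + n_cue + _n_steps(d.onset_ms, dt)
        off = on + _n_steps(d.duration_ms, dt)
        if off > stim0:
            raise ValueError("distractor extends past the delay period")
        cur[0, on:off] += d.amplitude

    return AnalogInputs(
        currents=cur,
        dt=dt,
        fixation_end=n_fix,
        cue_end=n_fix + n_cue,
        delay_end=stim0,
    )


def encode_to_spikes(
    inputs: AnalogInputs | np.ndarray,
    enc: EncoderParams = EncoderParams(),
    dt: float = 2.0,
) -> np.ndarray:
    """LIF-encode analog currents into binary spike trains (channels x steps).

    Exponential-Euler integration with reset to rest on spike; the encoder is
    deterministic -- trial-to-trial variability enters through the white-noise
    component of the currents. For a constant suprathreshold current the
    inter-spike interval matches the exact continuous-time LIF solution
    rounded up to the step grid (exponential Euler is exact between resets).
    """
    if isinstance(inputs, AnalogInputs):
        cur, dt = inputs.currents, inputs.dt
    else:
        cur = np.asarray(inputs)
    n_ch, n_step = cur.shape
    alpha = np.exp(-dt / enc.tau_m)
    drive = (1.0 - alpha) * enc.R * cur
    v = np.full(n_ch, enc.v_rest)
    spikes = np.zeros((n_ch, n_step), dtype=np.uint8)
    for t in range(n_step):
        v = enc.v_rest + alpha * (v - enc.v_rest) + drive[:, t]
        fired = v >= enc.v_th
        spikes[fired, t] = 1
        v[fired] = enc.v_rest
    return spikes


def choice_target(choice: str, n_outputs: int = 2) -> np.ndarray:
    """Decoder voltage target: (0,1) codes a left choice, (1,0) a right choice."""
    if n_outputs == 2:
        return np.array([0.0, 1.0]) if choice == "L" else np.array([1.0, 0.0])
    raise ValueError("use port_target for 4AFC")


def port_target(rule: int, side: str) -> np.ndarray:
    """4AFC one-hot target over (Vision-L, Vision-R, Audition-L, Audition-R)."""
    idx = {(1, "L"): 0, (1, "R"): 1, (2, "L"): 2, (2, "R"): 3}[(rule, side)]
    y = np.zeros(4)
    y[idx] = 1.0
    return y


@dataclass
class TrialBatch:
    specs: list
    analogs: list
    spikes: list          # each (5, n_step) uint8
    targets: np.ndarray   # (n, n_outputs)


def export_batch(batch: "TrialBatch", out_dir) -> None:
    """Write a batch as a JSON sidecar of trial specs plus a CSV spike-event
    list of the encoder output (columns: trial_id, channel, time_ms)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = []
    for s in batch.specs:
        d = asdict(s)
        d["correct_choice"] = s.correct_choice
        specs.append(d)
    (out / "trial_specs.json").write_text(json.dumps(specs, indent=1))
    rows = ["trial_id,channel,time_ms"]
    for i, spk in enumerate(batch.spikes):
        ch, t = np.nonzero(spk)
        for c, k in zip(ch, t):
            rows.append(f"{i},{CHANNEL_NAMES[c]},{k * 2.0}")
    (out / "input_spikes.csv").write_text("\n".join(rows) + "\n")


def make_batch(
    n: int,
    params: SimulationParams,
    base_seed: int = 0,
    balance: bool = True,
    own_rule_fraction: float = 1.0,
    delay_ms: float = DEFAULT_DELAY_MS,
    distractor: Optional[Distractor] = None,
    noise_sd: float = NOISE_SD,
    enc: EncoderParams = EncoderParams(),
    sides: str = "independent",
) -> TrialBatch:
    """Draw ``n`` trials; rules alternate exactly when ``balance`` is set,
    sides are sampled independently (50/50) per trial.

    ``own_rule_fraction`` sets the cue purity: 1.0 gives every trial a clean
    cue for its own rule, 0.5 a fully ambiguous cue for both rules.
    ``sides`` may be "independent" (default) or "incongruent" (visual and
    auditory targets always on opposite sides, so every trial requires the
    rule).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sides not in ("independent", "incongruent"):
        raise ValueError("sides must be 'independent' or 'incongruent'")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n)
    specs, analogs, ys = [], [], []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        rule = (i % 2) + 1 if balance else int(rng.integers(1, 3))
        vside = "L" if rng.random() < 0.5 else "R"
        if sides == "incongruent":
            aside = "R" if vside == "L" else "L"
            rng.random()                      # keep the draw count stable
        else:
            aside = "L" if rng.random() < 0.5 else "R"
        spec = TrialSpec(
            rule=rule,
            visual_side=vside,
            auditory_side=aside,
            mixture_q=own_rule_fraction_to_q(rule, own_rule_fraction),
            delay_ms=delay_ms,
            distractor=distractor,
            seed=int(children[i].generate_state(1)[0] % (2**31)),
        )
        ai = build_trial_inputs(spec, params, noise_sd=noise_sd, rng=rng)
        specs.append(spec)
        analogs.append(ai)
        if params.n_outputs == 2:
            ys.append(choice_target(spec.correct_choice))
        else:
            ys.append(port_target(spec.rule, spec.correct_choice))
    # encode all trials in one LIF pass (channels are independent)
    n_step = analogs[0].n_step
    stacked = np.concatenate([ai.currents for ai in analogs], axis=0)
    spikes = encode_to_spikes(stacked, enc, dt=params.dt).reshape(n, 5, n_step)
    spk = [spikes[i] for i in range(n)]
    return TrialBatch(specs=specs, analogs=analogs, spikes=spk, targets=np.array(ys))
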