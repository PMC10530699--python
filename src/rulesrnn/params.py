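"""Model hyperparameters.

All voltages are in mV, times in ms, currents in nA. The membrane resistance
``R`` is stored in GOhm; with currents in nA the product ``R * I`` is then in
mV after the 1e3 scale fold (10^-2 GOhm == 10 mV/nA), which is what the
voltage update uses. Per-step Gaussian noise terms are scaled by sqrt(dt) in
seconds (Euler-Maruyama), so the variances below are per-second spectral
densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


@dataclass
class SimulationParams:
    """Constants of the recurrent network and its integration.

    Defaults are the reference configuration of the model: a 500-unit network
    with an 80/20 excitatory/inhibitory split, 2-ms Euler steps, spike-frequency
    adaptation on a random quarter of the units, and a random-walk baseline
    current that keeps units firing at a few Hz in the absence of input.
    """

    dt: float = 2.0                 # ms
    v_rest: float = -65.0           # mV
    v_th: float = -50.0             # mV
    tau_m: float = 20.0             # ms, membrane
    tau_syn_exc: float = 35.0       # ms, synaptic, excitatory units
    tau_syn_inh: float = 40.0       # ms, synaptic, inhibitory units
    tau_a: float = 400.0            # ms, spike-frequency adaptation
    tau_ref: float = 6.0            # ms, absolute refractory period
    R: float = 1e-2                 # GOhm
    phi_exc: float = 0.8            # excitatory fraction
    n_rec: int = 500
    psi: float = 1.6                # mV, adaptation threshold scale
    g: float = 1.5                  # target spectral radius of the init
    beta: float = 1000.0            # surrogate sharpness, per volt
    sigma2_m: float = 16.0          # membrane noise variance (mV^2/s)
    sigma2_base: float = 4e-6       # baseline-current walk variance (nA^2/s)
    i_base_scale: float = 0.041     # nA per unit of the truncated normal
    i_base_mu: float = 2.0
    i_base_sigma: float = 0.1       # sqrt(0.01)
    i_base_lo: float = 1.8
    i_base_hi: float = 2.4
    sfa_fraction: float = 0.25
    n_outputs: int = 2              # 2 for 2AFC, 4 for 4AFC

    def __post_init__(self) -> None:
        for name in ("dt", "tau_m", "tau_syn_exc", "tau_syn_inh", "tau_a", "tau_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.phi_exc < 1.0:
            raise ValueError("phi_exc must lie in (0, 1)")
        if self.v_th <= self.v_rest:
            raise ValueError("v_th must exceed v_rest")
        n_ref = self.tau_ref / self.dt
        if abs(n_ref - round(n_ref)) > 1e-9:
            raise ValueError("tau_ref must be an integer multiple of dt")
        n_exc = self.phi_exc * self.n_rec
        if abs(n_exc - round(n_exc)) > 1e-9:
            raise ValueError("phi_exc * n_rec must be an integer")
        if self.n_outputs not in (2, 4):
            raise ValueError("n_outputs must be 2 or 4")

    # ---- derived quantities -------------------------------------------------
    @property
    def n_exc(self) -> int:
        return round(self.phi_exc * self.n_rec)

    @property
    def n_inh(self) -> int:
        return self.n_rec - self.n_exc

    @property
    def n_ref_steps(self) -> int:
        return round(self.tau_ref / self.dt)

    @property
    def alpha_m(self) -> float:
        return math.exp(-self.dt / self.tau_m)

    @property
    def phi_a(self) -> float:
        """Per-step decay of the adaptation variable."""
        return math.exp(-self.dt / self.tau_a)

    @property
    def r_mv_per_na(self) -> float:
        """Membrane resistance as mV per nA (GOhm * 1e3)."""
        return self.R * 1e3

    @property
    def psi_mv(self) -> float:
        """Adaptation threshold scale in mV.

        ``psi`` is dimensionless in the normalized LIF convention (resting
        potential 0, threshold 1); on the mV scale the shift is psi times
        the rest-to-threshold gap, so a fully adapted unit (A = 1) raises
        its threshold by psi * 15 mV.
        """
        return self.psi * (self.v_th - self.v_rest)

    @property
    def noise_sd_m(self) -> float:
        """Per-step membrane noise SD in mV (Euler scaling: sigma * dt, dt in s).

        In this regime spontaneous firing comes from the heterogeneous
        baseline current (units whose I_base draw puts them above threshold
        fire tonically), which is what the truncated-normal I_base recipe is
        for; the white noise only jitters spike times.
        """
        return math.sqrt(self.sigma2_m) * self.dt * 1e-3

    @property
    def noise_sd_base(self) -> float:
        """Per-step baseline-current walk SD in nA."""
        return math.sqrt(self.sigma2_base) * self.dt * 1e-3


@dataclass
class EncoderParams:
    """LIF constants shared by the input encoder and the output decoder."""

    v_rest: float = 0.0     # mV
    v_th: float = 1.0       # mV
    R: float = 1.0          # Ohm (unit-free here: I is already in threshold units)
    tau_m: float = 5.0      # ms
    tau_syn: float = 20.0   # ms, decoder synaptic filter

    def __post_init__(self) -> None:
        if self.v_th <= self.v_rest:
            raise ValueError("v_th must exceed v_rest")
        if self.tau_m <= 0 or self.tau_syn <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class TrainingConfig:
    """Optimization settings for surrogate-gradient training."""

    eta: float = 3e-4               # Adam learning rate
    lam: float = 1e-9               # firing-rate regularization coefficient
    batch_size: int = 64
    batches_per_epoch: int = 200
    max_epochs: int = 60
    scored_steps: int = 5           # final steps entering the MSE
    reg_bin_steps: int = 5          # steps per regularizer bin (10 ms at dt=2)
    sfa_enabled: bool = True
    early_stop_acc: float = 0.99
    early_stop_patience: int = 3    # consecutive validation epochs
    val_trials: int = 64
    grad_clip: float = 5.0          # global-norm clip; 0 disables
    surrogate_gain: float = 0.3     # backward-only dampening of the pseudo-derivative
    restart_every: int = 20         # Adam warm-restart period in epochs; 0 disables
    consolidate: bool = False       # decay the step size once validation is high
    time_budget_s: float = 0.0      # wall-clock training cap; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.scored_steps < 1:
            raise ValueError("scored_steps must be >= 1")


def scaled_down_params(**overrides) -> SimulationParams:
    """128E + 32I configuration used for single-CPU experiments."""
    kw = dict(n_rec=160)
    kw.update(overrides)
    return SimulationParams(**kw)


def scaled_down_training(**overrides) -> TrainingConfig:
    """Reduced batch schedule paired with :func:`scaled_down_params`."""
    kw = dict(batch_size=32, batches_per_epoch=50, max_epochs=120)
    kw.update(overrides)
    return TrainingConfig(**kw)


def params_to_dict(p) -> dict:
    return {f.name: getattr(p, f.name) for f in fields(p)}


def params_from_dict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


def with_overrides(p, **kw):
    return replace(p, **kw)
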