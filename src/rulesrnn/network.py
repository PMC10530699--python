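"""Excitatory-inhibitory LIF recurrent network with adaptation.

Each of the ``n_rec`` units is a leaky integrate-and-fire neuron driven by a
low-pass-filtered synaptic current (exponential-Euler updates at dt = 2 ms),
a slowly drifting baseline current, and white membrane noise. A
fixed sign mask enforces Dale's principle: the first 80% of units make purely
excitatory synapses, the rest purely inhibitory, with no self-connections. A
random quarter of the units carries spike-frequency adaptation: each spike
increments a variable A in [0, 1] that decays with tau_a = 400 ms and raises
the unit's spiking threshold by psi * A.

A non-spiking leaky readout ("decoder") integrates the excitatory spikes
through W_out; its final voltages express the network's choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .params import EncoderParams, SimulationParams


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def glorot_init(fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform(-b, b) with b = sqrt(6 / (fan_in + fan_out)), shape (fan_out, fan_in)."""
    if fan_in < 1 or fan_out < 1:
        raise ValueError("fans must be >= 1")
    b = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-b, b, size=(fan_out, fan_in))


def spectral_rescale(w: np.ndarray, g: float) -> np.ndarray:
    """Scale a square matrix so its spectral radius equals ``g``."""
    w = np.asarray(w)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("matrix must be square")
    rho = np.max(np.abs(np.linalg.eigvals(w)))
    if rho == 0:
        raise ValueError("zero matrix has no spectral radius to rescale")
    return (g / rho) * w


@dataclass
class DaleMask:
    """Sign-and-normalization mask D with per-neuron constraint items.

    Excitatory columns carry d_exc = 1, inhibitory columns
    d_inh = -phi_exc / (1 - phi_exc); both are divided by
    d_norm = sqrt(sum d^2), and the diagonal is zero. The raw constraint
    items sum to zero, balancing excitation and inhibition.
    """

    D: np.ndarray
    n_exc: int
    d_exc: float
    d_inh: float
    d_norm: float

    @property
    def n_rec(self) -> int:
        return self.D.shape[0]

    def constraint_sum(self) -> float:
        """Sum of per-neuron constraint items (0 by construction)."""
        n_inh = self.n_rec - self.n_exc
        return self.n_exc * self.d_exc + n_inh * self.d_inh


def build_dale_mask(n_rec: int, phi_exc: float) -> DaleMask:
    if not 0.0 < phi_exc < 1.0:
        raise ValueError("phi_exc must lie in (0, 1)")
    n_exc_f = phi_exc * n_rec
    if abs(n_exc_f - round(n_exc_f)) > 1e-9:
        raise ValueError("phi_exc * n_rec must be an integer")
    n_exc = round(n_exc_f)
    n_inh = n_rec - n_exc
    d_exc = 1.0
    # phi/(1-phi) reduces to the integer ratio n_exc/n_inh; evaluate it that
    # way so the excitation/inhibition balance sum is exactly zero
    d_inh = -n_exc / n_inh
    d_norm = np.sqrt(n_exc * d_exc**2 + n_inh * d_inh**2)
    col = np.empty(n_rec)
    col[:n_exc] = d_exc / d_norm
    col[n_exc:] = d_inh / d_norm
    D = np.tile(col, (n_rec, 1))
    np.fill_diagonal(D, 0.0)
    return DaleMask(D=D, n_exc=n_exc, d_exc=d_exc, d_inh=d_inh, d_norm=d_norm)


@dataclass
class NetworkWeights:
    """All trainable weights plus fixed masks and the baseline current."""

    M_rec: np.ndarray          # (N, N) nonnegative magnitudes
    dale: DaleMask
    W_cue: np.ndarray          # (N, 1)
    W_sen: np.ndarray          # (N, 4)
    W_out: np.ndarray          # (n_outputs, n_exc)
    sfa_mask: np.ndarray       # (N,) float 0/1
    i_base0: np.ndarray        # (N,) nA, fixed across trials

    @property
    def n_rec(self) -> int:
        return self.M_rec.shape[0]

    @property
    def n_exc(self) -> int:
        return self.dale.n_exc

    def effective_rec(self) -> np.ndarray:
        """Signed recurrent matrix W_rec = M_rec (elementwise*) D."""
        return self.M_rec * self.dale.D

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            M_rec=self.M_rec.copy(),
            dale=DaleMask(
                D=self.dale.D.copy(),
                n_exc=self.dale.n_exc,
                d_exc=self.dale.d_exc,
                d_inh=self.dale.d_inh,
                d_norm=self.dale.d_norm,
            ),
            W_cue=self.W_cue.copy(),
            W_sen=self.W_sen.copy(),
            W_out=self.W_out.copy(),
            sfa_mask=self.sfa_mask.copy(),
            i_base0=self.i_base0.copy(),
        )


def _truncated_normal(params: SimulationParams, size: int, rng) -> np.ndarray:
    a = (params.i_base_lo - params.i_base_mu) / params.i_base_sigma
    b = (params.i_base_hi - params.i_base_mu) / params.i_base_sigma
    x = stats.truncnorm.rvs(
        a, b, loc=params.i_base_mu, scale=params.i_base_sigma,
        size=size, random_state=rng,
    )
    return params.i_base_scale * x


def init_network(params: SimulationParams, rng: np.random.Generator) -> NetworkWeights:
    """Glorot-initialize all weights; rescale the recurrent matrix to spectral
    radius ``g`` before taking magnitudes; draw the SFA assignment and the
    per-unit baseline currents (truncated normal, fixed across trials)."""
    n = params.n_rec
    dale = build_dale_mask(n, params.phi_exc)
    w = glorot_init(n, n, rng)
    M = np.abs(spectral_rescale(w, params.g))
    # combined 5-channel input matrix, then split cue/sensory columns
    w_in = glorot_init(5, n, rng)
    W_cue = w_in[:, :1].copy()
    W_sen = w_in[:, 1:].copy()
    W_out = glorot_init(dale.n_exc, params.n_outputs, rng)
    sfa_idx = rng.choice(n, size=int(params.sfa_fraction * n), replace=False)
    sfa_mask = np.zeros(n)
    sfa_mask[sfa_idx] = 1.0
    i_base0 = _truncated_normal(params, n, rng)
    return NetworkWeights(
        M_rec=M, dale=dale, W_cue=W_cue, W_sen=W_sen, W_out=W_out,
        sfa_mask=sfa_mask, i_base0=i_base0,
    )


@dataclass
class NetworkState:
    """Per-unit dynamic state for a batch of trials (arrays are (N, B))."""

    V: np.ndarray
    I: np.ndarray
    A: np.ndarray
    refrac: np.ndarray     # integer countdown steps
    I_base: np.ndarray


def init_state(
    params: SimulationParams,
    weights: NetworkWeights,
    batch: int,
    rng: np.random.Generator,
) -> NetworkState:
    """Fresh per-trial state: V ~ U(v_rest, v_th), everything else quiescent;
    the baseline current is the network's fixed draw."""
    n = params.n_rec
    return NetworkState(
        V=rng.uniform(params.v_rest, params.v_th, size=(n, batch)),
        I=np.zeros((n, batch)),
        A=np.zeros((n, batch)),
        refrac=np.zeros((n, batch), dtype=np.int64),
        I_base=np.tile(weights.i_base0[:, None], (1, batch)),
    )


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class ForwardTraces:
    """Per-step records needed by the backward pass (all (T, N, B) float32)."""

    S: np.ndarray            # spikes (soft values in soft mode)
    sg: np.ndarray           # surrogate derivative at (V_pre - V_th_eff)
    reset_carry: np.ndarray  # dV_post/dV_pre
    elig: np.ndarray         # dV_pre/d(anything upstream) gate
    in_spikes: np.ndarray    # (B, 5, T) inputs as given
    Id: np.ndarray           # decoder synaptic current (T, n_out, B)


@dataclass
class SimResult:
    rasters: np.ndarray          # (B, N, T) uint8 (float in soft mode)
    decoder_V: np.ndarray        # (B, n_out, T)
    currents: Optional[np.ndarray]  # (B, N, T) float32 synaptic currents
    traces: Optional[ForwardTraces]


def superspike_surrogate(v: np.ndarray, v_th_eff: np.ndarray | float, beta: float) -> np.ndarray:
    """Fast-sigmoid pseudo-derivative 1 / (1 + beta * |V - V_th|)^2.

    ``beta`` follows the volt-scaled convention: voltages here are in mV, so
    the distance is converted to volts before applying beta (beta = 1000/V
    gives a ~1 mV half-width).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    dv = np.abs(np.asarray(v) - v_th_eff) * 1e-3
    return 1.0 / (1.0 + beta * dv) ** 2


def _fast_sigmoid(x_mv: np.ndarray, beta: float) -> np.ndarray:
    """Fast sigmoid sigma(u) = u / (1 + |u|), u = beta * (x in volts).

    At the default beta = 1000/V the derivative of this map with respect to x
    in mV is exactly :func:`superspike_surrogate`, which is what makes the
    soft forward model an oracle for the backward pass.
    """
    u = x_mv * 1e-3 * beta
    return u / (1.0 + np.abs(u))


def simulate_batch(
    input_spikes: np.ndarray,
    weights: NetworkWeights,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    enc: EncoderParams = EncoderParams(),
    noise: bool = True,
    record_currents: bool = False,
    record_traces: bool = False,
    soft: bool = False,
    state: Optional[NetworkState] = None,
) -> SimResult:
    """Roll the network over a batch of input spike trains.

    ``input_spikes`` is (B, 5, T). With ``soft=True`` the hard threshold,
    reset, refractory period and noise are all replaced by the differentiable
    fast-sigmoid relaxation; this mode exists so the backward pass can be
    validated against finite differences of an everywhere-smooth model.
    """
    input_spikes = np.asarray(input_spikes)
    if input_spikes.ndim != 3 or input_spikes.shape[1] != 5:
        raise ValueError("input_spikes must be (batch, 5, n_step)")
    B, _, T = input_spikes.shape
    n = params.n_rec
    if weights.n_rec != n:
        raise ValueError("weights/params size mismatch")
    if rng is None:
        rng = np.random.default_rng(0)

    alpha_s = np.empty(n)
    alpha_s[: weights.n_exc] = np.exp(-params.dt / params.tau_syn_exc)
    alpha_s[weights.n_exc:] = np.exp(-params.dt / params.tau_syn_inh)
    W_eff = weights.effective_rec()
    W_in = np.concatenate([weights.W_cue, weights.W_sen], axis=1)   # (N, 5)
    W_out = weights.W_out
    n_out = W_out.shape[0]
    a_dm = np.exp(-params.dt / enc.tau_m)
    a_ds = np.exp(-params.dt / enc.tau_syn)

    if state is None:
        state = init_state(params, weights, B, rng)
    inp = np.ascontiguousarray(np.moveaxis(input_spikes, 0, 2)).astype(float)  # (5,T,B)

    if soft:
        out = _simulate_soft(inp, state, weights, params, enc, alpha_s,
                             a_dm, a_ds, record_currents)
        S_t, sg_t, carry_t, elig_t, dec_t, Id_t, cur_t = out
        rasters = S_t
    else:
        from ._kernels import forward_hard

        # the compiled path runs in float32: traces and matmuls at half the
        # memory traffic, with scalar arithmetic still in double
        f32 = np.float32
        use_noise = bool(noise)
        if use_noise:
            noise_m = rng.standard_normal((T, n, B), dtype=f32)
            noise_b = rng.standard_normal((T, n, B), dtype=f32)
        else:
            noise_m = np.zeros((1, 1, 1), dtype=f32)
            noise_b = noise_m
        S_t, sg_t, carry_t, elig_t, dec_t, Id_t, cur_t = forward_hard(
            np.ascontiguousarray(inp, dtype=f32),
            np.ascontiguousarray(W_eff, dtype=f32),
            np.ascontiguousarray(W_in, dtype=f32),
            np.ascontiguousarray(W_out, dtype=f32),
            weights.n_exc,
            params.alpha_m, alpha_s, params.phi_a, params.r_mv_per_na,
            params.v_rest, params.v_th, params.psi_mv, params.beta,
            weights.sfa_mask.astype(float), params.n_ref_steps,
            a_dm, a_ds, enc.R,
            np.ascontiguousarray(state.V, dtype=f32),
            np.ascontiguousarray(state.I_base, dtype=f32),
            params.noise_sd_m, params.noise_sd_base, noise_m, noise_b,
            use_noise, record_currents,
        )
        rasters = S_t

    traces = None
    if record_traces:
        traces = ForwardTraces(
            S=S_t, sg=sg_t, reset_carry=carry_t, elig=elig_t,
            in_spikes=input_spikes, Id=Id_t,
        )
    return SimResult(
        rasters=np.ascontiguousarray(
            np.transpose(rasters, (2, 1, 0))
        ).astype(float if soft else np.uint8),
        decoder_V=np.ascontiguousarray(np.transpose(dec_t, (2, 1, 0))),
        currents=(
            np.ascontiguousarray(np.transpose(cur_t, (2, 1, 0)))
            if record_currents else None
        ),
        traces=traces,
    )


def _simulate_soft(inp, state, weights, params, enc, alpha_s, a_dm, a_ds,
                   record_currents):
    """Differentiable relaxed forward: fast-sigmoid spikes, no reset, no
    refractory period, no noise. Used by the gradient-consistency oracle."""
    _, T, B = inp.shape
    n = params.n_rec
    n_out = weights.W_out.shape[0]
    alpha_m = params.alpha_m
    phi_a = params.phi_a
    r_eff = params.r_mv_per_na
    sfa = weights.sfa_mask[:, None]
    W_eff = weights.effective_rec()
    W_in = np.concatenate([weights.W_cue, weights.W_sen], axis=1)
    als = alpha_s[:, None]

    V = state.V.astype(float).copy()
    I = np.zeros((n, B))
    A = np.zeros((n, B))
    I_base = state.I_base.astype(float)
    S_prev = np.zeros((n, B))
    Vd = np.zeros((n_out, B))
    Id = np.zeros((n_out, B))

    S_t = np.empty((T, n, B))
    sg_t = np.empty((T, n, B))
    ones = np.ones((T, n, B))
    dec_t = np.empty((T, n_out, B))
    Id_t = np.empty((T, n_out, B))
    cur_t = np.empty((T, n, B)) if record_currents else np.empty((1, 1, 1))

    for t in range(T):
        I = als * I + W_eff @ S_prev + W_in @ inp[:, t, :] + I_base
        V_pre = params.v_rest + alpha_m * (V - params.v_rest) \
            + (1.0 - alpha_m) * r_eff * I
        A = phi_a * A + (1.0 - phi_a) * S_prev
        V_th_eff = params.v_th + params.psi_mv * (A * sfa)
        S = _fast_sigmoid(V_pre - V_th_eff, params.beta)
        V = V_pre
        Id = a_ds * Id + weights.W_out @ S[: weights.n_exc]
        Vd = a_dm * Vd + (1.0 - a_dm) * enc.R * Id
        S_t[t] = S
        sg_t[t] = superspike_surrogate(V_pre, V_th_eff, params.beta)
        dec_t[t] = Vd
        Id_t[t] = Id
        if record_currents:
            cur_t[t] = I
        S_prev = S
    return S_t, sg_t, ones, ones, dec_t, Id_t, cur_t


def srnn_step(
    state: NetworkState,
    input_spikes_t: np.ndarray,
    weights: NetworkWeights,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    noise: bool = False,
) -> tuple:
    """Advance the network one 2-ms step; returns (new_state, spikes).

    ``input_spikes_t`` is (5,) or (5, B). Update order: synaptic-current
    decay + spike accumulation + baseline inflow; membrane update with noise;
    adaptation and effective threshold; spike emission; reset and refractory
    countdown; baseline random walk. State arrays are (N, B). The batched
    :func:`simulate_batch` loop applies exactly these updates.
    """
    n = params.n_rec
    inp = np.atleast_2d(np.asarray(input_spikes_t, dtype=float))
    if inp.shape[0] != 5:
        inp = inp.T
    B = state.V.shape[1]
    if not np.all(np.isfinite(state.V)) or not np.all(np.isfinite(state.I)):
        raise FloatingPointError("non-finite network state")
    alpha_s = np.empty((n, 1))
    alpha_s[: weights.n_exc] = np.exp(-params.dt / params.tau_syn_exc)
    alpha_s[weights.n_exc:] = np.exp(-params.dt / params.tau_syn_inh)
    W_in = np.concatenate([weights.W_cue, weights.W_sen], axis=1)

    S_prev = getattr(state, "_S_prev", np.zeros((n, B)))
    I = alpha_s * state.I + weights.effective_rec() @ S_prev + W_in @ inp + state.I_base
    I_base = state.I_base.copy()
    if noise:
        I_base += rng.normal(0.0, params.noise_sd_base, size=(n, B))
    elig = state.refrac == 0
    V_pre = params.v_rest + params.alpha_m * (state.V - params.v_rest) \
        + (1.0 - params.alpha_m) * params.r_mv_per_na * I
    if noise:
        V_pre = V_pre + rng.normal(0.0, params.noise_sd_m, size=(n, B))
    V_pre = np.where(elig, V_pre, params.v_rest)
    A = params.phi_a * state.A + (1.0 - params.phi_a) * S_prev
    V_th_eff = params.v_th + params.psi_mv * A * weights.sfa_mask[:, None]
    S = ((V_pre >= V_th_eff) & elig).astype(float)
    V = np.where(S > 0, params.v_rest, V_pre)
    refrac = np.where(S > 0, params.n_ref_steps, np.maximum(state.refrac - 1, 0))
    new = NetworkState(V=V, I=I, A=A, refrac=refrac, I_base=I_base)
    new._S_prev = S
    return new, S


# --------------------------------------------------------------------------
# single-trial convenience and decisions
# --------------------------------------------------------------------------

@dataclass
class TrialRecord:
    raster: np.ndarray           # (N, T)
    decoder_V: np.ndarray        # (n_out, T)
    currents: Optional[np.ndarray]
    spec: object = None


@dataclass
class Decision:
    index: int
    choice: str          # "L"/"R" for 2AFC; port name for 4AFC
    tie: bool = False


def run_trial(
    input_spikes: np.ndarray,
    weights: NetworkWeights,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    record_currents: bool = True,
    noise: bool = True,
    spec=None,
) -> TrialRecord:
    res = simulate_batch(
        input_spikes[None], weights, params, rng=rng,
        noise=noise, record_currents=record_currents,
    )
    return TrialRecord(
        raster=res.rasters[0],
        decoder_V=res.decoder_V[0],
        currents=res.currents[0] if record_currents else None,
        spec=spec,
    )


_PORTS_4AFC = ("vision_L", "vision_R", "audition_L", "audition_R")


def decide(record: TrialRecord) -> Decision:
    """Choice = argmax of the decoder voltages at the final step.

    For the 2-output network, output index 1 codes the left choice and index 0
    the right choice ((0,1) = left target, (1,0) = right). For four outputs a
    softmax-argmax over the ports is used. Exact ties resolve to output 0 and
    are flagged.
    """
    v = record.decoder_V[:, -1]
    return decide_from_voltages(v)


def decide_from_voltages(v: np.ndarray) -> Decision:
    v = np.asarray(v, dtype=np.float64)
    if v.shape[0] == 2:
        tie = v[0] == v[1]
        idx = 0 if tie else int(np.argmax(v))
        return Decision(index=idx, choice="R" if idx == 0 else "L", tie=bool(tie))
    p = np.exp(v - np.max(v))
    p /= p.sum()
    idx = int(np.argmax(p))
    tie = bool(np.sum(p == p[idx]) > 1)
    if tie:
        idx = int(np.flatnonzero(p == p[idx])[0])
    return Decision(index=idx, choice=_PORTS_4AFC[idx], tie=tie)
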