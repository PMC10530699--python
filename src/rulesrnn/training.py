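"""Surrogate-gradient training of the recurrent spiking network.

The forward pass uses hard spike thresholds; the backward pass unrolls the
exact discrete dynamics (backpropagation through time) and substitutes the
SuperSpike fast-sigmoid pseudo-derivative for the undefined derivative of the
Heaviside threshold. Gradients flow through the membrane-potential, synaptic
-current and adaptation chains; the hard reset and refractory gating are
treated as non-differentiable constants of the forward trajectory. All
weights (recurrent magnitudes, cue/sensory input weights, readout) are
updated with Adam, and the recurrent magnitudes are clipped at zero after
every step so the Dale sign pattern is preserved exactly.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats as sps

from .network import (
    NetworkWeights,
    SimResult,
    decide_from_voltages,
    simulate_batch,
    superspike_surrogate,
)
from .params import EncoderParams, SimulationParams, TrainingConfig
from .task import TrialBatch, make_batch


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def mse_loss(decoder_V: np.ndarray, y: np.ndarray, scored_steps: int = 5) -> float:
    """Readout loss: 1/(2 * scored * B) * sum of squared residuals over the
    final ``scored_steps`` steps, both outputs, all trials.

    ``decoder_V`` is (B, n_out, T), ``y`` is (B, n_out).
    """
    if decoder_V.shape[2] < scored_steps:
        raise ValueError("decoder trace shorter than the scored window")
    v = decoder_V[:, :, -scored_steps:]
    resid = v - y[:, :, None]
    return float(np.sum(resid**2) / (2.0 * scored_steps * decoder_V.shape[0]))


def fr_regularizer(
    rasters: np.ndarray, reg_bin_steps: int = 5, dt_ms: float = 2.0
) -> float:
    """Sum over bins of the squared population-and-batch mean firing rate.

    ``rasters`` is (B, N, T); rates are in Hz (spikes per bin / bin length).
    With the default 10-ms bins an 800-ms trial yields N_bin = 80.
    """
    B, N, T = rasters.shape
    if T % reg_bin_steps != 0:
        raise ValueError("n_step must be divisible by the regularizer bin")
    n_bin = T // reg_bin_steps
    bin_s = reg_bin_steps * dt_ms * 1e-3
    counts = rasters.reshape(B, N, n_bin, reg_bin_steps).sum(axis=3)
    mean_rate = counts.mean(axis=(0, 1)) / bin_s        # (n_bin,) Hz
    return float(np.sum(mean_rate**2))


@dataclass
class LossBreakdown:
    l_mse: float
    l_fr: float
    lam: float

    @property
    def l_total(self) -> float:
        return self.l_mse + self.lam * self.l_fr


# --------------------------------------------------------------------------
# backward pass
# --------------------------------------------------------------------------

def backward_pass(
    res: SimResult,
    targets: np.ndarray,
    weights: NetworkWeights,
    params: SimulationParams,
    tcfg: TrainingConfig,
    enc: EncoderParams = EncoderParams(),
) -> dict:
    """Reverse-mode gradients of L = L_mse + lam * L_fr wrt all weights.

    Requires a forward run with ``record_traces=True``. Works for both the
    hard-threshold forward (surrogate in place of the threshold derivative)
    and the soft relaxed forward (where it is the exact gradient).
    """
    from ._kernels import backward_core

    tr = res.traces
    if tr is None:
        raise ValueError("forward must be run with record_traces=True")
    S, sg, carry, elig = tr.S, tr.sg, tr.reset_carry, tr.elig
    T, n, B = S.shape
    n_exc = weights.n_exc

    alpha_s = np.empty(n)
    alpha_s[:n_exc] = np.exp(-params.dt / params.tau_syn_exc)
    alpha_s[n_exc:] = np.exp(-params.dt / params.tau_syn_inh)
    psi_sfa = params.psi_mv * weights.sfa_mask.astype(float)
    a_dm = np.exp(-params.dt / enc.tau_m)
    a_ds = np.exp(-params.dt / enc.tau_syn)

    dtype = S.dtype
    W_eff_T = np.ascontiguousarray(weights.effective_rec().T, dtype=dtype)
    W_out = np.ascontiguousarray(weights.W_out, dtype=dtype)
    W_out_T = np.ascontiguousarray(W_out.T)

    dec_V = np.ascontiguousarray(
        np.transpose(res.decoder_V, (2, 1, 0)), dtype=dtype)               # (T,n_out,B)
    inp = np.ascontiguousarray(
        np.moveaxis(tr.in_spikes, 0, 2), dtype=dtype)                      # (5,T,B)
    y = np.ascontiguousarray(np.asarray(targets).T, dtype=dtype)           # (n_out,B)

    # firing-rate regularizer: constant dL/dS within each 10-ms bin
    lam = tcfg.lam
    nb_steps = tcfg.reg_bin_steps
    bin_s = nb_steps * params.dt * 1e-3
    n_bin = T // nb_steps
    counts = S.reshape(n_bin, nb_steps, n, B).sum(axis=1)
    m_b = counts.mean(axis=(1, 2)) / bin_s                        # (n_bin,) Hz
    g_reg_bin = lam * 2.0 * m_b / (n * B * bin_s)

    gM_eff, gW_in, gW_out = backward_core(
        S, sg, carry, elig, inp, dec_V, y,
        W_eff_T, W_out, W_out_T, n_exc,
        params.alpha_m, alpha_s, params.phi_a, params.r_mv_per_na, psi_sfa,
        a_dm, a_ds, enc.R, tcfg.scored_steps, g_reg_bin, nb_steps,
        tcfg.surrogate_gain,
    )
    gM = gM_eff.astype(np.float64) * weights.dale.D
    return {
        "M_rec": gM,
        "W_cue": gW_in[:, :1].astype(np.float64),
        "W_sen": gW_in[:, 1:].astype(np.float64),
        "W_out": gW_out.astype(np.float64),
    }


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

class Adam:
    """Canonical Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, shapes: dict, eta: float, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8):
        self.eta, self.b1, self.b2, self.eps = eta, b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, grads: dict) -> dict:
        self.t += 1
        updates = {}
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            updates[k] = -self.eta * mh / (np.sqrt(vh) + self.eps)
        return updates


def dale_project(weights: NetworkWeights) -> None:
    """Clip recurrent magnitudes at zero in place (idempotent)."""
    np.maximum(weights.M_rec, 0.0, out=weights.M_rec)


def clip_global_norm(grads: dict, max_norm: float) -> dict:
    if max_norm <= 0:
        return grads
    total = math.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        grads = {k: g * scale for k, g in grads.items()}
    return grads


# --------------------------------------------------------------------------
# training / evaluation loops
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    weights: NetworkWeights       # best-by-validation weights
    history: list                 # per-epoch dicts
    converged: bool
    epochs_run: int
    final_weights: Optional[NetworkWeights] = None
    best_val: float = 0.0


def default_task_source(params: SimulationParams, **task_kwargs) -> Callable:
    def source(n: int, seed: int) -> TrialBatch:
        return make_batch(n, params, base_seed=seed, balance=True, **task_kwargs)
    return source


def train(
    weights: NetworkWeights,
    params: SimulationParams,
    tcfg: TrainingConfig,
    task_source: Optional[Callable] = None,
    epoch_callback: Optional[Callable] = None,
    verbose: bool = False,
) -> TrainResult:
    """Adam/BPTT training loop with per-epoch validation and early stopping.

    ``task_source(n, seed)`` must return a :class:`TrialBatch`; the default
    draws balanced clean-cue trials. Training aborts (keeping the last good
    weights) if the loss turns non-finite.
    """
    if task_source is None:
        task_source = default_task_source(params)
    if not tcfg.sfa_enabled:
        weights = weights.copy()
        weights.sfa_mask = np.zeros_like(weights.sfa_mask)

    opt = Adam(
        {k: getattr(weights, k).shape for k in ("M_rec", "W_cue", "W_sen", "W_out")},
        eta=tcfg.eta,
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=tcfg.seed))
    history = []
    good = weights.copy()
    best = weights.copy()
    best_val = -1.0
    streak = 0
    converged = False
    epochs_run = 0

    eta_now = tcfg.eta
    decay_stage = 0
    t_start = time.monotonic()
    for epoch in range(tcfg.max_epochs):
        if tcfg.time_budget_s and time.monotonic() - t_start > tcfg.time_budget_s:
            break
        if tcfg.restart_every and epoch and epoch % tcfg.restart_every == 0 \
                and decay_stage == 0:
            # Adam warm restart: clearing the moment estimates periodically
            # kicks the optimizer out of the long side-only plateau that
            # precedes rule learning on this task
            opt = Adam(
                {k: getattr(weights, k).shape
                 for k in ("M_rec", "W_cue", "W_sen", "W_out")},
                eta=eta_now,
            )
        ep_mse, ep_fr = [], []
        for b in range(tcfg.batches_per_epoch):
            seed = int((tcfg.seed * 1_000_003 + epoch * 1009 + b) % (2**31))
            batch = task_source(tcfg.batch_size, seed)
            spikes = np.stack(batch.spikes)
            res = simulate_batch(
                spikes, weights, params, rng=rng,
                record_traces=True, noise=True,
            )
            l_mse = mse_loss(res.decoder_V, batch.targets, tcfg.scored_steps)
            l_fr = fr_regularizer(res.rasters, tcfg.reg_bin_steps, params.dt)
            if not np.isfinite(l_mse):
                return TrainResult(best if best_val >= 0 else good, history,
                                   False, epochs_run, final_weights=good,
                                   best_val=max(best_val, 0.0))
            grads = backward_pass(res, batch.targets, weights, params, tcfg)
            grads = clip_global_norm(grads, tcfg.grad_clip)
            updates = opt.step(grads)
            for k, u in updates.items():
                getattr(weights, k).__iadd__(u)
            dale_project(weights)
            ep_mse.append(l_mse)
            ep_fr.append(l_fr)
        good = weights.copy()

        val_seed = int((tcfg.seed * 7_919 + 31 * epoch + 2**20) % (2**31))
        ev = evaluate(weights, params, tcfg.val_trials, seed=val_seed,
                      task_source=task_source)
        epochs_run = epoch + 1
        rec = {
            "epoch": epoch,
            "l_mse": float(np.mean(ep_mse)),
            "l_fr": float(np.mean(ep_fr)),
            "l_total": float(np.mean(ep_mse) + tcfg.lam * np.mean(ep_fr)),
            "val_accuracy": ev["accuracy"],
        }
        history.append(rec)
        if verbose:
            print(f"epoch {epoch}: L_mse={rec['l_mse']:.4f} "
                  f"val_acc={rec['val_accuracy']:.3f}", flush=True)
        if epoch_callback is not None:
            epoch_callback(epoch, weights, rec)
        if ev["accuracy"] > best_val:
            best_val = ev["accuracy"]
            best = weights.copy()
        if tcfg.consolidate:
            # once rule learning shows, shrink the step size so the freshly
            # formed attractor is refined rather than overshot
            if decay_stage == 0 and ev["accuracy"] >= 0.90:
                eta_now = tcfg.eta * 0.3
                opt.eta = eta_now
                decay_stage = 1
            elif decay_stage == 1 and ev["accuracy"] >= 0.97:
                eta_now = tcfg.eta * 0.1
                opt.eta = eta_now
                decay_stage = 2
        streak = streak + 1 if ev["accuracy"] >= tcfg.early_stop_acc else 0
        if streak >= tcfg.early_stop_patience:
            converged = True
            break
    return TrainResult(best, history, converged, epochs_run,
                       final_weights=weights, best_val=best_val)


def _correct_index(spec, n_outputs: int) -> int:
    if n_outputs == 2:
        return 1 if spec.correct_choice == "L" else 0
    return {(1, "L"): 0, (1, "R"): 1, (2, "L"): 2, (2, "R"): 3}[
        (spec.rule, spec.correct_choice)
    ]


def evaluate(
    weights: NetworkWeights,
    params: SimulationParams,
    n_trials: int,
    seed: int = 0,
    task_source: Optional[Callable] = None,
    batch_size: int = 64,
    noise: bool = True,
) -> dict:
    """Fraction of trials decided correctly, with a 95% binomial CI and a
    per-rule / per-congruency breakdown."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if task_source is None:
        task_source = default_task_source(params)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed) + 2**32))
    batch = task_source(n_trials, int(seed))
    correct = np.zeros(n_trials, dtype=bool)
    for lo in range(0, n_trials, batch_size):
        hi = min(lo + batch_size, n_trials)
        spikes = np.stack(batch.spikes[lo:hi])
        res = simulate_batch(spikes, weights, params, rng=rng, noise=noise)
        for i in range(hi - lo):
            d = decide_from_voltages(res.decoder_V[i, :, -1])
            correct[lo + i] = d.index == _correct_index(
                batch.specs[lo + i], params.n_outputs
            )
    k = int(correct.sum())
    ci = sps.binomtest(k, n_trials).proportion_ci(0.95)
    by = {}
    for key, mask in [
        ("rule1", np.array([s.rule == 1 for s in batch.specs])),
        ("rule2", np.array([s.rule == 2 for s in batch.specs])),
        ("congruent", np.array([s.congruent for s in batch.specs])),
        ("incongruent", np.array([not s.congruent for s in batch.specs])),
    ]:
        by[key] = float(correct[mask].mean()) if mask.any() else float("nan")
    return {
        "accuracy": k / n_trials,
        "n": n_trials,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "by_condition": by,
    }
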