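"""Test-time manipulations of a trained network.

Psychometric curves over cue ambiguity, delay elongation, recurrent-weight
sparsification, cell-type-specific block scaling (W_EE / W_EI / W_IE / W_II),
and noise / distractor sweeps. Every manipulation is a pure function of
(weights, specification, seed): reapplying it reproduces bit-identical
modified weights, and none of them can violate the Dale sign pattern because
they only touch the nonnegative magnitude matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import NetworkWeights
from .params import SimulationParams
from .task import DEFAULT_DELAY_MS, Distractor
from .training import default_task_source, evaluate


# --------------------------------------------------------------------------
# weight modifications
# --------------------------------------------------------------------------

def sparsify(weights: NetworkWeights, fraction: float, rng: np.random.Generator) -> NetworkWeights:
    """Zero an exact ``fraction`` of the currently nonzero recurrent magnitudes."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    out = weights.copy()
    nz = np.flatnonzero((out.M_rec > 0) & (out.dale.D != 0))
    k = int(np.floor(fraction * nz.size))
    if k > 0:
        drop = rng.choice(nz, size=k, replace=False)
        out.M_rec.flat[drop] = 0.0
    return out


_BLOCKS = ("EE", "EI", "IE", "II")


def scale_block(weights: NetworkWeights, block: str, factor: float) -> NetworkWeights:
    """Multiply one cell-type block of the recurrent magnitudes by ``factor``.

    Blocks are named target<-source: "EE" excitatory-to-excitatory, "EI"
    inhibitory-to-excitatory (I source, E target), "IE" excitatory-to-
    inhibitory, "II" inhibitory-to-inhibitory.
    """
    if block not in _BLOCKS:
        raise ValueError(f"unknown block {block!r}; expected one of {_BLOCKS}")
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = weights.copy()
    ne = out.n_exc
    rows = slice(0, ne) if block in ("EE", "EI") else slice(ne, None)
    cols = slice(0, ne) if block in ("EE", "IE") else slice(ne, None)
    out.M_rec[rows, cols] *= factor
    return out


# --------------------------------------------------------------------------
# sweeps
# --------------------------------------------------------------------------

def _tidy(rows: list) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["condition", "value", "n", "accuracy",
                                       "ci_lo", "ci_hi", "seed"])


def sweep_mixture(
    weights: NetworkWeights,
    params: SimulationParams,
    grid: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Psychometric curve over cue purity (fraction of the trial's own rule).

    Measured on incongruent trials only: congruent trials are solvable
    without the rule and would floor the curve at ~0.75; on incongruent
    trials a fully ambiguous cue (q = 0.5, identical for both labels) gives
    exactly chance.
    """
    rows = []
    for q in grid:
        src = default_task_source(params, own_rule_fraction=float(q),
                                  sides="incongruent")
        ev = evaluate(weights, params, n_trials, seed=seed, task_source=src)
        rows.append(("mixture_q", float(q), n_trials, ev["accuracy"],
                     ev["ci_low"], ev["ci_high"], seed))
    return _tidy(rows)


def sweep_delay(
    weights: NetworkWeights,
    params: SimulationParams,
    delays: Sequence[float] = (400.0, 500.0, 600.0, 700.0, 800.0),
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy under test-time delay elongation (no retraining)."""
    rows = []
    for d in delays:
        src = default_task_source(params, delay_ms=float(d))
        ev = evaluate(weights, params, n_trials, seed=seed, task_source=src)
        rows.append(("delay_ms", float(d), n_trials, ev["accuracy"],
                     ev["ci_low"], ev["ci_high"], seed))
    return _tidy(rows)


def sweep_sparsity(
    weights: NetworkWeights,
    params: SimulationParams,
    fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.4),
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    rows = []
    for f in fractions:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed + 13))
        mod = sparsify(weights, float(f), rng)
        ev = evaluate(mod, params, n_trials, seed=seed)
        rows.append(("sparsity", float(f), n_trials, ev["accuracy"],
                     ev["ci_low"], ev["ci_high"], seed))
    return _tidy(rows)


def sweep_block_scale(
    weights: NetworkWeights,
    params: SimulationParams,
    block: str = "EE",
    factors: Sequence[float] = (0.5, 1.0, 2.0, 5.0),
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Scale one connectivity block and report accuracy plus E/I rates."""
    from .analysis import simulate_condition

    rows = []
    for f in factors:
        mod = scale_block(weights, block, float(f))
        ev = evaluate(mod, params, n_trials, seed=seed)
        rasters, _ = simulate_condition(mod, params, rule=1, n_trials=10,
                                        seed=seed + 1)
        ne = weights.n_exc
        e_rate = float(rasters[:, :ne].mean() / (params.dt * 1e-3))
        i_rate = float(rasters[:, ne:].mean() / (params.dt * 1e-3))
        rows.append({"condition": f"scale_{block}", "value": float(f),
                     "n": n_trials, "accuracy": ev["accuracy"],
                     "ci_lo": ev["ci_low"], "ci_hi": ev["ci_high"],
                     "seed": seed, "e_rate_hz": e_rate, "i_rate_hz": i_rate})
    return pd.DataFrame(rows)


def sweep_noise(
    weights: NetworkWeights,
    params: SimulationParams,
    noise_sds: Sequence[float] = (0.05, 0.2, 0.5, 1.0),
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy vs the SD of the background input noise during fixation/delay."""
    rows = []
    for sd in noise_sds:
        src = default_task_source(params, noise_sd=float(sd))
        ev = evaluate(weights, params, n_trials, seed=seed, task_source=src)
        rows.append(("noise_sd", float(sd), n_trials, ev["accuracy"],
                     ev["ci_low"], ev["ci_high"], seed))
    return _tidy(rows)


def sweep_distractor(
    weights: NetworkWeights,
    params: SimulationParams,
    onsets_ms: Sequence[float] = (0.0, 100.0, 200.0, 300.0),
    amplitude: float = 1.0,
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """50-ms pulse distractor on the cue channel across delay windows."""
    rows = []
    for onset in onsets_ms:
        d = None if amplitude == 0 else Distractor(onset_ms=float(onset),
                                                   amplitude=amplitude)
        src = default_task_source(params, distractor=d)
        ev = evaluate(weights, params, n_trials, seed=seed, task_source=src)
        rows.append(("distractor_onset_ms", float(onset), n_trials,
                     ev["accuracy"], ev["ci_low"], ev["ci_high"], seed))
    return _tidy(rows)
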