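"""Configuration, checkpoints and data export.

A run is fully determined by (config, seed): the YAML config mirrors the
simulation/encoder/training parameter tables plus a task preset, and a single
global seed fans out into named substreams (network init, trial generation,
simulation noise) so each module can be re-seeded independently. Checkpoints
are HDF5 files holding every weight matrix, mask and parameter set; loading
restores them bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .network import DaleMask, NetworkWeights, build_dale_mask
from .params import (
    EncoderParams,
    SimulationParams,
    TrainingConfig,
    params_from_dict,
    params_to_dict,
)

SCHEMA_VERSION = 1
_PRESETS = {"full", "scaled_down", "4afc"}


@dataclass
class RunConfig:
    sim: SimulationParams = field(default_factory=SimulationParams)
    encoder: EncoderParams = field(default_factory=EncoderParams)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    preset: str = "full"
    seed: int = 0

    def __post_init__(self):
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    def seed_for(self, stream: str) -> np.random.SeedSequence:
        """Named substream of the global seed (init / trials / noise / masks)."""
        key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "preset": self.preset,
            "seed": self.seed,
            "sim": params_to_dict(self.sim),
            "encoder": params_to_dict(self.encoder),
            "training": params_to_dict(self.training),
        }


def preset_config(name: str, seed: int = 0) -> RunConfig:
    from .params import scaled_down_params, scaled_down_training

    if name == "full":
        return RunConfig(seed=seed)
    if name == "scaled_down":
        return RunConfig(sim=scaled_down_params(),
                         training=scaled_down_training(),
                         preset="scaled_down", seed=seed)
    if name == "4afc":
        return RunConfig(sim=SimulationParams(n_rec=800, n_outputs=4),
                         preset="4afc", seed=seed)
    raise ValueError(f"unknown preset {name!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; missing sections fall back to defaults, unknown
    keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    preset = raw.pop("preset", "full")
    seed = raw.pop("seed", 0)
    base = preset_config(preset, seed=seed)
    sections = {"sim": (SimulationParams, base.sim),
                "encoder": (EncoderParams, base.encoder),
                "training": (TrainingConfig, base.training)}
    built = {}
    for name, (cls, default) in sections.items():
        d = params_to_dict(default)
        overrides = raw.pop(name, {}) or {}
        unknown = set(overrides) - set(d)
        if unknown:
            raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
        d.update(overrides)
        built[name] = params_from_dict(cls, d)
    if raw:
        raise ValueError(f"unknown top-level keys: {sorted(raw)}")
    return RunConfig(sim=built["sim"], encoder=built["encoder"],
                     training=built["training"], preset=preset, seed=seed)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(
    weights: NetworkWeights,
    cfg: RunConfig,
    path: str | Path,
    extra: dict | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config_json"] = json.dumps(cfg.to_dict(), sort_keys=True)
        g = f.create_group("weights")
        for name in ("M_rec", "W_cue", "W_sen", "W_out", "sfa_mask", "i_base0"):
            g.create_dataset(name, data=getattr(weights, name))
        if extra:
            f.attrs["extra_json"] = json.dumps(extra, sort_keys=True)


def load_checkpoint(path: str | Path) -> tuple:
    with h5py.File(path, "r") as f:
        if f.attrs["schema_version"] != SCHEMA_VERSION:
            raise ValueError("checkpoint schema version mismatch")
        cfg_d = json.loads(f.attrs["config_json"])
        cfg = load_config_dict(cfg_d)
        g = f["weights"]
        arrays = {k: g[k][()] for k in g}
    n = arrays["M_rec"].shape[0]
    if n != cfg.sim.n_rec:
        raise ValueError("checkpoint n_rec does not match its config")
    dale = build_dale_mask(n, cfg.sim.phi_exc)
    w = NetworkWeights(M_rec=arrays["M_rec"], dale=dale,
                       W_cue=arrays["W_cue"], W_sen=arrays["W_sen"],
                       W_out=arrays["W_out"], sfa_mask=arrays["sfa_mask"],
                       i_base0=arrays["i_base0"])
    return w, cfg


def load_config_dict(d: dict) -> RunConfig:
    d = dict(d)
    d.pop("schema_version", None)
    return RunConfig(
        sim=params_from_dict(SimulationParams, d["sim"]),
        encoder=params_from_dict(EncoderParams, d["encoder"]),
        training=params_from_dict(TrainingConfig, d["training"]),
        preset=d.get("preset", "full"),
        seed=d.get("seed", 0),
    )


# --------------------------------------------------------------------------
# exports
# --------------------------------------------------------------------------

def export_run(records: list, out_dir: str | Path, cfg: RunConfig | None = None,
               n_exc: int | None = None) -> dict:
    """Write spike events, decoder voltages and trial metadata for a list of
    :class:`~rulesrnn.network.TrialRecord`; returns the manifest.

    When ``n_exc`` is given (or derivable from the config) each spike event
    carries its unit class (E/I).
    """
    import pandas as pd

    if not records:
        raise ValueError("no records to export")
    if n_exc is None and cfg is not None:
        n_exc = cfg.sim.n_exc
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev_rows, dv_rows, meta = [], [], []
    for i, rec in enumerate(records):
        units, steps = np.nonzero(rec.raster)
        for u, t in zip(units, steps):
            cls = "" if n_exc is None else ("E" if u < n_exc else "I")
            ev_rows.append((i, int(u), float(t * 2.0), cls))
        for t in range(rec.decoder_V.shape[1]):
            dv_rows.append((i, float(t * 2.0), *map(float, rec.decoder_V[:, t])))
        spec = rec.spec
        meta.append({
            "trial_id": i,
            "rule": getattr(spec, "rule", None),
            "visual_side": getattr(spec, "visual_side", None),
            "auditory_side": getattr(spec, "auditory_side", None),
            "correct_choice": getattr(spec, "correct_choice", None),
            "n_spikes": int(rec.raster.sum()),
        })
    pd.DataFrame(
        ev_rows, columns=["trial_id", "unit_id", "time_ms", "unit_class"]
    ).to_csv(out / "spikes.csv", index=False)
    n_out = records[0].decoder_V.shape[0]
    cols = ["trial_id", "time_ms"] + [f"decoder_v{i}" for i in range(n_out)]
    pd.DataFrame(dv_rows, columns=cols).to_csv(out / "decoder.csv", index=False)
    manifest = {
        "n_trials": len(records),
        "trials": meta,
        "config_hash": config_hash(cfg) if cfg is not None else None,
    }
    (out / "trials.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
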