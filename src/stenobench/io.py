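"""Recording, config and result file round-tripping, fixtures and manifests.

A recording is stored as a plain CSV (``time_s, ch1..chN`` in mmHg, 17
significant digits so float64 round-trips bit-exactly) next to a YAML
sidecar ``<name>.meta.yaml`` holding sensor positions, sampling rate, flow
condition, seed, session/condition labels and scalar ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import (
    FlowCondition,
    GroundTruth,
    PhantomConfig,
    SensorArray,
    SensorRecording,
    fast_config,
    simulate_recording,
)

#: float format that round-trips IEEE doubles exactly through text.
FLOAT_FORMAT = "%.17g"


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".meta.yaml")


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(recording: SensorRecording, path) -> Path:
    """Write a recording as CSV plus YAML sidecar; returns the CSV path."""
    path = Path(path)
    n_ch = recording.sensor_array.n_channels
    header = "time_s," + ",".join(
        f"ch{i}" for i in recording.sensor_array.channel_ids
    )
    data = np.column_stack([recording.time_s, recording.pressures_mmhg])
    np.savetxt(path, data, fmt=FLOAT_FORMAT, delimiter=",",
               header=header, comments="")

    meta = {
        "positions_mm": list(recording.sensor_array.positions_mm),
        "channel_ids": list(recording.sensor_array.channel_ids),
        "sampling_rate_hz": float(recording.sampling_rate_hz),
        "mode": recording.condition.mode,
        "peak_flow_ml_s": float(recording.condition.peak_flow_ml_s),
        "heart_rate_bpm": (
            None if recording.condition.heart_rate_bpm is None
            else float(recording.condition.heart_rate_bpm)
        ),
        "n_channels": n_ch,
        "provenance": dict(recording.provenance),
    }
    if recording.ground_truth is not None:
        gt = recording.ground_truth
        meta["ground_truth"] = {
            "true_peak_drop_mmhg": float(gt.true_peak_drop_mmhg),
            "true_net_drop_mmhg": float(gt.true_net_drop_mmhg),
            "true_peak_instant_s": float(gt.true_peak_instant_s),
            "true_peak_location_mm": float(gt.true_peak_location_mm),
        }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_recording(path) -> SensorRecording:
    """Read a recording written by :func:`write_recording`.

    Validates the sidecar against the CSV: channel count must match the
    sensor positions and the time base must be strictly increasing.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {side}")
    with open(side) as fh:
        try:
            meta = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed sidecar {side}: {exc}") from exc
    if not isinstance(meta, dict):
        raise ValueError(f"malformed sidecar {side}: expected a mapping")
    for key in ("positions_mm", "sampling_rate_hz", "mode", "peak_flow_ml_s"):
        if key not in meta:
            raise ValueError(f"sidecar {side} lacks required field {key!r}")

    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be time_s")
    n_csv_channels = frame.shape[1] - 1
    n_meta_channels = len(meta["positions_mm"])
    if n_csv_channels != n_meta_channels:
        raise ValueError(
            f"{path}: {n_csv_channels} pressure channels in the CSV but "
            f"{n_meta_channels} sensor positions in the sidecar"
        )
    t = frame["time_s"].to_numpy()
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based line numbers
        raise ValueError(
            f"{path}: time not strictly increasing at data line "
            f"{int(bad[0]) + 2}"
        )

    array = SensorArray(
        positions_mm=tuple(meta["positions_mm"]),
        channel_ids=tuple(meta.get("channel_ids")
                          or range(1, n_meta_channels + 1)),
    )
    condition = FlowCondition(
        mode=meta["mode"],
        peak_flow_ml_s=meta["peak_flow_ml_s"],
        heart_rate_bpm=meta.get("heart_rate_bpm"),
    )
    truth = None
    if "ground_truth" in meta:
        truth = GroundTruth(**meta["ground_truth"])
    return SensorRecording(
        time_s=t,
        pressures_mmhg=frame.iloc[:, 1:].to_numpy(),
        sensor_array=array,
        condition=condition,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        ground_truth=truth,
        provenance=dict(meta.get("provenance", {})),
    )


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

def config_to_dict(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sensor_array"] = {
        "positions_mm": list(config.sensor_array.positions_mm),
        "channel_ids": list(config.sensor_array.channel_ids),
    }
    if d["channel_offsets_mmhg"] is not None:
        d["channel_offsets_mmhg"] = list(d["channel_offsets_mmhg"])
    return d


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if "sensor_array" in d and d["sensor_array"] is not None:
        sa = d["sensor_array"]
        if isinstance(sa, dict):
            d["sensor_array"] = SensorArray(
                positions_mm=tuple(sa["positions_mm"]),
                channel_ids=tuple(sa["channel_ids"]) if sa.get("channel_ids")
                else None,
            )
    if d.get("channel_offsets_mmhg") is not None:
        d["channel_offsets_mmhg"] = tuple(d["channel_offsets_mmhg"])
    unknown = set(d) - {f.name for f in dataclasses.fields(PhantomConfig)}
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return PhantomConfig(**d)


def load_config(path) -> PhantomConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: PhantomConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: PhantomConfig) -> str:
    """Stable SHA-256 of the fully resolved configuration."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_FIXTURE_SPECS = {
    # name: (config overrides, flow mode, peak flow)
    "clean": (
        dict(noise_broadband_sd_mmhg=0.0, turbulence_noise_amplitude_mmhg=0.0,
             pump_artifact_amplitude_mmhg=0.0, reflection_coefficient=0.0,
             rng_seed=101),
        "pulsatile", 250.0,
    ),
    "noisy": (dict(rng_seed=202), "pulsatile", 250.0),
    "reflected": (
        dict(noise_broadband_sd_mmhg=0.0, turbulence_noise_amplitude_mmhg=0.0,
             pump_artifact_amplitude_mmhg=0.0, reflection_coefficient=0.3,
             rng_seed=303),
        "pulsatile", 250.0,
    ),
    "constant": (dict(rng_seed=404), "constant", 250.0),
}


def make_fixture(name: str) -> SensorRecording:
    """Deterministic miniature recording (4 kHz, 4 cycles) for fast tests.

    Known names: "clean" (zero noise, no reflection), "noisy" (default
    noise), "reflected" (noise-free, reflection coefficient 0.3) and
    "constant" (constant-flow, default noise); all at 250 ml/s peak flow.
    """
    try:
        overrides, mode, flow = _FIXTURE_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURE_SPECS)}"
        ) from None
    config = fast_config(**overrides)
    condition = FlowCondition(mode=mode, peak_flow_ml_s=flow,
                              heart_rate_bpm=75.0)
    return simulate_recording(config, condition,
                              provenance={"fixture": name})


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path,
    command: str,
    params: dict,
    inputs: Optional[list] = None,
    outputs: Optional[list] = None,
    seed: Optional[int] = None,
) -> Path:
    """JSON manifest next to an output file, sufficient to re-run the
    command bit-identically (command, parameters, seed, config hash,
    input/output paths with output content hashes, package version)."""
    out_path = Path(out_path)
    manifest = {
        "command": command,
        "params": params,
        "seed": seed,
        "inputs": [str(p) for p in (inputs or [])],
        "outputs": {
            str(p): file_sha256(p) for p in (outputs or []) if Path(p).exists()
        },
        "package_version": __version__,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path
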