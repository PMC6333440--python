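"""On-disk formats: sweep-bundle directories, ventral-root CSV, YAML config.

A bundle directory holds ``metadata.json`` (pair/cell metadata, protocol,
modes, ground truth and simulator logs) plus one CSV per sweep with
columns ``time_ms, i_inj_pA, cell1_<unit>, cell2_<unit>``; the unit
suffix (mV/pA) names the recording mode.  All writers round floats
through ``repr``-exact formatting so read(write(x)) is lossless at
float64.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .model import (
    CURRENT_CLAMP,
    ChemSynParams,
    GapJunctionParams,
    NeuronParams,
    PairMeta,
    PairModelSpec,
    PulseTrainProtocol,
    SinusoidProtocol,
    StepFamilyProtocol,
    SweepBundle,
)
from .simulate import VentralRootRecording

_FLOAT_FMT = "%.17g"

_PROTO_CLASSES = {
    "pulse_train": PulseTrainProtocol,
    "step_family": StepFamilyProtocol,
    "sinusoid": SinusoidProtocol,
}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _spec_to_dict(spec: PairModelSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["chem_synapses"] = [dataclasses.asdict(s) for s in spec.chem_synapses]
    return d


def _spec_from_dict(d: dict) -> PairModelSpec:
    return PairModelSpec(
        neuron_1=NeuronParams(**d["neuron_1"]),
        neuron_2=NeuronParams(**d["neuron_2"]),
        gap=GapJunctionParams(**d["gap"]),
        chem_synapses=tuple(ChemSynParams(**s) for s in d["chem_synapses"]),
        noise_sd_mv=d["noise_sd_mv"], seed=d["seed"])


def _protocol_to_dict(proto) -> dict:
    d = dataclasses.asdict(proto)
    d["kind"] = proto.kind
    return d


def _protocol_from_dict(d: dict):
    d = dict(d)
    cls = _PROTO_CLASSES[d.pop("kind")]
    for key in ("amplitudes_pa", "frequencies_hz"):
        if key in d:
            d[key] = tuple(d[key])
    return cls(**d)


def _unit(mode: str) -> str:
    return "mV" if mode == CURRENT_CLAMP else "pA"


def write_bundle(bundle: SweepBundle, path: Union[str, Path]) -> Path:
    """Write one pair's bundle as metadata.json + per-sweep CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "pair_id": bundle.pair_id,
        "meta": dataclasses.asdict(bundle.meta),
        "protocol": _protocol_to_dict(bundle.protocol),
        "modes": list(bundle.modes),
        "sampling_rate_hz": bundle.sampling_rate_hz,
        "sweep_labels": list(bundle.sweep_labels),
        "sweep_files": [f"sweep_{i:03d}.csv" for i in range(bundle.n_sweeps)],
        "ground_truth": (_spec_to_dict(bundle.ground_truth)
                         if bundle.ground_truth else None),
        "spike_log": ([[s[0].tolist(), s[1].tolist()] for s in bundle.spike_log]
                      if bundle.spike_log else None),
        "release_log": ([[r.tolist() for r in sweep]
                         for sweep in bundle.release_log]
                        if bundle.release_log else None),
    }
    (path / "metadata.json").write_text(
        json.dumps(meta, indent=1, default=_jsonable))
    t = bundle.time_ms(0)
    cols = ["time_ms", "i_inj_pA",
            f"cell1_{_unit(bundle.modes[0])}", f"cell2_{_unit(bundle.modes[1])}"]
    for i, sw in enumerate(bundle.sweeps):
        df = pd.DataFrame({cols[0]: np.arange(sw.shape[1]) * bundle.dt_ms,
                           cols[1]: sw[0], cols[2]: sw[1], cols[3]: sw[2]})
        df.to_csv(path / f"sweep_{i:03d}.csv", index=False,
                  float_format=_FLOAT_FMT)
    return path


def read_bundle(path: Union[str, Path]) -> SweepBundle:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    sweeps = []
    for fname in meta["sweep_files"]:
        df = pd.read_csv(path / fname, float_precision="round_trip")
        sweeps.append(np.vstack([df.iloc[:, 1].to_numpy(),
                                 df.iloc[:, 2].to_numpy(),
                                 df.iloc[:, 3].to_numpy()]))
    spike_log = None
    if meta["spike_log"] is not None:
        spike_log = [(np.array(s[0]), np.array(s[1]))
                     for s in meta["spike_log"]]
    release_log = None
    if meta["release_log"] is not None:
        release_log = [[np.array(r, np.int8) for r in sweep]
                       for sweep in meta["release_log"]]
    return SweepBundle(
        pair_id=meta["pair_id"],
        protocol=_protocol_from_dict(meta["protocol"]),
        sweeps=sweeps,
        sweep_labels=[float(l) for l in meta["sweep_labels"]],
        modes=tuple(meta["modes"]),
        sampling_rate_hz=meta["sampling_rate_hz"],
        meta=PairMeta(**meta["meta"]),
        ground_truth=(_spec_from_dict(meta["ground_truth"])
                      if meta["ground_truth"] else None),
        spike_log=spike_log,
        release_log=release_log)


def write_ventral_roots(rec: VentralRootRecording,
                        path: Union[str, Path]) -> Path:
    """One CSV: time_s column plus one column per channel."""
    path = Path(path)
    data = {"time_s": rec.time_s}
    for name, ch in zip(rec.channel_names, rec.channels):
        data[name] = ch
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_ventral_roots(path: Union[str, Path],
                       sampling_rate_hz: float = None) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Returns (time_s, channels (n_ch, n), channel names)."""
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    names = tuple(c for c in df.columns if c != "time_s")
    channels = np.vstack([df[c].to_numpy() for c in names])
    return t, channels, names


def load_source_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-figure source-data table (plain CSV) for group statistics.

    Columns are passed through untouched; numeric columns parse with
    round-trip float precision so re-exported tables stay identical.
    """
    return pd.read_csv(path, float_precision="round_trip")


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path
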