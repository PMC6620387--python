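"""HDF5 / CSV / YAML persistence for sessions and results.

Session layout: /pedal (positions + grid attrs), /blocks, /units/<id>
(spikes, waveform), /stim/<id>/<k> (event sets), /emg/<side>, /lfp/<area>.
Ground truth and analysis tables go to CSV; configs round-trip through YAML.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import (
    BlockSpec,
    EmgTrace,
    LfpTrace,
    PedalTrace,
    SessionData,
    StimEventSet,
    UnitRecord,
)


def save_session(session: SessionData, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = f.create_group("pedal")
        g.create_dataset("right_pos", data=session.pedal.right_pos)
        g.create_dataset("left_pos", data=session.pedal.left_pos)
        g.attrs["t0"] = float(session.pedal.times[0])
        g.attrs["sampling_rate"] = session.pedal.sampling_rate

        g = f.create_group("blocks")
        g.create_dataset("t_start", data=[b.t_start for b in session.blocks])
        g.create_dataset("t_end", data=[b.t_end for b in session.blocks])
        g.attrs["sides"] = json.dumps([b.side for b in session.blocks])

        for u in session.units:
            g = f.create_group(f"units/{u.unit_id}")
            g.create_dataset("spikes", data=u.spike_times)
            if u.waveform is not None:
                g.create_dataset("waveform", data=u.waveform)
            g.attrs.update(area=u.area, condition=u.condition,
                           hemisphere=u.hemisphere,
                           waveform_sampling_rate=u.waveform_sampling_rate)

        for uid, sets in session.stim.items():
            for k, ev in enumerate(sets):
                g = f.create_group(f"stim/{uid}/{k}")
                g.create_dataset("stim_times", data=ev.stim_times)
                g.create_dataset("snippets", data=ev.snippets)
                g.create_dataset("snippet_times", data=ev.snippet_times)
                if ev.trigger_spike_times is not None:
                    g.create_dataset("trigger_spike_times",
                                     data=ev.trigger_spike_times)
                g.attrs.update(site=ev.site, mode=ev.mode,
                               snippet_sampling_rate=ev.snippet_sampling_rate,
                               pulse_offsets=list(ev.pulse_offsets))

        for side, emg in session.emg.items():
            g = f.create_group(f"emg/{side}")
            g.create_dataset("values", data=emg.values.astype(np.float32))
            g.attrs.update(sampling_rate=emg.sampling_rate, t0=emg.t0, side=side)

        for area, lfp in session.lfp.items():
            g = f.create_group(f"lfp/{area}")
            g.create_dataset("values", data=lfp.values)
            g.attrs.update(sampling_rate=lfp.sampling_rate, t0=lfp.t0, area=area)

        f.attrs["metadata"] = json.dumps(session.metadata)


def load_session(path) -> SessionData:
    with h5py.File(path, "r") as f:
        g = f["pedal"]
        n = g["right_pos"].shape[0]
        times = g.attrs["t0"] + np.arange(n) / g.attrs["sampling_rate"]
        pedal = PedalTrace(times=times, right_pos=g["right_pos"][:],
                           left_pos=g["left_pos"][:])

        g = f["blocks"]
        sides = json.loads(g.attrs["sides"])
        blocks = [BlockSpec(side=s, t_start=float(a), t_end=float(b))
                  for s, a, b in zip(sides, g["t_start"][:], g["t_end"][:])]

        units = []
        for uid in sorted(f.get("units", {}).keys()):
            g = f[f"units/{uid}"]
            units.append(UnitRecord(
                unit_id=uid, area=g.attrs["area"], condition=g.attrs["condition"],
                hemisphere=g.attrs["hemisphere"], spike_times=g["spikes"][:],
                waveform=g["waveform"][:] if "waveform" in g else None,
                waveform_sampling_rate=float(g.attrs["waveform_sampling_rate"]),
            ))

        stim = {}
        if "stim" in f:
            for uid in f["stim"]:
                sets = []
                for k in sorted(f[f"stim/{uid}"], key=int):
                    g = f[f"stim/{uid}/{k}"]
                    sets.append(StimEventSet(
                        unit_id=uid, site=g.attrs["site"], mode=g.attrs["mode"],
                        stim_times=g["stim_times"][:], snippets=g["snippets"][:],
                        snippet_times=g["snippet_times"][:],
                        snippet_sampling_rate=float(g.attrs["snippet_sampling_rate"]),
                        trigger_spike_times=(g["trigger_spike_times"][:]
                                             if "trigger_spike_times" in g else None),
                        pulse_offsets=tuple(g.attrs["pulse_offsets"]),
                    ))
                stim[uid] = sets

        emg = {}
        if "emg" in f:
            for side in f["emg"]:
                g = f[f"emg/{side}"]
                emg[side] = EmgTrace(values=g["values"][:].astype(float),
                                     sampling_rate=float(g.attrs["sampling_rate"]),
                                     side=side, t0=float(g.attrs["t0"]))

        lfp = {}
        if "lfp" in f:
            for area in f["lfp"]:
                g = f[f"lfp/{area}"]
                lfp[area] = LfpTrace(values=g["values"][:],
                                     sampling_rate=float(g.attrs["sampling_rate"]),
                                     area=area, t0=float(g.attrs["t0"]))

        metadata = json.loads(f.attrs.get("metadata", "{}"))
    return SessionData(pedal=pedal, blocks=blocks, units=units, stim=stim,
                       emg=emg, lfp=lfp, metadata=metadata)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config_yaml(config, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_ground_truth(truth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.units.to_csv(out / "ground_truth_units.csv")
    truth.trials.to_csv(out / "ground_truth_trials.csv", index=False)
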