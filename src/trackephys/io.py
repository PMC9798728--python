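"""On-disk session bundle format.

A session directory holds: ``spikes.tsv`` (unit_id, region, time_s),
``positions.tsv`` (t_s, x_cm, y_cm), ``lfp.h5`` with one dataset per
channel and a ``sampling_rate`` attribute (``*.csv`` fallback when HDF5 is
unavailable), and ``metadata.json``.  Interval sets are BED-like TSV
(label, start_s, end_s, peak_s, attributes).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ContinuousSignal, IntervalSet, PositionTrace, SessionBundle, SpikeTrain

__all__ = ["write_bundle", "read_bundle", "write_intervals", "read_intervals"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_bundle(bundle: SessionBundle, path: str | Path, use_hdf5: bool = True) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = [
        (st.unit_id, st.region, t) for st in bundle.spikes for t in st.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "region", "time_s"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"t_s": bundle.positions.t, "x_cm": bundle.positions.x, "y_cm": bundle.positions.y}
    ).to_csv(path / "positions.tsv", sep="\t", index=False)
    channels = dict(bundle.lfp)
    channels["EMG"] = bundle.emg
    if use_hdf5:
        import h5py

        with h5py.File(path / "lfp.h5", "w") as f:
            for name, sig in channels.items():
                d = f.create_dataset(name, data=sig.samples)
                d.attrs["sampling_rate"] = sig.sampling_rate
                d.attrs["t0"] = sig.t0
    else:
        for name, sig in channels.items():
            pd.DataFrame({name: sig.samples}).to_csv(path / f"lfp_{name}.csv", index=False)
            (path / f"lfp_{name}.rate").write_text(f"{sig.sampling_rate}\n{sig.t0}")
    meta = {k: _jsonable(v) for k, v in bundle.metadata.items() if k != "unit_params"}
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_bundle(path: str | Path) -> SessionBundle:
    path = Path(path)
    spk = pd.read_csv(path / "spikes.tsv", sep="\t")
    trains = [
        SpikeTrain(str(uid), str(g["region"].iloc[0]), g["time_s"].to_numpy())
        for uid, g in spk.groupby("unit_id", sort=True)
    ]
    posdf = pd.read_csv(path / "positions.tsv", sep="\t")
    positions = PositionTrace(posdf["t_s"].to_numpy(), posdf["x_cm"].to_numpy(), posdf["y_cm"].to_numpy())
    channels: dict[str, ContinuousSignal] = {}
    h5 = path / "lfp.h5"
    if h5.exists():
        import h5py

        with h5py.File(h5, "r") as f:
            for name in f:
                d = f[name]
                channels[name] = ContinuousSignal(
                    name, float(d.attrs["sampling_rate"]), d[...], float(d.attrs.get("t0", 0.0))
                )
    else:
        for csv in sorted(path.glob("lfp_*.csv")):
            name = csv.stem.removeprefix("lfp_")
            rate_file = (path / f"lfp_{name}.rate").read_text().splitlines()
            channels[name] = ContinuousSignal(
                name, float(rate_file[0]), pd.read_csv(csv)[name].to_numpy(),
                float(rate_file[1]) if len(rate_file) > 1 else 0.0,
            )
    emg = channels.pop("EMG")
    meta = json.loads((path / "metadata.json").read_text())
    return SessionBundle(positions=positions, spikes=trains, lfp=channels, emg=emg, metadata=meta)


def write_intervals(iv: IntervalSet, path: str | Path) -> None:
    df = pd.DataFrame({"label": iv.label, "start_s": iv.start, "end_s": iv.end, "peak_s": iv.peak})
    for k, v in iv.attrs.items():
        df[k] = v
    df.to_csv(path, sep="\t", index=False)


def read_intervals(path: str | Path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t")
    attrs = {
        c: df[c].to_numpy()
        for c in df.columns
        if c not in ("label", "start_s", "end_s", "peak_s")
    }
    label = str(df["label"].iloc[0]) if len(df) else "interval"
    return IntervalSet(label, df["start_s"], df["end_s"], df["peak_s"], attrs or None)
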