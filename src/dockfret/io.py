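"""On-disk formats for trace datasets, ground truth, and melting curves.

A dataset is stored either as a directory of 3-column TSVs (frame, I_D,
I_A) plus a JSON manifest, or as a single HDF5 container with the same
schema. Ground-truth sidecars live in a parallel JSON file that the
analysis stages never read. Melting curves are 2-3 column CSVs
(temperature degC, A260[, A_background]).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .melting import MeltingCurve
from .simulate import GroundTruthSidecar
from .traces import Condition, ConditionDataset, IntensityTrace

__all__ = [
    "write_dataset_tsv", "read_dataset_tsv",
    "write_dataset_hdf5", "read_dataset_hdf5",
    "write_sidecars", "read_sidecars",
    "read_melting_csv", "write_melting_csv",
    "write_transition_map",
]


def write_transition_map(tmap, path: str | Path) -> Path:
    """Write a TDP/TODP density grid as CSV (rows = final FRET bins)."""
    path = Path(path)
    centers = 0.5 * (tmap.edges[:-1] + tmap.edges[1:])
    df = pd.DataFrame(tmap.grid, index=np.round(centers, 4),
                      columns=np.round(centers, 4))
    df.index.name = f"{tmap.kind}_final\\initial"
    df.to_csv(path)
    return path

MANIFEST_NAME = "manifest.json"


def write_dataset_tsv(dataset: ConditionDataset, directory: str | Path) -> Path:
    """Write one dataset as traces/<id>.tsv files plus a manifest."""
    directory = Path(directory)
    (directory / "traces").mkdir(parents=True, exist_ok=True)
    ids = []
    for tr in dataset:
        ids.append(tr.molecule_id)
        df = pd.DataFrame({
            "frame": np.arange(len(tr)),
            "I_D": tr.i_donor,
            "I_A": tr.i_acceptor,
        })
        df.to_csv(directory / "traces" / f"{tr.molecule_id}.tsv", sep="\t", index=False)
    manifest = {
        "frame_interval": dataset.frame_interval,
        "condition": dataset.condition.to_dict(),
        "molecules": ids,
    }
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return directory


def read_dataset_tsv(directory: str | Path) -> ConditionDataset:
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    condition = Condition.from_dict(manifest["condition"])
    dt = float(manifest["frame_interval"])
    traces = []
    for mol_id in manifest["molecules"]:
        df = pd.read_csv(directory / "traces" / f"{mol_id}.tsv", sep="\t")
        traces.append(IntensityTrace(df["I_D"].to_numpy(), df["I_A"].to_numpy(),
                                     dt, molecule_id=mol_id, condition=condition))
    return ConditionDataset(traces, condition=condition, frame_interval=dt)


def write_dataset_hdf5(dataset: ConditionDataset, path: str | Path) -> Path:
    """Single hierarchical container: /traces/<id>/{I_D,I_A} + attrs."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["frame_interval"] = dataset.frame_interval
        f.attrs["condition"] = json.dumps(dataset.condition.to_dict())
        grp = f.create_group("traces")
        for tr in dataset:
            g = grp.create_group(tr.molecule_id)
            g.create_dataset("I_D", data=tr.i_donor)
            g.create_dataset("I_A", data=tr.i_acceptor)
    return path


def read_dataset_hdf5(path: str | Path) -> ConditionDataset:
    with h5py.File(path, "r") as f:
        dt = float(f.attrs["frame_interval"])
        condition = Condition.from_dict(json.loads(f.attrs["condition"]))
        traces = []
        for mol_id in sorted(f["traces"]):
            g = f["traces"][mol_id]
            traces.append(IntensityTrace(g["I_D"][:], g["I_A"][:], dt,
                                         molecule_id=mol_id, condition=condition))
    return ConditionDataset(traces, condition=condition, frame_interval=dt)


def write_sidecars(sidecars: list[GroundTruthSidecar], path: str | Path) -> Path:
    """Ground truth for simulated datasets; analysis stages never read this."""
    path = Path(path)
    payload = [{
        "molecule_id": sc.molecule_id,
        "state_path": sc.state_path.tolist(),
        "dwell_states": sc.dwell_states.tolist(),
        "dwell_durations": sc.dwell_durations.tolist(),
        "bleach_frame": sc.bleach_frame,
        "bleach_time": sc.bleach_time,
        "static": sc.static,
        "seed": sc.seed,
    } for sc in sidecars]
    path.write_text(json.dumps(payload))
    return path


def read_sidecars(path: str | Path) -> list[GroundTruthSidecar]:
    payload = json.loads(Path(path).read_text())
    return [GroundTruthSidecar(
        molecule_id=d["molecule_id"],
        state_path=np.asarray(d["state_path"], dtype=np.int8),
        dwell_states=np.asarray(d["dwell_states"], dtype=np.int8),
        dwell_durations=np.asarray(d["dwell_durations"], dtype=float),
        bleach_frame=int(d["bleach_frame"]),
        bleach_time=float(d["bleach_time"]),
        static=bool(d["static"]),
        seed=int(d["seed"]),
    ) for d in payload]


def read_melting_csv(path: str | Path, label: str | None = None) -> MeltingCurve:
    """2-3 column CSV: temperature, A260, optional background absorbance."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: need at least 2 columns (T, A260)")
    bg = df[cols[2]].to_numpy() if len(cols) >= 3 else None
    return MeltingCurve(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), bg,
                        label=label or Path(path).stem)


def write_melting_csv(curve: MeltingCurve, path: str | Path) -> Path:
    data = {"temperature_C": curve.temperature, "A260": curve.absorbance}
    if curve.background is not None:
        data["A_bg"] = curve.background
    pd.DataFrame(data).to_csv(path, index=False)
    return Path(path)
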