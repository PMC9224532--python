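"""Readers and writers for the pipeline's on-disk formats.

Tables are plain CSV/TSV with fixed float precision so a fixed seed
yields byte-identical files across runs; voltage sweep families go to
HDF5 (one group per neuron, datasets ``current_pA``, ``voltage_mV`` and
step timing attributes).  Every writer has a matching reader and the
pair round-trips without loss at the written precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ephys import EPSCSeries, Sweep, SweepSet
from .expression import ExpressionMatrix

__all__ = [
    "write_behavior", "read_behavior",
    "write_social", "read_social",
    "write_sweeps_h5", "read_sweeps_h5",
    "write_epsc", "read_epsc",
    "write_expression", "read_expression",
]

FLOAT_FMT = "%.6f"


def write_behavior(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_behavior(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_social(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_social(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sweeps_h5(sweep_sets: list[SweepSet], path) -> None:
    """One HDF5 group per neuron; traces stored float32."""
    with h5py.File(path, "w") as f:
        for ss in sweep_sets:
            g = f.create_group(ss.neuron_id)
            g.attrs["sampling_rate"] = ss.sampling_rate
            g.attrs["step_onset_s"] = ss.sweeps[0].step_onset_s
            g.attrs["step_offset_s"] = ss.sweeps[0].step_offset_s
            g.create_dataset(
                "current_pA",
                data=np.array([s.current_pA for s in ss.sweeps]),
            )
            g.create_dataset(
                "voltage_mV",
                data=np.stack([s.voltage_mV for s in ss.sweeps]).astype(
                    np.float32
                ),
            )


def read_sweeps_h5(path) -> list[SweepSet]:
    out = []
    with h5py.File(path, "r") as f:
        for nid in sorted(f.keys()):
            g = f[nid]
            currents = g["current_pA"][()]
            traces = g["voltage_mV"][()].astype(float)
            sweeps = [
                Sweep(
                    current_pA=float(i),
                    step_onset_s=float(g.attrs["step_onset_s"]),
                    step_offset_s=float(g.attrs["step_offset_s"]),
                    voltage_mV=v,
                )
                for i, v in zip(currents, traces)
            ]
            out.append(SweepSet(
                neuron_id=nid,
                sampling_rate=float(g.attrs["sampling_rate"]),
                sweeps=sweeps,
            ))
    return out


def write_epsc(series_list: list[EPSCSeries], path) -> None:
    rows = []
    for s in series_list:
        phase = np.where(
            s.times_s < s.protocol_onset_s, "baseline",
            np.where(s.times_s < s.protocol_end_s, "protocol", "post"),
        )
        rows.append(pd.DataFrame({
            "neuron_id": s.neuron_id,
            "t_s": s.times_s,
            "amplitude_pA": s.amplitudes_pA,
            "phase": phase,
            "protocol_onset_s": s.protocol_onset_s,
            "protocol_end_s": s.protocol_end_s,
            "stimulation_intensity": s.stimulation_intensity,
        }))
    pd.concat(rows, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_epsc(path) -> list[EPSCSeries]:
    df = pd.read_csv(path)
    out = []
    for nid, g in df.groupby("neuron_id", sort=True):
        out.append(EPSCSeries(
            neuron_id=str(nid),
            times_s=g["t_s"].to_numpy(),
            amplitudes_pA=g["amplitude_pA"].to_numpy(),
            protocol_onset_s=float(g["protocol_onset_s"].iloc[0]),
            protocol_end_s=float(g["protocol_end_s"].iloc[0]),
            stimulation_intensity=float(g["stimulation_intensity"].iloc[0]),
        ))
    return out


def write_expression(matrix: ExpressionMatrix, matrix_path,
                     meta_path) -> None:
    """Gene x sample TSV (first column ``gene``) plus a sample sidecar."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t", float_format="%.8g")
    meta = matrix.sample_meta.copy()
    meta.index.name = "sample"
    meta.to_csv(meta_path, sep="\t")


def read_expression(matrix_path, meta_path,
                    scale: str = "linear") -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    return ExpressionMatrix(values=values, sample_meta=meta, scale=scale)
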