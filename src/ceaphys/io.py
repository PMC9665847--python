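"""Reading and writing the package's on-disk formats.

Cohorts of baseline/post trial pairs live in HDF5
(``/neurons/<id>/{baseline,post}`` datasets, ``frame_rate_hz`` file
attribute); ground-truth labels and event counts in a CSV manifest;
voltage/current sweeps in HDF5 (``/sweeps/<id>`` with per-sweep
attributes); von Frey tables, zone tracks and two-column test inputs as
plain CSV; simulation configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import CalciumGroundTruth, SimConfig, VonFreyTable
from .traces import InputError, Trace, TrialPair

__all__ = [
    "write_cohort_h5",
    "read_cohort_h5",
    "write_ground_truth_csv",
    "load_sim_config",
    "read_trace_csv",
    "read_vonfrey_csv",
    "write_vonfrey_csv",
]


def write_cohort_h5(
    path: str | Path, pairs: list[TrialPair], frame_rate_hz: float | None = None
) -> None:
    """Write trial pairs to HDF5 (groups ``/neurons/<id>/{baseline,post}``)."""
    if frame_rate_hz is None:
        frame_rate_hz = pairs[0].rate_hz
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate_hz"] = frame_rate_hz
        grp = f.create_group("neurons")
        for pair in pairs:
            g = grp.create_group(pair.neuron_id)
            g.create_dataset("baseline", data=pair.baseline.samples)
            g.create_dataset("post", data=pair.post.samples)


def read_cohort_h5(path: str | Path) -> list[TrialPair]:
    """Read trial pairs written by :func:`write_cohort_h5`."""
    pairs = []
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["frame_rate_hz"])
        for neuron_id in sorted(f["neurons"]):
            g = f["neurons"][neuron_id]
            pairs.append(
                TrialPair(
                    neuron_id=neuron_id,
                    baseline=Trace(g["baseline"][...], rate_hz=rate),
                    post=Trace(g["post"][...], rate_hz=rate),
                )
            )
    return pairs


def write_ground_truth_csv(path: str | Path, truth: CalciumGroundTruth) -> None:
    """Ground-truth manifest: one row per neuron with label and event counts."""
    rows = [
        {
            "neuron_id": nid,
            "label": label,
            "n_events_baseline": truth.baseline_events[nid].size,
            "n_events_post": truth.post_events[nid].size,
        }
        for nid, label in truth.labels.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML mapping."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise InputError("config YAML must be a mapping")
    return SimConfig(**raw)


def read_trace_csv(path: str | Path) -> Trace:
    """Per-neuron trace CSV with columns ``time_s`` and a value column.

    The value column may be named ``dff``, ``current_pa`` or
    ``voltage_mv``; the sampling rate is inferred from the time column.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise InputError("trace CSV needs a time_s column and one value column")
    value_col = next(c for c in df.columns if c != "time_s")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InputError("trace CSV needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InputError("trace CSV must be uniformly sampled")
    return Trace(df[value_col].to_numpy(dtype=float), rate_hz=1.0 / dt[0])


def read_vonfrey_csv(path: str | Path) -> VonFreyTable:
    """Von Frey table CSV: columns ``force_g``, ``withdrawals``[, ``n_trials``]."""
    df = pd.read_csv(path)
    n_trials = int(df["n_trials"].iloc[0]) if "n_trials" in df.columns else 5
    return VonFreyTable(
        filaments_g=df["force_g"].to_numpy(dtype=float),
        withdrawals=df["withdrawals"].to_numpy(dtype=int),
        n_trials=n_trials,
    )


def write_vonfrey_csv(path: str | Path, table: VonFreyTable) -> None:
    pd.DataFrame(
        {
            "force_g": table.filaments_g,
            "withdrawals": table.withdrawals,
            "n_trials": table.n_trials,
        }
    ).to_csv(path, index=False)
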