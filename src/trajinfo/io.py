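"""Delimited-text file formats for networks, trajectory datasets and results.

Everything is plain text: network specifications as JSON, trajectory
datasets as CSV (wide rows for discretely sampled data, event lists for
continuous paths), result tables as CSV with a JSON sidecar carrying the
full run configuration for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import InputEnsemble, RateSchedule, Reaction, ReactionNetwork
from .simulate import ContinuousTrajectory

__all__ = [
    "read_network_json",
    "write_network_json",
    "read_discrete_dataset",
    "write_discrete_dataset",
    "read_event_list",
    "write_event_list",
    "write_results",
]

RESULT_COLUMNS = [
    "method", "example", "q", "d", "N", "replicates",
    "info_bits_mean", "info_bits_std", "seed",
]


def write_network_json(network: ReactionNetwork, ensemble: InputEnsemble, path):
    doc = {
        "species": network.species_names,
        "labels": list(ensemble.labels),
        "prior": list(map(float, ensemble.prior)),
        "reactions": [
            {
                "reactants": list(rx.reactant_coeffs),
                "products": list(rx.product_coeffs),
                "rates": {
                    str(lab): {
                        "values": list(sched.values),
                        "breakpoints": list(sched.breakpoints),
                    }
                    for lab, sched in rx.rates.items()
                },
            }
            for rx in network.reactions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_network_json(path) -> tuple[ReactionNetwork, InputEnsemble]:
    doc = json.loads(Path(path).read_text())
    reactions = [
        Reaction(
            tuple(rx["reactants"]),
            tuple(rx["products"]),
            {
                lab: RateSchedule(
                    tuple(sched["values"]), tuple(sched.get("breakpoints", ()))
                )
                for lab, sched in rx["rates"].items()
            },
        )
        for rx in doc["reactions"]
    ]
    network = ReactionNetwork(doc["species"], reactions)
    ensemble = InputEnsemble(doc["labels"], np.asarray(doc["prior"]) if "prior" in doc else None)
    return network, ensemble


def write_discrete_dataset(X, labels, path, dt: float | None = None, T: float | None = None):
    """Wide CSV: one row per trajectory, label column plus x_1..x_d.

    ``dt`` and ``T`` go into a ``#`` header comment line.
    """
    X = np.asarray(X)
    d = X.shape[1]
    df = pd.DataFrame(X, columns=[f"x_{i}" for i in range(1, d + 1)])
    df.insert(0, "input_label", list(labels))
    df.insert(0, "trajectory_id", np.arange(len(df)))
    with open(path, "w") as fh:
        if dt is not None or T is not None:
            fh.write(f"# dt={dt} T={T}\n")
        df.to_csv(fh, index=False)


def read_discrete_dataset(path):
    """Read a wide trajectory table; returns ``(X, labels, meta)``.

    Rows are cells/trajectories, columns the sampled values.  Non-numeric
    cells are rejected with a diagnostic naming the offending row and
    column.
    """
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
    df = pd.read_csv(path, skiprows=skip)
    if df.empty:
        raise ValueError(f"{path}: empty dataset")
    if "input_label" not in df.columns:
        raise ValueError(f"{path}: missing required 'input_label' column")
    labels = df["input_label"].tolist()
    value_cols = [c for c in df.columns if c.startswith("x_")]
    if not value_cols:
        raise ValueError(f"{path}: no trajectory value columns (x_1, x_2, ...)")
    values = df[value_cols].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        rows, cols = np.nonzero(values.isna().to_numpy())
        raise ValueError(
            f"{path}: non-numeric or missing value at row {rows[0]}, "
            f"column {value_cols[cols[0]]!r}"
        )
    return values.to_numpy(), labels, meta


def write_event_list(trajectories: list[ContinuousTrajectory], path):
    """Event-list CSV: (trajectory_id, input_label, state, dwell_time)."""
    rows = []
    for i, tr in enumerate(trajectories):
        for s, t in zip(tr.states, tr.dwell_times):
            rows.append((i, tr.input_label, int(s[0]), float(t)))
    pd.DataFrame(
        rows, columns=["trajectory_id", "input_label", "state", "dwell_time"]
    ).to_csv(path, index=False)


def read_event_list(path, horizon: float | None = None) -> list[ContinuousTrajectory]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("trajectory_id", sort=True):
        dwell = grp["dwell_time"].to_numpy()
        T = float(dwell.sum()) if horizon is None else horizon
        out.append(
            ContinuousTrajectory(
                grp["input_label"].iloc[0], grp["state"].to_numpy()[:, None], dwell, T
            )
        )
    return out


def write_results(table: pd.DataFrame, path, config: dict | None = None):
    """Result CSV in fixed column order plus a JSON config sidecar."""
    if table.empty:
        raise ValueError("refusing to write an empty results table")
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)
    if config is not None:
        sidecar = Path(path).with_suffix(".config.json")
        from . import __version__

        doc = dict(config)
        doc.setdefault("package_version", __version__)
        sidecar.write_text(json.dumps(doc, indent=2, default=str))
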