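"""Readers and writers for rasters (TSV), connectivity/weights (MatrixMarket)
and configurations (YAML/JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from scipy import io as spio
from scipy import sparse

from .model_core import Connectivity
from .raster import SpikeRaster
from .simulator import SimulationConfig, config_from_dict, config_to_dict


def write_raster(raster: SpikeRaster, path) -> None:
    """Event-list TSV: ``time_ms<TAB>neuron_id`` with header comments.

    Events are written sorted by time then neuron; neuron ids are 0-based.
    """
    path = Path(path)
    order = np.lexsort((raster.neurons, raster.steps))
    with path.open("w") as fh:
        fh.write(f"#n_neurons={raster.n_neurons}\n")
        fh.write(f"#dt_ms={raster.dt_ms:g}\n")
        for i in order:
            fh.write(f"{raster.steps[i] * raster.dt_ms:g}\t{raster.neurons[i]}\n")


def read_raster(path) -> SpikeRaster:
    """Read an event-list TSV written by :func:`write_raster`."""
    path = Path(path)
    n_neurons = None
    dt_ms = 1.0
    times, neurons = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#n_neurons="):
                    n_neurons = int(line.split("=", 1)[1])
                elif line.startswith("#dt_ms="):
                    dt_ms = float(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
            try:
                times.append(float(parts[0]))
                neurons.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if n_neurons is None:
        raise ValueError(f"{path}: missing #n_neurons header")
    steps = np.round(np.asarray(times) / dt_ms).astype(np.int64)
    neurons = np.asarray(neurons, dtype=np.int64)
    if neurons.size and (neurons.min() < 0 or neurons.max() >= n_neurons):
        raise ValueError(f"{path}: neuron id outside declared range")
    return SpikeRaster(steps, neurons, n_neurons, dt_ms)


def write_connectivity(conn: Connectivity, path_mtx, path_json=None) -> None:
    """Connectivity snapshot: MTX coordinate file + sidecar JSON with types."""
    path_mtx = Path(path_mtx)
    spio.mmwrite(str(path_mtx), conn.adjacency.astype(np.int8))
    side = Path(path_json) if path_json else path_mtx.with_suffix(".json")
    side.write_text(json.dumps({
        "n_neurons": conn.n_neurons,
        "is_inhibitory": conn.is_inhibitory.astype(int).tolist(),
        "connection_prob": conn.connection_prob,
        "seed": conn.seed,
    }))


def read_connectivity(path_mtx, path_json=None) -> Connectivity:
    path_mtx = Path(path_mtx)
    side = Path(path_json) if path_json else path_mtx.with_suffix(".json")
    meta = json.loads(side.read_text())
    A = sparse.csr_matrix(spio.mmread(str(path_mtx)).astype(bool))
    return Connectivity(
        n_neurons=meta["n_neurons"],
        is_inhibitory=np.asarray(meta["is_inhibitory"], dtype=bool),
        adjacency=A,
        connection_prob=meta["connection_prob"],
        seed=meta["seed"],
    )


def write_weights(conn: Connectivity, weights: np.ndarray, path_mtx,
                  path_json=None, note: str = "normalized [0,1]") -> None:
    """Per-synapse weight snapshot in MTX coordinate format.

    The value of each (pre, post) entry is the synapse's weight; the
    sidecar JSON documents the scale.
    """
    A = conn.adjacency
    W = sparse.csr_matrix((np.asarray(weights, dtype=np.float64),
                           A.indices, A.indptr), shape=A.shape)
    path_mtx = Path(path_mtx)
    spio.mmwrite(str(path_mtx), W)
    side = Path(path_json) if path_json else path_mtx.with_suffix(".json")
    side.write_text(json.dumps({"units": note, "n_synapses": int(A.nnz)}))


def write_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config)))


def read_config(path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
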