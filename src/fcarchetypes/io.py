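"""Reading and writing pipeline artifacts.

Connectome sets live either as a directory of delimited N x N matrices
(one TSV per (subject, run), named ``<subject>_run-<run>.tsv``) or as a
single ``.npz`` array container with id arrays; the two dialects are
auto-detected from the path. Behavior tables are CSV, ground truth and
reports are JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ConnectomeSet, ReducedFeatures
from .synth import GroundTruth

__all__ = [
    "write_connectomes",
    "read_connectomes",
    "write_behavior",
    "read_behavior",
    "write_ground_truth",
    "read_ground_truth",
    "write_reduced_features",
    "read_reduced_features",
]

_RUN_RE = re.compile(r"^(?P<subject>.+)_run-(?P<run>\d+)\.(tsv|txt|csv)$")


def write_connectomes(cs: ConnectomeSet, path) -> Path:
    """Write a connectome set; directory -> TSV dialect, ``.npz`` -> container."""
    path = Path(path)
    if path.suffix == ".npz":
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path,
            matrices=cs.matrices,
            subject_ids=np.asarray(cs.subject_ids, dtype=str),
            run_ids=np.asarray(cs.run_ids),
            node_labels=np.asarray(cs.node_labels, dtype=str),
        )
        if cs.network_map:
            sidecar = path.with_suffix(".json")
            sidecar.write_text(json.dumps({"network_map": cs.network_map}, indent=2))
        return path
    path.mkdir(parents=True, exist_ok=True)
    for mat, sub, run in zip(cs.matrices, cs.subject_ids, cs.run_ids):
        np.savetxt(path / f"{sub}_run-{int(run)}.tsv", mat, delimiter="\t")
    meta = {"node_labels": list(cs.node_labels)}
    if cs.network_map:
        meta["network_map"] = cs.network_map
    (path / "nodes.json").write_text(json.dumps(meta, indent=2))
    return path


def read_connectomes(path) -> ConnectomeSet:
    """Read a connectome set written by :func:`write_connectomes`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            matrices = z["matrices"]
            subject_ids = z["subject_ids"]
            run_ids = z["run_ids"]
            node_labels = list(z["node_labels"])
        network_map = None
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            network_map = json.loads(sidecar.read_text()).get("network_map")
        return ConnectomeSet(matrices, subject_ids, run_ids, node_labels, network_map)
    entries = []
    for f in sorted(path.iterdir()):
        m = _RUN_RE.match(f.name)
        if m:
            entries.append((m["subject"], int(m["run"]), f))
    if not entries:
        raise FileNotFoundError(f"no connectome matrices found under {path}")
    entries.sort(key=lambda e: (e[0], e[1]))
    matrices = np.stack([np.loadtxt(f, delimiter="\t") for _, _, f in entries])
    node_labels = network_map = None
    meta_path = path / "nodes.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        node_labels = meta.get("node_labels")
        network_map = meta.get("network_map")
    return ConnectomeSet(
        matrices,
        np.array([e[0] for e in entries]),
        np.array([e[1] for e in entries]),
        node_labels,
        network_map,
    )


def write_behavior(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_behavior(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "grid_dims": list(truth.grid_dims),
        "archetype_per_obs": np.asarray(truth.archetype_per_obs).tolist(),
        "subject_modal_archetype": np.asarray(truth.subject_modal_archetype).tolist(),
        "subject_ids": None
        if truth.subject_ids is None
        else np.asarray(truth.subject_ids, dtype=str).tolist(),
        "run_ids": None
        if truth.run_ids is None
        else np.asarray(truth.run_ids).tolist(),
        "coding_map": truth.coding_map,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        archetype_per_obs=np.asarray(payload["archetype_per_obs"]),
        subject_modal_archetype=np.asarray(payload["subject_modal_archetype"]),
        grid_dims=tuple(payload["grid_dims"]),
        subject_ids=None
        if payload["subject_ids"] is None
        else np.asarray(payload["subject_ids"]),
        run_ids=None if payload["run_ids"] is None else np.asarray(payload["run_ids"]),
        coding_map=payload.get("coding_map") or {},
    )


def write_reduced_features(rf: ReducedFeatures, path) -> Path:
    """Array container plus JSON sidecar with eigenvalues and counts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        scores=rf.scores,
        loadings=rf.loadings,
        eigenvalues=rf.eigenvalues,
        subject_ids=np.asarray(rf.subject_ids, dtype=str),
        run_ids=np.asarray(rf.run_ids),
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "n_components": int(rf.n_components),
                "eigenvalues": [float(v) for v in rf.eigenvalues[: rf.n_components]],
            },
            indent=2,
        )
    )
    return path


def read_reduced_features(path) -> ReducedFeatures:
    with np.load(Path(path), allow_pickle=False) as z:
        return ReducedFeatures(
            scores=z["scores"],
            loadings=z["loadings"],
            eigenvalues=z["eigenvalues"],
            n_components=z["scores"].shape[1],
            subject_ids=z["subject_ids"],
            run_ids=z["run_ids"],
        )
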