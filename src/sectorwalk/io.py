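"""TSV/JSON interchange shared by the CLI and scripts.

The interchange format is a plain TSV with a single ``#``-prefixed JSON
metadata line on top — human-inspectable, diff-able, no binary dependency.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import EnsembleSummary, FrontierState, SimParams
from .simulator import Trajectory

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_state",
    "read_state",
    "write_events",
    "read_events",
    "write_summary",
    "RunManifest",
]


def write_tsv(path, df: pd.DataFrame, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta is not None:
            fh.write("#" + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> tuple[pd.DataFrame, Optional[dict]]:
    path = Path(path)
    meta = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first[1:])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_state(path, state: FrontierState, extra_meta: Optional[dict] = None) -> None:
    """One row per wall: (phi, left_label, right_label)."""
    meta = {
        "R0": state.R0, "R": state.R, "L": state.L, "t": state.t,
        "geometry": state.geometry, "fixed_label": state.fixed_label,
    }
    if extra_meta:
        meta.update(extra_meta)
    walls = state.walls
    df = pd.DataFrame({
        "phi": [w.phi for w in walls],
        "left_label": [w.type.left for w in walls],
        "right_label": [w.type.right for w in walls],
    })
    write_tsv(path, df, meta)


def read_state(path) -> FrontierState:
    df, meta = read_tsv(path)
    if meta is None:
        raise ValueError("state file lacks its JSON metadata header")
    return FrontierState(
        df["phi"].to_numpy(dtype=float),
        df["right_label"].to_numpy(dtype=np.int64),
        R0=meta["R0"], R=meta["R"], L=meta["L"], t=meta["t"],
        geometry=meta["geometry"], fixed_label=meta.get("fixed_label"),
    )


def write_events(path, traj: Trajectory, meta: Optional[dict] = None) -> None:
    lab = traj.event_labels
    df = pd.DataFrame({
        "L_at": traj.event_L,
        "kind": np.where(traj.event_kind == 0, "annihilation", "coalescence"),
        "left_in1": lab[:, 0], "right_in1": lab[:, 1],
        "left_in2": lab[:, 2], "right_in2": lab[:, 3],
        "left_out": lab[:, 4], "right_out": lab[:, 5],
    })
    write_tsv(path, df, meta)


def read_events(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df, _ = read_tsv(path)
    kind = np.where(df["kind"].to_numpy() == "annihilation", 0, 1).astype(np.int8)
    lab = df[["left_in1", "right_in1", "left_in2", "right_in2",
              "left_out", "right_out"]].to_numpy(dtype=np.int64)
    return df["L_at"].to_numpy(dtype=float), kind, lab


def write_summary(outdir, summ: EnsembleSummary, params: Optional[SimParams] = None) -> list[Path]:
    """Write fractions.tsv, corr.tsv and het.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"n_replicates": summ.n_replicates}
    if params is not None:
        meta["params"] = params.to_dict()
    paths = []
    q, nL = summ.Fi.shape
    rows = [
        {"L": summ.L_grid[m], "strain": i, "F": summ.Fi[i, m],
         "SE": None if summ.Fi_se is None else summ.Fi_se[i, m]}
        for m in range(nL) for i in range(q)
    ]
    p = outdir / "fractions.tsv"
    write_tsv(p, pd.DataFrame(rows), meta)
    paths.append(p)

    half = summ.phi_grid.size // 2 + 1
    rows = []
    for m in range(nL):
        for i in range(q):
            for j in range(i, q):
                for k in range(half):
                    rows.append({
                        "L": summ.L_grid[m], "phi": summ.phi_grid[k],
                        "i": i, "j": j, "Fij": summ.Fij[i, j, k, m],
                        "SE": None if summ.Fij_se is None else summ.Fij_se[i, j, k, m],
                    })
    p = outdir / "corr.tsv"
    write_tsv(p, pd.DataFrame(rows), meta)
    paths.append(p)

    rows = [
        {"L": summ.L_grid[m], "phi": summ.phi_grid[k], "H": summ.H[k, m],
         "SE": None if summ.H_se is None else summ.H_se[k, m]}
        for m in range(nL) for k in range(half)
    ]
    p = outdir / "het.tsv"
    write_tsv(p, pd.DataFrame(rows), meta)
    paths.append(p)
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output set."""

    command: str
    config: dict
    seed: Optional[int]
    version: str = ""
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    outputs: dict = field(default_factory=dict)

    def add_outputs(self, paths) -> None:
        for p in paths:
            p = Path(p)
            self.outputs[p.name] = _sha256(p)

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "timestamp": self.timestamp,
            "outputs": self.outputs,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
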