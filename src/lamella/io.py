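"""Trajectory, table and configuration I/O.

Two trajectory dialects are supported:

* **extended XYZ** — plain text, one block per frame: an atom count, a
  comment line carrying ``Lattice=...`` and per-frame metadata
  (time, walled flag), then one line per bead with species label,
  coordinates, molecule id and frozen flag.  Portable and diffable.
* **NPZ container** — compressed NumPy archive with the same schema
  plus bond lists, for large runs.

Foreign extended-XYZ files without molecule ids are read with every
bead as its own molecule (a warning is emitted).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .forcefield import SPECIES, SPECIES_INDEX
from .state import SystemState, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_xyz_frame",
    "load_config",
    "config_hash",
    "RunManifest",
    "TrajectoryParseError",
]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the offending record index."""


def write_xyz_frame(fh, state: SystemState) -> None:
    labels = state.species_labels()
    lx, ly, lz = state.box
    fh.write(f"{state.n_beads}\n")
    fh.write(
        f'Lattice="{lx} 0 0 0 {ly} 0 0 0 {lz}" '
        f"Properties=species:S:1:pos:R:3:molecule:I:1:frozen:I:1 "
        f"Time={state.time} WalledX={int(state.walled_x)}\n"
    )
    for i in range(state.n_beads):
        p = state.positions[i]
        fh.write(
            f"{labels[i]} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f} "
            f"{state.molecule_id[i]} {int(state.frozen[i])}\n"
        )


def _read_xyz_frame(lines, start, frame_index):
    try:
        n = int(lines[start].split()[0])
    except (ValueError, IndexError):
        raise TrajectoryParseError(
            f"frame {frame_index}: bad atom count at line {start + 1}"
        )
    if start + 2 + n > len(lines):
        raise TrajectoryParseError(
            f"frame {frame_index}: truncated after line {len(lines)} "
            f"(expected {n} atom records)"
        )
    comment = lines[start + 1]
    box = np.array([1.0, 1.0, 1.0])
    time = 0.0
    walled = False
    if "Lattice=" in comment:
        lat = comment.split('Lattice="')[1].split('"')[0].split()
        box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
    for token in comment.split():
        if token.startswith("Time="):
            time = float(token[5:])
        elif token.startswith("WalledX="):
            walled = bool(int(token[8:]))
    pos = np.empty((n, 3))
    species = np.empty(n, dtype=np.int8)
    mol = np.empty(n, dtype=np.int32)
    frozen = np.zeros(n, dtype=bool)
    has_mol = True
    for k in range(n):
        parts = lines[start + 2 + k].split()
        if len(parts) < 4:
            raise TrajectoryParseError(
                f"frame {frame_index}: malformed atom record {k} "
                f"(line {start + 3 + k})"
            )
        if parts[0] not in SPECIES_INDEX:
            raise TrajectoryParseError(
                f"frame {frame_index}: unknown species {parts[0]!r} in record {k}"
            )
        species[k] = SPECIES_INDEX[parts[0]]
        pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if len(parts) >= 5:
            mol[k] = int(parts[4])
        else:
            has_mol = False
            mol[k] = k
        if len(parts) >= 6:
            frozen[k] = bool(int(parts[5]))
    if not has_mol:
        warnings.warn(
            "extended-XYZ without molecule ids: beads read as singleton molecules",
            stacklevel=3,
        )
    state = SystemState(
        positions=pos,
        velocities=np.zeros((n, 3)),
        species=species,
        molecule_id=mol,
        box=box,
        frozen=frozen,
        walled_x=walled,
        time=time,
    )
    return state, start + 2 + n


def write_trajectory(trajectory: Trajectory | SystemState, path: str | Path) -> None:
    """Write a trajectory (or single state) in the format the suffix picks:
    ``.xyz``/``.extxyz`` text or ``.npz`` binary."""
    path = Path(path)
    if isinstance(trajectory, SystemState):
        trajectory = Trajectory([trajectory])
    if path.suffix in (".xyz", ".extxyz"):
        with open(path, "w") as fh:
            for frame in trajectory:
                write_xyz_frame(fh, frame)
    elif path.suffix == ".npz":
        arrays: dict[str, np.ndarray] = {}
        for k, f in enumerate(trajectory):
            arrays[f"pos_{k}"] = f.positions
            arrays[f"vel_{k}"] = f.velocities
            arrays[f"time_{k}"] = np.array([f.time])
        first = trajectory[0]
        arrays.update(
            n_frames=np.array([len(trajectory)]),
            species=first.species,
            molecule_id=first.molecule_id,
            frozen=first.frozen,
            box=first.box,
            walled_x=np.array([first.walled_x]),
            bonds=first.bonds,
        )
        np.savez_compressed(path, **arrays)
    else:
        raise ValueError(f"unrecognised trajectory format {path.suffix!r}")


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    if path.suffix in (".xyz", ".extxyz"):
        lines = Path(path).read_text().splitlines()
        frames = []
        cursor = 0
        idx = 0
        while cursor < len(lines) and lines[cursor].strip():
            state, cursor = _read_xyz_frame(lines, cursor, idx)
            frames.append(state)
            idx += 1
        if not frames:
            raise TrajectoryParseError("no frames found")
        return Trajectory(frames)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            n_frames = int(z["n_frames"][0])
            frames = []
            for k in range(n_frames):
                frames.append(
                    SystemState(
                        positions=z[f"pos_{k}"],
                        velocities=z[f"vel_{k}"],
                        species=z["species"],
                        molecule_id=z["molecule_id"],
                        frozen=z["frozen"],
                        box=z["box"],
                        walled_x=bool(z["walled_x"][0]),
                        bonds=z["bonds"],
                        time=float(z[f"time_{k}"][0]),
                    )
                )
        return Trajectory(frames)
    raise ValueError(f"unrecognised trajectory format {path.suffix!r}")


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (see the schema in the docs)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = ""

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
                "outputs": self.outputs,
            },
            indent=2,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            config_hash=d["config_hash"],
            seed=d["seed"],
            stages=d.get("stages", []),
            outputs=d.get("outputs", []),
            version=d.get("version", ""),
        )
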