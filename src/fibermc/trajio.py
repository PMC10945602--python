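"""Trajectory container (single-file chunked HDF5 per replica).

Layout (schema 1): root attributes hold replica metadata (seed, twist
offset, step counts, acceptance); ``/topology``, ``/forcefield`` and
``/restraint_params`` store the run definition; ``/frames`` holds chunked
float64 position arrays, energies, and the ragged engaged-restraint pairs
(concatenated, with per-frame counts); ``/initial`` stores the start
structure; ``/events`` the restraint engagement/release log. Files round-trip
losslessly and are readable by the analysis module without the simulator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .energy import EnergyBreakdown
from .forcefield import ForceField
from .geometry import Configuration
from .restraints import RestraintParams
from .sampler import Frame, Trajectory
from .topology import FiberTopology

__all__ = ["write_trajectory", "read_trajectory", "write_pdb"]

SCHEMA = 1
_CONFIG_ARRAYS = ("core_pos", "core_frames", "linker_pos", "tail_pos", "lh_pos",
                  "twist_registry", "tail_state")


def _write_config(grp: h5py.Group, config: Configuration) -> None:
    for name in _CONFIG_ARRAYS:
        grp.create_dataset(name, data=getattr(config, name))
    grp.attrs["twist_offset"] = config.twist_offset


def _read_config(grp: h5py.Group) -> Configuration:
    kw = {name: np.asarray(grp[name]) for name in _CONFIG_ARRAYS}
    kw["tail_state"] = kw["tail_state"].astype(np.int8)
    return Configuration(twist_offset=float(grp.attrs["twist_offset"]), **kw)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write one replica's trajectory to a single HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        from . import __version__

        f.attrs["schema"] = SCHEMA
        f.attrs["fibermc_version"] = __version__
        f.attrs["seed"] = trajectory.seed
        f.attrs["twist_offset"] = trajectory.twist_offset
        f.attrs["n_steps"] = trajectory.n_steps
        f.attrs["save_every"] = trajectory.save_every
        f.attrs["n_frames"] = len(trajectory.frames)
        f.attrs["acceptance"] = json.dumps(trajectory.acceptance)
        f.create_dataset("topology", data=trajectory.topology.to_json())
        f.create_dataset("forcefield", data=json.dumps(dataclasses.asdict(trajectory.ff)))
        f.create_dataset(
            "restraint_params", data=json.dumps(dataclasses.asdict(trajectory.restraint_params))
        )
        frames = trajectory.frames
        fg = f.create_group("frames")
        fg.create_dataset("steps", data=np.array([fr.step for fr in frames], dtype=np.int64))
        for name in _CONFIG_ARRAYS:
            arrs = [getattr(fr.config, name) for fr in frames]
            fg.create_dataset(name, data=np.stack(arrs) if frames else np.zeros((0,)))
        fg.create_dataset(
            "energy", data=np.stack([fr.energy.as_array() for fr in frames])
            if frames else np.zeros((0, 11)),
        )
        counts = np.array([len(fr.restraint_pairs) for fr in frames], dtype=np.int64)
        fg.create_dataset("restraint_counts", data=counts)
        pairs = (
            np.concatenate([fr.restraint_pairs.reshape(-1, 2) for fr in frames])
            if frames and counts.sum()
            else np.zeros((0, 2), dtype=np.int64)
        )
        fg.create_dataset("restraint_pairs", data=pairs.astype(np.int64))
        if trajectory.initial is not None:
            _write_config(f.create_group("initial"), trajectory.initial)
        ev = trajectory.events
        eg = f.create_group("events")
        eg.create_dataset("step", data=np.array([e[0] for e in ev], dtype=np.int64))
        eg.create_dataset(
            "kind", data=np.array([1 if e[1] == "engage" else 0 for e in ev], dtype=np.int8)
        )
        eg.create_dataset("bead_i", data=np.array([e[2] for e in ev], dtype=np.int64))
        eg.create_dataset("bead_j", data=np.array([e[3] for e in ev], dtype=np.int64))
        eg.create_dataset("distance", data=np.array([e[4] for e in ev]))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` (any schema)."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise IOError(f"not a readable trajectory file: {path}: {exc}") from exc
    with f:
        schema = int(f.attrs.get("schema", -1))
        if schema != SCHEMA:
            raise IOError(f"unsupported trajectory schema {schema} in {path}")
        topology = FiberTopology.from_json(f["topology"][()].decode())
        ff = ForceField(**json.loads(f["forcefield"][()].decode()))
        params = RestraintParams(**json.loads(f["restraint_params"][()].decode()))
        n_frames = int(f.attrs["n_frames"])
        fg = f["frames"]
        steps = np.asarray(fg["steps"])
        if len(steps) != n_frames:
            raise IOError(f"truncated trajectory: expected {n_frames} frames, found {len(steps)}")
        counts = np.asarray(fg["restraint_counts"])
        pairs = np.asarray(fg["restraint_pairs"])
        if counts.sum() != len(pairs):
            raise IOError("truncated trajectory: restraint pair table inconsistent")
        offsets = np.concatenate(([0], np.cumsum(counts)))
        frames = []
        twist_offset = float(f.attrs["twist_offset"])
        for k in range(n_frames):
            cfg = Configuration(
                core_pos=np.asarray(fg["core_pos"][k]),
                core_frames=np.asarray(fg["core_frames"][k]),
                linker_pos=np.asarray(fg["linker_pos"][k]),
                tail_pos=np.asarray(fg["tail_pos"][k]),
                lh_pos=np.asarray(fg["lh_pos"][k]),
                twist_registry=np.asarray(fg["twist_registry"][k]),
                twist_offset=twist_offset,
                tail_state=np.asarray(fg["tail_state"][k]).astype(np.int8),
            )
            frames.append(
                Frame(
                    step=int(steps[k]),
                    config=cfg,
                    restraint_pairs=pairs[offsets[k] : offsets[k + 1]].copy(),
                    energy=EnergyBreakdown.from_array(np.asarray(fg["energy"][k])),
                )
            )
        initial = _read_config(f["initial"]) if "initial" in f else None
        eg = f["events"]
        events = [
            (int(s), "engage" if k else "release", int(i), int(j), float(d))
            for s, k, i, j, d in zip(
                eg["step"], eg["kind"], eg["bead_i"], eg["bead_j"], eg["distance"]
            )
        ]
        return Trajectory(
            topology=topology,
            ff=ff,
            restraint_params=params,
            frames=frames,
            seed=int(f.attrs["seed"]),
            twist_offset=twist_offset,
            n_steps=int(f.attrs["n_steps"]),
            save_every=int(f.attrs["save_every"]),
            acceptance={k: tuple(v) for k, v in json.loads(f.attrs["acceptance"]).items()},
            initial=initial,
            events=events,
        )


def write_pdb(config: Configuration, topology: FiberTopology, ff: ForceField,
              path: str | Path) -> None:
    """Export one structure as PDB ATOM records for visualization.

    One bead per atom record; chain identifiers per component class
    (C = cores, D = linker DNA, T = tails, L = linker histones); the bead
    class is encoded in the atom-name field. Coordinates are written in
    Angstrom (nm x 10).
    """
    lines = []
    serial = 1

    def atom(name: str, chain: str, resseq: int, xyz) -> None:
        nonlocal serial
        x, y, z = (np.asarray(xyz) * 10.0).tolist()
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} BEA {chain}{resseq % 10000:4d}    "
            f"{x:8.2f}{y:8.2f}{z:8.2f}  1.00  0.00\n"
        )
        serial += 1

    for i, p in enumerate(config.core_pos):
        atom("NUC", "C", i + 1, p)
    for b, p in enumerate(config.linker_pos):
        atom("DNA", "D", b + 1, p)
    for t, p in enumerate(config.tail_pos):
        atom("TAI", "T", t + 1, p)
    for l, p in enumerate(config.lh_pos):
        atom("LHB", "L", l + 1, p)
    lines.append("END\n")
    Path(path).write_text("".join(lines))
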