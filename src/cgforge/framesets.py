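"""Frame containers: atomistic framesets, CG framesets and their HDF5 form.

One hierarchical-array container serves atomistic frames, CG frames and CG
trajectories; datasets are ``coords``/``forces`` (frames x sites x 3) plus
optional labels, with units, temperature and a topology hash stored as
string attributes.  Internal units are nm and kJ/mol/nm throughout.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .topology import CGTopology, AtomisticTopology, map_coordinates, aggregate_forces

__all__ = ["AtomisticFrameSet", "CGFrameSet", "map_frameset",
           "save_frameset", "load_frameset", "topology_hash"]

SOURCE_TAGS = ("domain-trajectory", "dimer-umbrella", "decoy")


def topology_hash(top) -> str:
    """Stable short hash of a topology's identifying content."""
    h = hashlib.sha256()
    if isinstance(top, CGTopology):
        h.update(repr((top.bead_names, tuple(top.bead_types.tolist()),
                       tuple(top.residue_index.tolist()), top.residue_names,
                       top.chain_id, top.aggregation_map)).encode())
    elif isinstance(top, AtomisticTopology):
        h.update(repr((top.atom_names, tuple(top.residue_index.tolist()),
                       top.residue_names, top.chain_id)).encode())
    else:
        h.update(repr(top).encode())
    return h.hexdigest()[:16]


@dataclass
class AtomisticFrameSet:
    """Per-frame atomistic coordinates and forces plus their topology.

    The raw training currency: coordinates in nm, forces in kJ/mol/nm,
    sampled at ``temperature`` K.
    """

    coords: np.ndarray               # (F, A, 3) nm
    forces: np.ndarray               # (F, A, 3) kJ/mol/nm
    topology: AtomisticTopology
    temperature: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.forces = np.asarray(self.forces, float)
        if self.coords.shape != self.forces.shape:
            raise ValueError(
                f"coords {self.coords.shape} and forces {self.forces.shape} "
                "must share shape")
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("expected (frames, atoms, 3) arrays")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class CGFrameSet:
    """CG coordinates R, mapped forces M_F f_AA and delta-force labels.

    ``delta_labels`` are mapped forces minus prior forces for genuine frames
    and identically zero for decoys.  ``weights`` carry per-frame statistical
    weights (umbrella-sampled data is non-uniform).
    """

    coords: np.ndarray                       # (F, n_beads, 3) nm
    topology: CGTopology
    temperature: float
    mapped_forces: np.ndarray | None = None  # (F, n_beads, 3)
    delta_labels: np.ndarray | None = None
    weights: np.ndarray | None = None
    source_tag: str = "domain-trajectory"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("expected (frames, beads, 3) coordinates")
        if self.coords.shape[1] != self.topology.n_beads:
            raise ValueError(
                f"frames have {self.coords.shape[1]} beads, topology has "
                f"{self.topology.n_beads}")
        if self.source_tag not in SOURCE_TAGS:
            raise ValueError(f"source_tag must be one of {SOURCE_TAGS}")
        for name in ("mapped_forces", "delta_labels"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                if arr.shape != self.coords.shape:
                    raise ValueError(f"{name} shape {arr.shape} != coords shape")
                setattr(self, name, arr)
        if self.weights is None:
            self.weights = np.ones(self.coords.shape[0])
        self.weights = np.asarray(self.weights, float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def subset(self, idx) -> "CGFrameSet":
        def pick(a):
            return None if a is None else a[idx]
        return CGFrameSet(self.coords[idx], self.topology, self.temperature,
                          pick(self.mapped_forces), pick(self.delta_labels),
                          self.weights[idx], self.source_tag)


def map_frameset(frames: AtomisticFrameSet, top: CGTopology) -> CGFrameSet:
    """Project an atomistic frameset to CG space: slice R, aggregate M_F f."""
    return CGFrameSet(
        coords=map_coordinates(frames.coords, top),
        topology=top,
        temperature=frames.temperature,
        mapped_forces=aggregate_forces(frames.forces, top),
    )


def save_frameset(path, fs, config_hash: str = "") -> None:
    """Write a frameset to the hierarchical container with unit attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=fs.coords)
        f.attrs["units_length"] = "nm"
        f.attrs["units_force"] = "kJ/mol/nm"
        f.attrs["temperature_K"] = float(fs.temperature)
        f.attrs["topology_hash"] = topology_hash(fs.topology)
        f.attrs["config_hash"] = config_hash
        if isinstance(fs, AtomisticFrameSet):
            f.attrs["kind"] = "atomistic"
            f.create_dataset("forces", data=fs.forces)
        else:
            f.attrs["kind"] = "cg"
            f.attrs["source_tag"] = fs.source_tag
            if fs.mapped_forces is not None:
                f.create_dataset("forces", data=fs.mapped_forces)
            if fs.delta_labels is not None:
                f.create_dataset("delta_labels", data=fs.delta_labels)
            f.create_dataset("weights", data=fs.weights)


def load_frameset(path, topology) -> AtomisticFrameSet | CGFrameSet:
    """Read a frameset back; ``topology`` must match the stored hash."""
    with h5py.File(path, "r") as f:
        stored = f.attrs["topology_hash"]
        if stored != topology_hash(topology):
            raise ValueError(
                f"topology hash mismatch: file has {stored}, argument hashes "
                f"to {topology_hash(topology)}")
        kind = f.attrs["kind"]
        if kind == "atomistic":
            return AtomisticFrameSet(f["coords"][...], f["forces"][...],
                                     topology, float(f.attrs["temperature_K"]))
        return CGFrameSet(
            coords=f["coords"][...], topology=topology,
            temperature=float(f.attrs["temperature_K"]),
            mapped_forces=f["forces"][...] if "forces" in f else None,
            delta_labels=f["delta_labels"][...] if "delta_labels" in f else None,
            weights=f["weights"][...] if "weights" in f else None,
            source_tag=str(f.attrs.get("source_tag", "domain-trajectory")),
        )
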