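"""Masked local-environment extraction and 6-channel voxelization.

Each residue's environment is the set of atoms within 9 Å of its Cα,
*excluding every atom of the residue itself* (the masking that makes
wild-type classification self-supervised).  Coordinates are expressed in a
local right-handed frame built from the residue's own backbone (N, Cα, C by
Gram–Schmidt), which makes the resulting grids invariant to rigid motions
of the whole structure.  Atoms are binned into the nearest center of a
1 Å³ voxel on an 18³ cube circumscribing the sphere, one channel per
element (C, N, O, H, S, P), and optionally smoothed with a normalized
Gaussian kernel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter

from .structure import (AA_INDEX, N_CHANNELS, ResidueSite, Structure,
                        residue_sites)

logger = logging.getLogger("stabscan.voxel")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the voxel grid.

    radius       sphere radius around Cα, Å
    voxel_edge   cubic voxel edge length, Å
    blur_sigma   Gaussian smoothing width, Å (kernel truncated at 2σ)
    """

    radius: float = 9.0
    voxel_edge: float = 1.0
    blur_sigma: float = 1.0
    channels: int = N_CHANNELS

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        side = 2.0 * self.radius / self.voxel_edge
        if abs(side - round(side)) > 1e-9:
            raise ValueError("2*radius must be an integer multiple of voxel_edge")

    @property
    def side_voxels(self) -> int:
        return int(round(2.0 * self.radius / self.voxel_edge))

    @property
    def shape(self) -> tuple[int, int, int, int]:
        s = self.side_voxels
        return (self.channels, s, s, s)

    def to_dict(self) -> dict:
        return {"radius": self.radius, "voxel_edge": self.voxel_edge,
                "blur_sigma": self.blur_sigma, "channels": self.channels}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class LocalFrame:
    """Backbone-anchored orthonormal frame: origin at Cα, axis 1 along
    N−Cα, axis 2 the in-plane component of C−Cα, axis 3 their cross
    product (right-handed)."""

    origin: np.ndarray          # (3,)
    axes: np.ndarray            # (3, 3), rows are the axes

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(coords) - self.origin) @ self.axes.T


@dataclass
class VoxelGrid:
    values: np.ndarray          # (channels, side, side, side), >= 0
    spec: GridSpec = field(default_factory=GridSpec)


def local_frame(site: ResidueSite) -> LocalFrame:
    """Gram–Schmidt frame from the N/Cα/C backbone; raises on (near-)
    collinear geometry, naming the residue."""
    u1 = site.n - site.ca
    n1 = np.linalg.norm(u1)
    v = site.c - site.ca
    if n1 < 1e-6:
        raise ValueError(f"degenerate backbone at residue {site.residue_index}")
    u1 = u1 / n1
    w = v - (v @ u1) * u1
    n2 = np.linalg.norm(w)
    if n2 < 1e-6:
        raise ValueError(
            f"collinear backbone at residue {site.residue_index} "
            f"({site.wt_aa}{site.residue_index}): cannot orient local frame")
    u2 = w / n2
    u3 = np.cross(u1, u2)
    return LocalFrame(origin=site.ca.copy(), axes=np.stack([u1, u2, u3]))


def extract_environment(structure: Structure, site: ResidueSite,
                        spec: GridSpec = GridSpec()
                        ) -> list[tuple[int, np.ndarray]]:
    """Atoms within ``spec.radius`` of the site's Cα, excluding the target
    residue's own atoms and atoms outside the six element channels, as
    (channel, local-coordinate) pairs.  An empty environment is legal."""
    frame = local_frame(site)
    env: list[tuple[int, np.ndarray]] = []
    for res in structure.residues:
        for atom in res.atoms:
            if (res.chain_id == site.chain_id
                    and res.residue_index == site.residue_index):
                continue                      # masking: drop the whole target residue
            ch = atom.channel
            if ch is None:
                continue
            if np.linalg.norm(atom.coords - site.ca) > spec.radius:
                continue
            env.append((ch, frame.to_local(atom.coords)[0]))
    return env


def voxelize(env: list[tuple[int, np.ndarray]],
             spec: GridSpec = GridSpec()) -> VoxelGrid:
    """Nearest-center binning of environment atoms into the channel grid.

    The cube spans [−radius, radius]³ with voxel centers at half-integer
    multiples of the edge length; each atom increments exactly one voxel, so
    with blurring disabled the per-channel sum equals the number of atoms of
    that channel.
    """
    s = spec.side_voxels
    values = np.zeros(spec.shape, dtype=np.float32)
    for ch, xyz in env:
        idx = np.floor((np.asarray(xyz) + spec.radius) / spec.voxel_edge).astype(int)
        idx = np.clip(idx, 0, s - 1)          # boundary atoms at exactly +radius
        values[ch, idx[0], idx[1], idx[2]] += 1.0
    return VoxelGrid(values=values, spec=spec)


def gaussian_blur(grid: VoxelGrid, sigma: float | None = None) -> VoxelGrid:
    """Per-channel isotropic Gaussian smoothing, kernel truncated at 2σ and
    normalized to unit sum, so per-channel mass is conserved except where it
    falls outside the cube (edge losses are accepted and documented)."""
    if sigma is None:
        sigma = grid.spec.blur_sigma
    if sigma <= 0:
        raise ValueError("blur sigma must be positive")
    sigma_vox = sigma / grid.spec.voxel_edge
    out = np.empty_like(grid.values)
    for c in range(grid.values.shape[0]):
        out[c] = gaussian_filter(grid.values[c], sigma=sigma_vox,
                                 truncate=2.0, mode="constant", cval=0.0)
    return VoxelGrid(values=out, spec=grid.spec)


def featurize_site(structure: Structure, site: ResidueSite,
                   spec: GridSpec = GridSpec()) -> VoxelGrid:
    """Convenience: masked environment → unblurred occupancy grid.
    (Blurring is applied by the representation model itself, so that the
    checkpointed GridSpec controls it.)"""
    return voxelize(extract_environment(structure, site, spec), spec)


# ---------------------------------------------------------------------------
# Batch serialization for representation-model training
# ---------------------------------------------------------------------------

def save_environment_dataset(path, grids: np.ndarray, labels: np.ndarray,
                             protein_ids: list[str], residue_indices: np.ndarray,
                             spec: GridSpec) -> None:
    """Chunked HDF5 container of occupancy grids + wild-type labels.

    One record per residue: (source_id, residue_index, wt label index, grid).
    The GridSpec is stored alongside so training cannot silently mismatch
    featurization.
    """
    grids = np.asarray(grids, dtype=np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("grids", data=grids, chunks=(1,) + grids.shape[1:],
                         compression="gzip")
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        f.create_dataset("protein_ids",
                         data=np.array(protein_ids, dtype=h5py.string_dtype()))
        f.create_dataset("residue_indices",
                         data=np.asarray(residue_indices, dtype=np.int64))
        f.attrs["grid_spec"] = json.dumps(spec.to_dict())


def load_environment_dataset(path):
    with h5py.File(path, "r") as f:
        grids = f["grids"][...]
        labels = f["labels"][...]
        protein_ids = [s.decode() if isinstance(s, bytes) else s
                       for s in f["protein_ids"][...]]
        residue_indices = f["residue_indices"][...]
        spec = GridSpec.from_dict(json.loads(f.attrs["grid_spec"]))
    return grids, labels, protein_ids, residue_indices, spec


def build_environment_dataset(structures: list[Structure],
                              spec: GridSpec = GridSpec()):
    """Featurize every scannable site of every structure.

    Returns (grids, labels, protein_ids, residue_indices): the occupancy
    grids are unblurred; labels are indices into the alphabetical
    one-letter amino-acid ordering.
    """
    grids, labels, pids, ridx = [], [], [], []
    for st in structures:
        for site in residue_sites(st):
            grids.append(featurize_site(st, site, spec).values)
            labels.append(AA_INDEX[site.wt_aa])
            pids.append(st.source_id)
            ridx.append(site.residue_index)
    if grids:
        g = np.stack(grids)
    else:
        g = np.zeros((0,) + spec.shape, dtype=np.float32)
    return g, np.array(labels, dtype=np.int64), pids, np.array(ridx, dtype=np.int64)
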