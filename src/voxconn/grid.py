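"""Grid geometry: affines, voxel centers, and the node <-> voxel map.

All volumes in a study share one rectilinear grid.  Voxel (i, j, k) maps
to millimetre space through a NIfTI-style 4x4 affine.  Gray-matter
voxels become network nodes through a :class:`NodeMap`, which fixes the
column order of every time-series matrix and the row order of every
metric vector: a linear scan of the grid with the x index varying
fastest (Fortran order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def make_affine(shape, voxel_size_mm, center_origin=True):
    """Build a diagonal grid-to-mm affine.

    With ``center_origin`` the mm origin sits at the geometric center of
    the grid, so coordinates are symmetric about zero (MNI-like).
    """
    shape = np.asarray(shape, dtype=float)
    vox = np.asarray(voxel_size_mm, dtype=float)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vox
    if center_origin:
        affine[:3, 3] = -vox * (shape - 1) / 2.0
    return affine


def voxel_centers_mm(shape, affine):
    """mm coordinates of every voxel center, shape ``(*grid, 3)``."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ijk = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    mm = ijk @ affine[:3, :3].T + affine[:3, 3]
    return mm.reshape(*shape, 3)


@dataclass
class NodeMap:
    """Bijection between node index, grid index and mm coordinate.

    Nodes are the True voxels of a boolean mask, numbered by a linear
    scan of the grid with x fastest.
    """

    shape: tuple
    affine: np.ndarray
    ijk: np.ndarray          # (N, 3) int, node -> grid index
    _flat_to_node: np.ndarray = field(repr=False)  # F-order flat -> node or -1

    @classmethod
    def from_mask(cls, mask: np.ndarray, affine: np.ndarray) -> "NodeMap":
        mask = np.asarray(mask, dtype=bool)
        flat = np.flatnonzero(mask.ravel(order="F"))
        ijk = np.stack(np.unravel_index(flat, mask.shape, order="F"), axis=1)
        inv = np.full(mask.size, -1, dtype=np.int64)
        inv[flat] = np.arange(flat.size)
        return cls(shape=tuple(mask.shape), affine=np.asarray(affine, float),
                   ijk=ijk.astype(np.int64), _flat_to_node=inv)

    @property
    def n_nodes(self) -> int:
        return self.ijk.shape[0]

    @property
    def mm(self) -> np.ndarray:
        """(N, 3) mm coordinates of node voxel centers."""
        return self.ijk.astype(float) @ self.affine[:3, :3].T + self.affine[:3, 3]

    def node_of_ijk(self, i, j, k) -> int:
        """Node index of a grid voxel, or -1 if it is not a node."""
        flat = np.ravel_multi_index((i, j, k), self.shape, order="F")
        return int(self._flat_to_node[flat])

    def nodes_of_volume_mask(self, vol_mask: np.ndarray) -> np.ndarray:
        """Boolean per-node vector: node lies inside ``vol_mask``."""
        if vol_mask.shape != self.shape:
            raise ValueError(
                f"mask shape {vol_mask.shape} does not match grid {self.shape}")
        return np.asarray(vol_mask, bool)[tuple(self.ijk.T)]

    def mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[tuple(self.ijk.T)] = True
        return out

    def to_volume(self, values: np.ndarray, missing=np.nan) -> np.ndarray:
        """Scatter per-node values into a 3-D volume (missing elsewhere)."""
        values = np.asarray(values)
        if values.shape[0] != self.n_nodes:
            raise ValueError(
                f"{values.shape[0]} values for {self.n_nodes} nodes")
        out = np.full(self.shape, missing, dtype=float)
        out[tuple(self.ijk.T)] = values
        return out

    def same_grid(self, other: "NodeMap") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine)
                and self.ijk.shape == other.ijk.shape
                and bool(np.all(self.ijk == other.ijk)))

    def to_frame(self):
        """Node table (node, i, j, k, x_mm, y_mm, z_mm) for TSV export."""
        import pandas as pd
        mm = self.mm
        return pd.DataFrame({
            "node": np.arange(self.n_nodes),
            "i": self.ijk[:, 0], "j": self.ijk[:, 1], "k": self.ijk[:, 2],
            "x_mm": mm[:, 0], "y_mm": mm[:, 1], "z_mm": mm[:, 2],
        })
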