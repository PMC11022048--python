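"""Voxelized spherical cell geometry.

The model cell is a cube of ``n**3`` voxels partitioned into concentric
regions: a cell-membrane shell (CM), a peripheral-cytoplasm shell (PC) just
beneath it, a bulk cytoplasm (CYTO) sandwiched between the PC shell and a
central-organelle ball (CO, representing the nucleus plus surrounding
ER/mitochondria), and a random cytoskeleton network (CS) occupying a chosen
fraction of that bulk cytoplasm.  Voxels outside the membrane, and in the
thin gap between the PC and CM shells, carry no label (EMPTY).

Coordinates are 0-based voxel indices; the physical position of voxel
``(i, j, k)`` is its center, with the origin at the center of the central
voxel, so the central voxel sits at distance exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Region(IntEnum):
    """Voxel region codes."""

    EMPTY = 0
    CM = 1      # cell membrane shell
    PC = 2      # peripheral cytoplasm shell
    CYTO = 3    # bulk cytoplasm (non-conducting)
    CS = 4      # cytoskeleton
    CO = 5      # central organelle ball


#: pseudo-code for :func:`region_vertices`: CO voxels with >=1 non-CO
#: 26-neighbor (the organelle surface feeding the readout layer).
CO_SURFACE = "co_surface"


class ConfigurationError(ValueError):
    """Invalid geometric or physical configuration."""


@dataclass
class CellGeometry:
    """A labeled voxel grid for one spherical cell.

    Parameters are in micrometres.  ``labels`` is an ``(n, n, n)`` uint8
    array of :class:`Region` codes; ``n`` is odd so a central voxel exists.
    """

    voxel_size: float
    r_cm: float
    r_pc: float
    r_co: float
    labels: np.ndarray
    cs_fraction: float = 0.0
    seed: int | None = None
    _cyto_order: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def center(self) -> int:
        return (self.n - 1) // 2

    def distances(self) -> np.ndarray:
        """Euclidean distance (μm) of every voxel center from the cell center."""
        ax = (np.arange(self.n) - self.center) * self.voxel_size
        return np.sqrt(
            ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        )

    def counts(self) -> dict[str, int]:
        return {r.name: int(np.count_nonzero(self.labels == r)) for r in Region}

    def cytoplasm_count(self) -> int:
        """Voxels eligible for cytoskeleton placement (CYTO ∪ CS)."""
        return int(np.count_nonzero((self.labels == Region.CYTO) | (self.labels == Region.CS)))


def build_cell(voxel_size: float, r_cm: float, r_pc: float, r_co: float) -> CellGeometry:
    """Construct the labeled voxel cell.

    The bounding cube has ``n = 2*ceil(r_cm/voxel_size) + 1`` voxels per
    side.  The CO ball contains every voxel whose center lies within
    ``r_co``; the PC and CM shells are one voxel thick: a voxel belongs to
    the r-shell iff ``round(|c|/voxel_size) == round(r/voxel_size)``.  Bulk
    cytoplasm is everything strictly between the CO ball and the PC shell.
    """
    if voxel_size <= 0:
        raise ConfigurationError("voxel_size must be positive")
    if not (0 < r_co < r_pc < r_cm):
        raise ConfigurationError(
            f"radii must satisfy 0 < r_co < r_pc < r_cm, got {r_co}, {r_pc}, {r_cm}"
        )
    if r_co < voxel_size:
        raise ConfigurationError(
            f"central organelle radius {r_co} μm is smaller than one voxel "
            f"({voxel_size} μm): degenerate organelle"
        )
    n = 2 * math.ceil(r_cm / voxel_size) + 1
    labels = np.full((n, n, n), Region.EMPTY, dtype=np.uint8)
    geom = CellGeometry(voxel_size, r_cm, r_pc, r_co, labels)

    dist = geom.distances()
    shell_index = np.rint(dist / voxel_size).astype(np.int64)
    pc_shell = round(r_pc / voxel_size)
    cm_shell = round(r_cm / voxel_size)
    if pc_shell >= cm_shell:
        raise ConfigurationError(
            "PC and CM shells coincide at this voxel size; refine voxel_size"
        )

    co = dist <= r_co
    labels[(dist > r_co) & (shell_index < pc_shell) & ~co] = Region.CYTO
    labels[shell_index == pc_shell] = Region.PC
    labels[shell_index == cm_shell] = Region.CM
    labels[co] = Region.CO
    return geom


def generate_cytoskeleton(geom: CellGeometry, cs_fraction: float, seed: int) -> CellGeometry:
    """Fill the bulk cytoplasm with a uniform random cytoskeleton.

    Exactly ``round(cs_fraction * |CYTO ∪ CS|)`` voxels are relabeled CS,
    drawn uniformly without replacement (exact-count sampling keeps the
    fill fraction exact per trial).  Any existing CS voxels are cleared
    first, so the call is idempotent in the fraction.  For a fixed seed the
    CS sets are nested in ``cs_fraction``: the fill is a prefix of one
    random permutation of the cytoplasm voxels.
    """
    if not (0.0 <= cs_fraction <= 1.0):
        raise ConfigurationError(f"cs_fraction must lie in [0, 1], got {cs_fraction}")
    labels = geom.labels
    labels[labels == Region.CS] = Region.CYTO
    cyto_flat = np.flatnonzero(labels == Region.CYTO)
    k = round(cs_fraction * cyto_flat.size)
    rng = np.random.default_rng(seed)
    order = rng.permutation(cyto_flat.size)
    chosen = cyto_flat[order[:k]]
    labels.ravel()[chosen] = Region.CS
    geom.cs_fraction = cs_fraction
    geom.seed = seed
    geom._cyto_order = order
    return geom


_NEIGHBOR_OFFSETS = np.array(
    [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ],
    dtype=np.int64,
)


def co_surface_mask(geom: CellGeometry) -> np.ndarray:
    """Boolean mask of CO voxels with at least one non-CO 26-neighbor.

    Out-of-bounds neighbors count as non-CO, so an organelle touching the
    grid boundary is all surface there.
    """
    from scipy.ndimage import binary_erosion

    co = geom.labels == Region.CO
    interior = binary_erosion(co, structure=np.ones((3, 3, 3), bool), border_value=0)
    return co & ~interior


def region_vertices(geom: CellGeometry, code: Region | str) -> np.ndarray:
    """All voxel index triples with the given label, in lexicographic order.

    ``code`` may be a :class:`Region` or the derived :data:`CO_SURFACE`
    code.  ``np.argwhere`` on a C-ordered array is already lexicographic,
    which fixes the canonical vertex ordering used by the readout features.
    """
    if code == CO_SURFACE:
        mask = co_surface_mask(geom)
    elif isinstance(code, Region) or code in Region.__members__.values():
        mask = geom.labels == Region(code)
    else:
        raise ValueError(f"unknown region code: {code!r}")
    return np.argwhere(mask)
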