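"""Grid-based solvent-excluded (Connolly-style) surface and shell masks.

The solvent-excluded surface is computed morphologically on the voxel grid:
voxels within ``atom_radius + probe`` of any atom center form the
probe-inflated volume; voxels of that volume reachable by a probe sphere
centered at any voxel outside it are then removed (erosion by the probe),
leaving the solvent-excluded interior.  Distances are exact Euclidean between
voxel centers, so the result is identical to brute-force probe placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import OutOfBoundsError
from .structure_io import Structure

DEFAULT_PROBE_RADIUS = 1.4  # Angstrom
DEFAULT_SHELL_THICKNESS = 2.0  # Angstrom


@dataclass(frozen=True)
class GridSpec:
    """Cubic grid covering [-extent, +extent]^3 at uniform spacing.

    ``padded_dim`` is the per-axis size of the zero-padded network input into
    which the physical block is centered (128 for the full-scale profile so
    six halvings leave a 2^3 spatial map).
    """

    extent: float = 36.0
    spacing: float = 0.75
    padded_dim: int = 128

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.padded_dim < self.n_points:
            raise ValueError("padded_dim smaller than the physical grid")

    @property
    def n_points(self) -> int:
        """Physical points per axis (97 at the defaults)."""
        n = 2.0 * self.extent / self.spacing
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9:
            raise ValueError("extent must be an integer multiple of spacing")
        return n_int + 1

    def axis(self) -> np.ndarray:
        return -self.extent + self.spacing * np.arange(self.n_points)

    def voxel_centers(self) -> np.ndarray:
        """(n, n, n, 3) array of voxel center coordinates."""
        ax = self.axis()
        g = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.stack(g, axis=-1)

    @property
    def pad_offset(self) -> int:
        return (self.padded_dim - self.n_points) // 2


#: full-scale profile: 97 physical points padded to 128^3
FULL_GRID = GridSpec(extent=36.0, spacing=0.75, padded_dim=128)
#: desk/test profile: 17 physical points padded to 32^3
DESK_GRID = GridSpec(extent=12.0, spacing=1.5, padded_dim=32)


@dataclass
class OccupancyGrid:
    spec: GridSpec
    interior: np.ndarray  # bool (n,n,n), inside the solvent-excluded volume
    surface_distance: np.ndarray  # float (n,n,n), Angstrom to the boundary layer


@dataclass
class ShellMask:
    spec: GridSpec
    active: np.ndarray  # bool (n,n,n)


def _stamp_balls(spec: GridSpec, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean grid of voxels whose center lies within radius_i of center_i."""
    n = spec.n_points
    ax = spec.axis()
    out = np.zeros((n, n, n), dtype=bool)
    h = spec.spacing
    for c, r in zip(centers, radii):
        lo = np.maximum(np.floor((c - r + spec.extent) / h).astype(int), 0)
        hi = np.minimum(np.ceil((c + r + spec.extent) / h).astype(int), n - 1)
        if np.any(lo > hi):
            continue
        sx = ax[lo[0] : hi[0] + 1] - c[0]
        sy = ax[lo[1] : hi[1] + 1] - c[1]
        sz = ax[lo[2] : hi[2] + 1] - c[2]
        d2 = (
            sx[:, None, None] ** 2
            + sy[None, :, None] ** 2
            + sz[None, None, :] ** 2
        )
        out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= r * r
    return out


def compute_ses(
    s: Structure,
    spec: GridSpec,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> OccupancyGrid:
    """Solvent-excluded volume of ``s`` on the grid.

    Raises OutOfBoundsError if any atom (plus its inflated radius) does not
    fit inside the grid extent: silent clipping would corrupt the ESP shell.
    """
    coords = s.coords()
    radii = s.radii()
    if np.any(np.isnan(radii)):
        raise ValueError("radii not assigned; run assign_parameters first")
    margin = radii + probe_radius
    for i, (c, m) in enumerate(zip(coords, margin)):
        if np.any(np.abs(c) + m > spec.extent):
            a = s.atoms[i]
            raise OutOfBoundsError(
                f"atom {a.serial} {a.name} {a.residue_name}{a.residue_number} "
                f"at {c.round(2).tolist()} exceeds grid extent {spec.extent}"
            )
    inflated = _stamp_balls(spec, coords, radii + probe_radius)
    # exact Euclidean distance from each inflated voxel to the nearest voxel
    # outside the inflated volume; probe-reachable voxels are carved away
    h = spec.spacing
    d_out = ndimage.distance_transform_edt(inflated, sampling=h)
    interior = inflated & (d_out > probe_radius)
    surface_distance = _boundary_distance(interior, h)
    return OccupancyGrid(spec=spec, interior=interior, surface_distance=surface_distance)


def _boundary_distance(interior: np.ndarray, spacing: float) -> np.ndarray:
    """Distance from every voxel center to the exterior boundary layer.

    The boundary layer is the set of exterior voxels 6-adjacent to an
    interior voxel.  With an empty interior the distance is +inf everywhere.
    """
    if not interior.any():
        return np.full(interior.shape, np.inf)
    dil = ndimage.binary_dilation(
        interior, structure=ndimage.generate_binary_structure(3, 1)
    )
    boundary = dil & ~interior
    if not boundary.any():  # structure fills the whole grid
        return np.full(interior.shape, np.inf)
    return ndimage.distance_transform_edt(~boundary, sampling=spacing)


def compute_shell(
    occ: OccupancyGrid,
    thickness: float = DEFAULT_SHELL_THICKNESS,
) -> ShellMask:
    """Exterior voxels within ``thickness`` of the surface boundary layer.

    Interior voxels (where the ESP is ill-defined) are never active; at
    thickness 0 the mask is exactly the exterior boundary layer.
    """
    active = (~occ.interior) & (occ.surface_distance <= thickness)
    return ShellMask(spec=occ.spec, active=active)
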