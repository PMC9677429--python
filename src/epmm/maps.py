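"""Electrostatic potential and density on cubic grids; Gaussian cube output.

The potential at each voxel is the sum over pseudoatoms of the exact
analytic potential (nucleus + continuous electrons) within ``rcrit`` of
that atom and the multipolar far field beyond it.  Values are in atomic
units (e/Bohr for the potential, e/Bohr^3 for the density); grid geometry
is specified in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import harmonics
from .constants import ANGSTROM_TO_BOHR, atomic_number
from .density import MolecularDensityModel, evaluate_density, moments_racah
from .energy import pseudoatom_potential

__all__ = ["GridSpec", "VolumetricMap", "esp_on_grid", "isodensity_mask",
           "density_on_grid", "surface_voxels", "write_cube"]

#: Potential values are clipped at this magnitude (a.u.) at voxels that sit
#: essentially on a nucleus.
POTENTIAL_CAP = 1.0e4
LARGE_GRID_VOXELS = 40_000_000


@dataclass(frozen=True)
class GridSpec:
    """Cubic voxel grid: ``center``/``extent``/``voxel`` in Angstrom.

    ``extent`` / ``voxel`` must give integer dimensions.
    """

    center: tuple[float, float, float]
    extent: tuple[float, float, float]
    voxel: float

    def __post_init__(self):
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        for e in self.extent:
            n = e / self.voxel
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"extent {e} is not an integer multiple of voxel {self.voxel}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.voxel)) for e in self.extent)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def origin(self) -> np.ndarray:
        """Center of the first voxel (Angstrom)."""
        c = np.asarray(self.center, dtype=float)
        e = np.asarray(self.extent, dtype=float)
        return c - e / 2.0 + self.voxel / 2.0

    def points(self) -> np.ndarray:
        """Voxel-center coordinates, shape (nx*ny*nz, 3), z fastest."""
        nx, ny, nz = self.shape
        o = self.origin
        ax = [o[k] + self.voxel * np.arange(n) for k, n in enumerate((nx, ny, nz))]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=-1)


@dataclass
class VolumetricMap:
    grid: GridSpec
    values: np.ndarray  # shape = grid.shape
    unit: str
    capped_voxels: int = 0


def _multipole_potential(atom, pts_bohr: np.ndarray, max_l: int = 4) -> np.ndarray:
    """Far-field potential (a.u.) of one atom's total-charge multipoles."""
    mom = moments_racah(atom, max_l)
    d = pts_bohr - atom.position * ANGSTROM_TO_BOHR
    r = np.linalg.norm(d, axis=-1)
    r = np.where(r > 0, r, 1e-30)
    v = np.zeros(len(d))
    for l in range(max_l + 1):
        if not np.any(mom[l]):
            continue
        cn = harmonics.racah_norm(l)
        for m in range(-l, l + 1):
            q = mom[l][m + l]
            if q != 0.0:
                v += q * cn * harmonics.real_sph_harm_xyz(l, m, d) / r ** (l + 1)
    return v


def esp_on_grid(
    model: MolecularDensityModel,
    grid: GridSpec,
    rcrit: float = 5.0,
    max_l: int = 4,
) -> VolumetricMap:
    """Total electrostatic potential map (e/Bohr): exact near field within
    ``rcrit`` (Angstrom) of each atom, multipolar far field beyond."""
    if grid.n_voxels > LARGE_GRID_VOXELS:
        import warnings

        warnings.warn(
            f"grid has {grid.n_voxels} voxels; this will be slow and "
            "memory-hungry", stacklevel=2)
    pts = grid.points()
    pts_bohr = pts * ANGSTROM_TO_BOHR
    v = np.zeros(len(pts))
    capped = np.zeros(len(pts), dtype=bool)
    for atom in model.atoms:
        d = np.linalg.norm(pts - atom.position, axis=-1)
        near = d <= rcrit
        if np.any(near):
            v[near] += pseudoatom_potential(atom, pts_bohr[near])
        far = ~near
        if np.any(far):
            v[far] += _multipole_potential(atom, pts_bohr[far], max_l)
        capped |= d < 1e-3
    n_capped = int(np.count_nonzero(capped))
    v = np.clip(v, -POTENTIAL_CAP, POTENTIAL_CAP)
    return VolumetricMap(grid, v.reshape(grid.shape), "e/Bohr", n_capped)


def density_on_grid(
    model: MolecularDensityModel, grid: GridSpec, cutoff: float = 6.0
) -> VolumetricMap:
    """Total electron density map (e/Bohr^3); per-atom contributions are
    truncated beyond ``cutoff`` Angstrom where they are negligible."""
    pts = grid.points()
    rho = np.zeros(len(pts))
    for atom in model.atoms:
        d = np.linalg.norm(pts - atom.position, axis=-1)
        near = d <= cutoff
        if np.any(near):
            rho[near] += np.asarray(evaluate_density(atom, pts[near]))
    return VolumetricMap(grid, rho.reshape(grid.shape), "e/Bohr^3")


def isodensity_mask(
    model: MolecularDensityModel, grid: GridSpec, level: float = 0.002
) -> np.ndarray:
    """Boolean mask of voxels with electron density >= ``level`` (e/Bohr^3)."""
    if level <= 0:
        raise ValueError("iso-density level must be positive")
    return density_on_grid(model, grid).values >= level


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one of their 6 neighbors outside the mask."""
    inside = np.asarray(mask, dtype=bool)
    core = np.ones_like(inside)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(inside, shift, axis=axis)
            # treat out-of-grid as outside
            idx = [slice(None)] * 3
            idx[axis] = 0 if shift == 1 else -1
            rolled[tuple(idx)] = False
            core &= rolled
    return inside & ~core


def write_cube(
    path,
    vol: VolumetricMap,
    model: MolecularDensityModel | None = None,
    comment: str = "epmm volumetric map",
) -> None:
    """Write a Gaussian cube file (Bohr header convention)."""
    grid = vol.grid
    nx, ny, nz = grid.shape
    origin = grid.origin * ANGSTROM_TO_BOHR
    step = grid.voxel * ANGSTROM_TO_BOHR
    atoms = model.atoms if model is not None else []
    lines = [comment, f"values in {vol.unit}"]
    lines.append(f"{len(atoms):5d}{origin[0]:12.6f}{origin[1]:12.6f}{origin[2]:12.6f}")
    lines.append(f"{nx:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}")
    lines.append(f"{ny:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}")
    lines.append(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}")
    for a in atoms:
        z = atomic_number(a.parameters.element)
        p = a.position * ANGSTROM_TO_BOHR
        lines.append(f"{z:5d}{float(z):12.6f}{p[0]:12.6f}{p[1]:12.6f}{p[2]:12.6f}")
    flat = vol.values.reshape(nx * ny, nz)
    for row in flat:
        for k in range(0, nz, 6):
            lines.append("".join(f"{v:13.5E}" for v in row[k : k + 6]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
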