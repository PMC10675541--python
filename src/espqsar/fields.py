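"""Charge density and electrostatic potential on uniform 3D grids.

Conventions
-----------
* Length in Å, charge in units of the elementary charge e, Coulomb
  constant 1: the potential of a point charge q is phi(r) = q/r in e/Å.
  Only relative ESP patterns matter downstream, so no SI prefactor is
  carried.
* Grids are uniform and isotropic; field arrays are indexed
  ``values[ix, iy, iz]`` and node (i,j,k) sits at origin + spacing*(i,j,k).
* The default density backend is a signed promolecule model: each atom
  contributes an isotropic Gaussian carrying its partial charge, with
  width sigma = width_scale * r_vdw(element). It is analytic and fast;
  externally computed densities can be supplied as Gaussian cube files
  instead.
* Poisson's equation is solved with free-space (zero-padded) boundary
  conditions by spectral convolution of the density with the 1/r kernel,
  so an isolated Gaussian charge reproduces q*erf(r/(sigma*sqrt(2)))/r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import fft as sfft

from .chemio import Molecule, vdw_radius

__all__ = [
    "GridSpec",
    "ScalarField",
    "DensityBackend",
    "PromoleculeBackend",
    "CubeBackend",
    "build_common_box",
    "promolecule_density",
    "solve_poisson",
    "read_cube",
    "write_cube",
    "BOHR_TO_ANGSTROM",
]

BOHR_TO_ANGSTROM = 0.529177210903

# Mean of 1/r over a unit cube centred on the singularity; used as the
# self-cell value of the discretised Coulomb kernel.
_CUBE_SELF_INTEGRAL = 2.3800774


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular grid: origin (Å), isotropic spacing (Å), node counts."""

    origin: tuple[float, float, float]
    spacing: float
    npoints: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(n < 2 for n in self.npoints):
            raise ValueError("grids need at least 2 nodes per axis")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "npoints", tuple(int(n) for n in self.npoints))

    @property
    def size(self) -> int:
        nx, ny, nz = self.npoints
        return nx * ny * nz

    @property
    def dV(self) -> float:
        return self.spacing ** 3

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.npoints[a])
            for a in range(3)
        )

    @property
    def center(self) -> np.ndarray:
        return np.array(
            [self.origin[a] + self.spacing * (self.npoints[a] - 1) / 2.0
             for a in range(3)]
        )

    def coarsen(self, stride: int = 2) -> "GridSpec":
        """Subsample every ``stride``-th node (same origin); node positions of
        the coarse grid are a subset of the fine grid's."""
        return GridSpec(
            origin=self.origin,
            spacing=self.spacing * stride,
            npoints=tuple((n - 1) // stride + 1 for n in self.npoints),
        )


@dataclass
class ScalarField:
    """A real scalar field (charge density or potential) on a GridSpec."""

    grid: GridSpec
    kind: Literal["density", "potential"]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.npoints:
            raise ValueError(
                f"field shape {self.values.shape} != grid {self.grid.npoints}"
            )

    def integral(self) -> float:
        """Volume integral of the field (total charge for a density)."""
        return float(self.values.sum() * self.grid.dV)

    def flatten(self) -> np.ndarray:
        """x-fastest node order (first index varies fastest)."""
        return self.values.flatten(order="F")


def build_common_box(
    molecules: Sequence[Molecule], spacing: float, margin: float = 2.7
) -> GridSpec:
    """Common grid box of a molecular subset.

    Each axis edge is the largest van der Waals extent of any molecule
    along that axis plus ``margin`` (appended once per axis, giving room
    for rotation and translation). Node count per axis is
    floor(edge/spacing)+1 and the box is centred on the coordinate origin.
    """
    if not molecules:
        raise ValueError("cannot build a box for an empty molecule list")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    extent = np.zeros(3)
    for mol in molecules:
        coords = mol.coords
        radii = np.array([vdw_radius(e) for e in mol.elements])
        hi = (coords + radii[:, None]).max(axis=0)
        lo = (coords - radii[:, None]).min(axis=0)
        extent = np.maximum(extent, hi - lo)
    edge = extent + margin
    npoints = tuple(int(np.floor(e / spacing + 1e-9)) + 1 for e in edge)
    origin = tuple(-(n - 1) * spacing / 2.0 for n in npoints)
    return GridSpec(origin=origin, spacing=spacing, npoints=npoints)


def promolecule_density(
    molecule: Molecule, grid: GridSpec, width_scale: float = 0.5
) -> ScalarField:
    """Signed promolecule charge density on ``grid``.

    rho(x) = sum_a q_a (2 pi sigma_a^2)^(-3/2) exp(-|x-R_a|^2 / 2 sigma_a^2)
    with sigma_a = width_scale * r_vdw(element_a). Each atomic Gaussian
    integrates to the atom's partial charge, so the field integral equals
    the molecular net charge when the molecule sits well inside the box.
    """
    if width_scale <= 0:
        raise ValueError("width_scale must be positive")
    ax, ay, az = grid.axes()
    rho = np.zeros(grid.npoints)
    lo = np.array([ax[0], ay[0], az[0]])
    hi = np.array([ax[-1], ay[-1], az[-1]])
    truncated = []
    for atom in molecule.atoms:
        sigma = width_scale * vdw_radius(atom.element)
        if np.any(atom.position - 2 * sigma < lo) or np.any(
            atom.position + 2 * sigma > hi
        ):
            truncated.append(atom.element)
        norm = atom.charge * (2.0 * np.pi * sigma * sigma) ** -1.5
        inv2s2 = 1.0 / (2.0 * sigma * sigma)
        # evaluate on a local sub-block: contributions beyond 6 sigma are
        # below double precision relative to the peak
        cut = 6.0 * sigma
        ix = np.searchsorted(ax, [atom.position[0] - cut, atom.position[0] + cut])
        iy = np.searchsorted(ay, [atom.position[1] - cut, atom.position[1] + cut])
        iz = np.searchsorted(az, [atom.position[2] - cut, atom.position[2] + cut])
        sx = slice(max(ix[0] - 1, 0), min(ix[1] + 1, len(ax)))
        sy = slice(max(iy[0] - 1, 0), min(iy[1] + 1, len(ay)))
        sz = slice(max(iz[0] - 1, 0), min(iz[1] + 1, len(az)))
        dx2 = (ax[sx] - atom.position[0]) ** 2
        dy2 = (ay[sy] - atom.position[1]) ** 2
        dz2 = (az[sz] - atom.position[2]) ** 2
        r2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        rho[sx, sy, sz] += norm * np.exp(-r2 * inv2s2)
    if truncated:
        warnings.warn(
            f"molecule {molecule.id!r}: {len(truncated)} atoms within 2 sigma "
            "of a box face; density truncated"
        )
    return ScalarField(grid=grid, kind="density", values=rho)


def _coulomb_kernel(npoints, spacing, padded_shape):
    """1/r kernel sampled on the padded lattice with circular index layout."""
    idx = []
    for n_pad in padded_shape:
        offs = np.arange(n_pad)
        # signed lattice offsets with wraparound: 0,1,...,-2,-1
        offs = np.where(offs <= n_pad // 2, offs, offs - n_pad)
        idx.append(offs * spacing)
    dx, dy, dz = np.meshgrid(*idx, indexing="ij", sparse=True)
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    with np.errstate(divide="ignore"):
        ker = 1.0 / r
    ker[0, 0, 0] = _CUBE_SELF_INTEGRAL / spacing
    return ker


def solve_poisson(density: ScalarField) -> ScalarField:
    """Free-space electrostatic potential of a gridded charge density.

    phi(x) = sum_y rho(y) dV / |x - y|, evaluated for all nodes at once by
    zero-padded FFT convolution with the 1/r kernel (the kernel's singular
    cell uses the cell-averaged value). Zero padding by a factor 2 per
    axis makes the convolution linear, not circular, so there are no
    periodic-image charges.
    """
    if not np.all(np.isfinite(density.values)):
        raise ValueError("density contains non-finite values")
    if density.kind != "density":
        raise ValueError("solve_poisson expects a density field")
    n = density.grid.npoints
    padded = tuple(sfft.next_fast_len(2 * ni) for ni in n)
    ker = _coulomb_kernel(n, density.grid.spacing, padded)
    rho_hat = sfft.rfftn(density.values, s=padded)
    ker_hat = sfft.rfftn(ker)
    phi = sfft.irfftn(rho_hat * ker_hat, s=padded)[: n[0], : n[1], : n[2]]
    phi = phi * density.grid.dV
    return ScalarField(grid=density.grid, kind="potential", values=phi)


# ---------------------------------------------------------------------------
# density backends
# ---------------------------------------------------------------------------

class DensityBackend:
    """Produces a charge-density ScalarField for a molecule on any grid."""

    name: str

    def density(self, molecule: Molecule, grid: GridSpec) -> ScalarField:
        raise NotImplementedError


class PromoleculeBackend(DensityBackend):
    """Analytic atom-centred Gaussian partial-charge density (the default)."""

    name = "promolecule"

    def __init__(self, width_scale: float = 0.5):
        if width_scale <= 0:
            raise ValueError("width_scale must be positive")
        self.width_scale = width_scale

    def density(self, molecule: Molecule, grid: GridSpec) -> ScalarField:
        return promolecule_density(molecule, grid, self.width_scale)


class CubeBackend(DensityBackend):
    """Serves pre-computed densities from Gaussian cube files, resampled
    onto the requested grid by trilinear interpolation."""

    name = "cube"

    def __init__(self, cube_paths: dict[str, str]):
        self.cube_paths = dict(cube_paths)

    def density(self, molecule: Molecule, grid: GridSpec) -> ScalarField:
        from scipy.ndimage import map_coordinates

        if molecule.id not in self.cube_paths:
            raise KeyError(f"no cube file registered for molecule {molecule.id!r}")
        src = read_cube(self.cube_paths[molecule.id])
        ax = grid.axes()
        pts = np.meshgrid(*ax, indexing="ij")
        coords = [
            (p - src.grid.origin[a]) / src.grid.spacing
            for a, p in enumerate(pts)
        ]
        vals = map_coordinates(
            src.values, np.array(coords), order=1, mode="constant", cval=0.0
        )
        return ScalarField(grid=grid, kind="density", values=vals)


# ---------------------------------------------------------------------------
# Gaussian cube files
# ---------------------------------------------------------------------------

def write_cube(field: ScalarField, path, molecule: Molecule | None = None) -> None:
    """Write a Gaussian cube file. Lengths are written in Bohr (positive
    voxel counts), the format's native convention."""
    from .chemio import _periodic_table

    grid = field.grid
    atoms = molecule.atoms if molecule is not None else []
    pt = _periodic_table() if atoms else None
    with open(path, "w") as fh:
        fh.write("espqsar scalar field\n")
        fh.write(f"kind={field.kind}\n")
        o = [x / BOHR_TO_ANGSTROM for x in grid.origin]
        fh.write(f"{len(atoms):5d} {o[0]: .6f} {o[1]: .6f} {o[2]: .6f}\n")
        sp = grid.spacing / BOHR_TO_ANGSTROM
        for a in range(3):
            vec = [0.0, 0.0, 0.0]
            vec[a] = sp
            fh.write(
                f"{grid.npoints[a]:5d} {vec[0]: .6f} {vec[1]: .6f} {vec[2]: .6f}\n"
            )
        for atom in atoms:
            z = pt.GetAtomicNumber(atom.element)
            p = atom.position / BOHR_TO_ANGSTROM
            fh.write(f"{z:5d} {atom.charge: .6f} {p[0]: .6f} {p[1]: .6f} {p[2]: .6f}\n")
        flat = field.values.reshape(-1)  # z fastest, the cube convention
        for start in range(0, flat.size, 6):
            chunk = flat[start:start + 6]
            fh.write(" ".join(f"{v: .6E}" for v in chunk) + "\n")


def read_cube(path) -> ScalarField:
    """Read a Gaussian cube file.

    Positive voxel counts mean Bohr axes (converted to Å); negative counts
    mean the lengths are already in Å, per the format's sign convention.
    """
    with open(path) as fh:
        tokens_lines = fh.read().split("\n")
    kind = "density"
    if "potential" in tokens_lines[1]:
        kind = "potential"
    header = tokens_lines[2].split()
    natoms = int(header[0])
    origin = np.array([float(x) for x in header[1:4]])
    npoints = []
    spacings = []
    for a in range(3):
        parts = tokens_lines[3 + a].split()
        npoints.append(int(parts[0]))
        vec = np.array([float(x) for x in parts[1:4]])
        spacings.append(vec[a])
        off_axis = np.delete(vec, a)
        if np.any(np.abs(off_axis) > 1e-12):
            raise ValueError("only axis-aligned cube grids are supported")
    to_ang = BOHR_TO_ANGSTROM if npoints[0] > 0 else 1.0
    npoints = [abs(n) for n in npoints]
    origin = origin * to_ang
    spacings = [s * to_ang for s in spacings]
    if abs(spacings[0] - spacings[1]) > 1e-9 or abs(spacings[0] - spacings[2]) > 1e-9:
        raise ValueError("anisotropic cube spacing is not supported")
    data_start = 6 + abs(natoms)
    values = np.array(
        [float(t) for line in tokens_lines[data_start:] for t in line.split()]
    )
    expected = npoints[0] * npoints[1] * npoints[2]
    if values.size != expected:
        raise ValueError(
            f"cube data length {values.size} inconsistent with voxel counts "
            f"{npoints} (expected {expected})"
        )
    grid = GridSpec(
        origin=tuple(origin), spacing=float(spacings[0]), npoints=tuple(npoints)
    )
    return ScalarField(grid=grid, kind=kind, values=values.reshape(npoints))
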