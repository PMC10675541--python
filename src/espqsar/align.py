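"""Rigid pairwise field alignment of a target molecule against a template.

The template's electrostatic potential phi is computed once on the common
grid. Each target is posed in a set of sampled rotations ("rotamers");
for every rotamer the target's charge density rho is obtained by trilinear
interpolation of the unrotated density, and the overlap functional

    E(t) = sum_x phi(x) * rho(x + t) * dV

is evaluated for every integer-cell translation t at once via zero-padded
FFT cross-correlation. The alignment is the (rotamer, translation) pair
maximizing E.

Rotations are sampled deterministically with Hopf coordinates: a
Fibonacci lattice on the base 2-sphere crossed with an evenly spaced
circle fiber, lifted to unit quaternions. The construction is near-uniform
under the Haar measure and needs no random seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from .chemio import Molecule, vdw_radius
from .fields import DensityBackend, GridSpec, PromoleculeBackend, ScalarField, solve_poisson

__all__ = [
    "RotationSet",
    "AlignmentResult",
    "hopf_rotations",
    "rotate_molecule",
    "cross_correlation_map",
    "best_alignment",
    "align_subset",
    "quaternion_distance",
]


@dataclass(frozen=True)
class RotationSet:
    """Ordered unit quaternions (scalar-first), identity at index 0."""

    quaternions: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.quaternions, dtype=float)
        if q.ndim != 2 or q.shape[1] != 4:
            raise ValueError("quaternions must be an (n, 4) array")
        norms = np.linalg.norm(q, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("quaternions must be unit length")
        object.__setattr__(self, "quaternions", q)

    @property
    def count(self) -> int:
        return len(self.quaternions)

    def matrix(self, i: int) -> np.ndarray:
        return _quat_to_matrix(self.quaternions[i])


@dataclass
class AlignmentResult:
    """Winning rigid pose of a target against the template."""

    target_id: str
    rotation: np.ndarray        # unit quaternion, scalar first
    translation: np.ndarray     # Å; integer multiples of the grid spacing
    score: float                # E in e^2/Å * Å^3
    rotamer_index: int
    clipped_fraction: float = 0.0


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    # scipy uses scalar-last ordering
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def quaternion_distance(q1: np.ndarray, q2: np.ndarray) -> float:
    """Geodesic distance on SO(3) via arccos |q1 . q2| (radians, max pi/2)."""
    return float(np.arccos(min(1.0, abs(float(np.dot(q1, q2))))))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform (theta, phi) lattice on S^2."""
    i = np.arange(n) + 0.5
    theta = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = np.mod(golden * i, 2.0 * np.pi)
    return np.column_stack([theta, phi])


def hopf_rotations(n: int) -> RotationSet:
    """Deterministic near-uniform sample of n rotations from SO(3).

    Uses the Hopf lift q = (cos(theta/2) cos(psi/2),
    cos(theta/2) sin(psi/2), sin(theta/2) cos(phi + psi/2),
    sin(theta/2) sin(phi + psi/2)) of a Fibonacci lattice on the base
    sphere crossed with an even circle grid on the fiber. The identity
    rotation is always element 0.
    """
    if n < 1:
        raise ValueError("rotation count must be at least 1")
    quats = [np.array([1.0, 0.0, 0.0, 0.0])]
    m = n - 1
    if m > 0:
        # balance fiber and base resolutions: fiber step pi/m1 matches the
        # base lattice spacing ~ sqrt(pi/m2) when m1 ~ (pi * m)^(1/3)
        m1 = max(1, int(round((np.pi * m) ** (1.0 / 3.0))))
        m2 = int(np.ceil(m / m1))
        base = _fibonacci_sphere(m2)
        out = []
        for theta, phi in base:
            ct, st = np.cos(theta / 2.0), np.sin(theta / 2.0)
            for j in range(m1):
                psi = 2.0 * np.pi * (j + 0.5) / m1
                out.append(
                    [
                        ct * np.cos(psi / 2.0),
                        ct * np.sin(psi / 2.0),
                        st * np.cos(phi + psi / 2.0),
                        st * np.sin(phi + psi / 2.0),
                    ]
                )
        quats.extend(out[:m])
    q = np.array(quats)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return RotationSet(quaternions=q)


def rotate_molecule(
    molecule: Molecule, q: np.ndarray, center: np.ndarray | None = None
) -> Molecule:
    """Rigidly rotate a molecule about ``center`` (default: origin)."""
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-9:
        raise ValueError("rotation quaternion must be unit length")
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    R = _quat_to_matrix(q)
    coords = (molecule.coords - c) @ R.T + c
    return molecule.with_coords(coords)


def cross_correlation_map(
    phi_template: ScalarField, rho_target: ScalarField
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap E(t) = sum_x phi(x) rho(x+t) dV for every integer-cell shift.

    Zero-padded (linear) correlation: density never wraps across box faces.
    Returns ``(shifts, emap)`` where ``shifts[a]`` holds the signed cell
    offsets along axis a, from -(n_a - 1) to n_a - 1, and ``emap`` is the
    corresponding (2 n_x - 1, 2 n_y - 1, 2 n_z - 1) map of E values.
    """
    if phi_template.grid != rho_target.grid:
        raise ValueError("template and target fields must share one grid")
    n = phi_template.grid.npoints
    full = tuple(2 * ni - 1 for ni in n)
    padded = tuple(sfft.next_fast_len(f) for f in full)
    phi_hat = sfft.rfftn(phi_template.values, s=padded)
    rho_hat = sfft.rfftn(rho_target.values, s=padded)
    corr = sfft.irfftn(np.conj(phi_hat) * rho_hat, s=padded)
    # circular index k corresponds to shift t = k (mod padded); fold to
    # the signed range -(n-1)..(n-1)
    emap = np.empty(full)
    shifts = []
    for a, ni in enumerate(n):
        shifts.append(np.arange(-(ni - 1), ni))
    ix = [np.mod(s, p) for s, p in zip(shifts, padded)]
    emap = corr[np.ix_(*ix)] * phi_template.grid.dV
    return [np.asarray(s) for s in shifts], emap


def _interpolated_rotamer_density(
    rho0: np.ndarray, grid: GridSpec, R: np.ndarray
) -> np.ndarray:
    """Density of the rotated molecule, by pulling grid nodes back through
    the inverse rotation about the grid center and sampling rho0 trilinearly.
    Nodes mapping outside the original support contribute zero."""
    ax = grid.axes()
    c = grid.center
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X - c[0], Y - c[1], Z - c[2]], axis=-1)
    back = pts @ R + c  # pts @ R == R^T applied to each row (inverse rotation)
    frac = [
        (back[..., a] - grid.origin[a]) / grid.spacing for a in range(3)
    ]
    return map_coordinates(
        rho0, np.array(frac), order=1, mode="constant", cval=0.0
    )


def center_in_box(molecule: Molecule, grid: GridSpec) -> Molecule:
    """Translate so the molecule's vdW bounding-box center sits at the grid
    center (the template's pinned pose; also each target's starting pose)."""
    coords = molecule.coords
    radii = np.array([vdw_radius(e) for e in molecule.elements])
    hi = (coords + radii[:, None]).max(axis=0)
    lo = (coords - radii[:, None]).min(axis=0)
    shift = grid.center - (hi + lo) / 2.0
    return molecule.with_coords(coords + shift)


def best_alignment(
    template: Molecule,
    target: Molecule,
    rotations: RotationSet,
    grid: GridSpec,
    backend: DensityBackend | None = None,
    clip_warn_fraction: float = 0.02,
) -> AlignmentResult:
    """Exhaustive maximum of E over all rotamers and integer translations.

    The template (pinned with its vdW bounding-box centre at the grid
    centre) supplies phi, solved once. The target is taken in the pose
    given — callers wanting a centred start (as ``align_subset`` does)
    centre it first — its density is evaluated once and re-sampled per
    rotamer by trilinear interpolation. The reported translation is the
    displacement applied to the rotated target to align it. Ties are
    broken by lower rotamer index, then lexicographically smaller
    translation.
    """
    backend = backend or PromoleculeBackend()
    template_c = center_in_box(template, grid)
    phi = solve_poisson(backend.density(template_c, grid))
    rho0 = backend.density(target, grid).values
    total_rho_abs = float(np.abs(rho0).sum())

    best = None  # (score, rotamer_index, shift_tuple, clipped)
    dV = grid.dV
    n = grid.npoints
    full = tuple(2 * ni - 1 for ni in n)
    padded = tuple(sfft.next_fast_len(f) for f in full)
    phi_hat_conj = np.conj(sfft.rfftn(phi.values, s=padded))
    shift_axes = [np.arange(-(ni - 1), ni) for ni in n]
    fold_ix = np.ix_(*[np.mod(s, p) for s, p in zip(shift_axes, padded)])

    for k in range(rotations.count):
        if k == 0:
            rho_k = rho0
        else:
            rho_k = _interpolated_rotamer_density(
                rho0, grid, rotations.matrix(k)
            )
        rho_hat = sfft.rfftn(rho_k, s=padded)
        emap = sfft.irfftn(phi_hat_conj * rho_hat, s=padded)[fold_ix] * dV
        flat = int(np.argmax(emap))
        score = float(emap.flat[flat])
        sx, sy, sz = np.unravel_index(flat, emap.shape)
        shift = (
            int(shift_axes[0][sx]),
            int(shift_axes[1][sy]),
            int(shift_axes[2][sz]),
        )
        clipped = 0.0
        if total_rho_abs > 0:
            clipped = 1.0 - float(np.abs(rho_k).sum()) / total_rho_abs
        cand = (score, k, shift, clipped)
        if best is None or _beats(cand, best):
            best = cand
        # resolve exact ties within the same rotamer map deterministically
        ties = np.argwhere(emap == score)
        if len(ties) > 1:
            tie_shifts = sorted(
                tuple(int(shift_axes[a][t[a]]) for a in range(3)) for t in ties
            )
            cand = (score, k, tie_shifts[0], clipped)
            if _beats(cand, best):
                best = cand

    score, k, shift, clipped = best
    if clipped > clip_warn_fraction:
        warnings.warn(
            f"target {target.id!r}: {clipped:.1%} of density clipped at the "
            "box boundary in the winning pose"
        )
    # E(t) peaks where the rotated density sits at +t cells relative to the
    # template, so the aligning move is -t.
    translation = -np.array(shift, dtype=float) * grid.spacing
    return AlignmentResult(
        target_id=target.id,
        rotation=rotations.quaternions[k].copy(),
        translation=translation,
        score=score,
        rotamer_index=k,
        clipped_fraction=clipped,
    )


def _beats(cand, best) -> bool:
    """Higher score wins; ties: lower rotamer index, then smaller shift."""
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] < best[1]
    return cand[2] < best[2]


def apply_alignment(
    molecule: Molecule, result: AlignmentResult, grid: GridSpec
) -> Molecule:
    """Aligned coordinates: rotate by the winning rotamer about the grid
    centre, then translate by the winning displacement. ``molecule`` must be
    in the same starting pose that was passed to ``best_alignment``."""
    posed = rotate_molecule(molecule, result.rotation, center=grid.center)
    return posed.with_coords(posed.coords + result.translation)


def align_subset(
    subset,
    molecules,
    grid: GridSpec,
    rotations: RotationSet,
    backend: DensityBackend | None = None,
    template: Molecule | None = None,
) -> tuple[list[AlignmentResult], list[Molecule]]:
    """Pairwise-align every non-template member of a subset to its template.

    Returns per-target results (sorted by member order) and the aligned
    molecules, template first and unchanged apart from centring in the box.
    One molecule's failure is reported but does not abort the others.
    """
    from .chemio import select_template

    backend = backend or PromoleculeBackend()
    by_id = {m.id: m for m in molecules}
    if template is None:
        template = select_template(subset, molecules)
    aligned = [center_in_box(template, grid)]
    results: list[AlignmentResult] = []
    for mid in subset.members:
        if mid == template.id or mid not in by_id:
            continue
        # centred starting pose keeps every target's density inside the box
        target = center_in_box(by_id[mid], grid)
        try:
            res = best_alignment(template, target, rotations, grid, backend)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"alignment of {mid!r} failed: {exc}")
            continue
        results.append(res)
        aligned.append(apply_alignment(target, res, grid))
    return results, aligned
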