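"""Seeded synthetic benchmark with known ground truth.

The generator emulates the shape of a hERG-blocker QSAR study — seven
molecular-weight bands of 70 molecules spanning 250–600 amu with pIC50
activities — using abstract rigid point-charge clusters instead of real
chemistry. Each band is built as a congeneric series: one random scaffold
per band, whose members differ by element substitutions (spreading the
molecular weight across the band), small zero-sum charge perturbations
and sub-0.1 Å coordinate jitter. A series of closely related structures
gives the pairwise field alignment a well-defined answer, as real QSAR
subsets of analogous molecules do.

Activities come from a known "teacher": a linear function of the leading
principal-component scores of the members' canonical-pose ESP
descriptors, mapped into a stated pIC50 window (default 3.5–9.0), plus
optional Gaussian noise. The teacher, scores and noise draws are stored
so recovery tests can compare against ground truth.

Everything is a pure function of the generation spec: the same spec
yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import (
    Atom,
    Molecule,
    atomic_mass,
    subset_bounds,
    write_xyz_charges,
)
from .fields import GridSpec, PromoleculeBackend, build_common_box

__all__ = [
    "SyntheticSpec",
    "make_toy_molecule",
    "make_benchmark",
    "write_benchmark",
    "plant_transform",
]

_ELEMENTS = ("C", "N", "O", "S", "Cl")
# substitutions of a scaffold carbon, heaviest first, for hitting a MW target
_SUBS = ("Cl", "S", "O", "N")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the dataset is a pure function of this spec."""

    n_subsets: int = 7
    members_per_subset: int = 70
    atoms_per_molecule: tuple[int, int] | None = None  # None: scaled per band
    charge_scale: float = 1.0       # member charges lie in ±0.5 * charge_scale e
    teacher: str = "linear"          # "linear" | "network"
    n_teacher_scores: int = 5
    noise_sd: float = 0.0            # pIC50 units
    pic50_range: tuple[float, float] = (3.5, 9.0)
    truth_spacing: float = 0.8       # Å, grid for ground-truth descriptors
    margin: float = 2.7
    hard_mode: bool = False          # re-pose members by random rigid moves
    seed: int = 0
    noise_seed: int | None = None    # None: derived from seed; set to vary
                                     # noise draws while keeping molecules fixed


def _composition(n_atoms: int, mw_target: float) -> list[str]:
    """Element list of an n-atom cluster with total mass within 5 amu of
    ``mw_target``: an all-carbon scaffold with heavy-atom substitutions
    applied greedily, heaviest first."""
    m_c = atomic_mass("C")
    lo = n_atoms * m_c
    hi = n_atoms * atomic_mass("Cl")
    if not (lo - 5.0 <= mw_target <= hi + 5.0):
        raise ValueError(
            f"mw_target {mw_target} infeasible for {n_atoms} atoms "
            f"(range {lo:.0f}-{hi:.0f} amu)"
        )
    elements = ["C"] * n_atoms
    diff = mw_target - lo
    slot = 0
    for sub in _SUBS:
        delta = atomic_mass(sub) - m_c
        while diff >= delta and slot < n_atoms:
            elements[slot] = sub
            diff -= delta
            slot += 1
    if diff > 5.0 and slot < n_atoms:
        # slots are scarce: allow one substitution to overshoot if that
        # lands closer to the target
        sub = min(_SUBS, key=lambda s: abs(diff - (atomic_mass(s) - m_c)))
        delta = atomic_mass(sub) - m_c
        if abs(diff - delta) < diff:
            elements[slot] = sub
            diff -= delta
            slot += 1
    if abs(diff) > 5.0:
        raise ValueError(
            f"mw_target {mw_target} not reachable within 5 amu for "
            f"{n_atoms} atoms"
        )
    return elements


def _cluster_positions(rng: np.random.Generator, n_atoms: int, radius: float,
                       min_sep: float = 1.2) -> np.ndarray:
    """Random positions in a ball with a soft minimum-separation rule."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_atoms:
        p = rng.uniform(-radius, radius, size=3)
        tries += 1
        if np.dot(p, p) > radius * radius:
            continue
        if pts and tries < 200 * n_atoms:
            d = np.linalg.norm(np.array(pts) - p, axis=1)
            if d.min() < min_sep:
                continue
        pts.append(p)
    arr = np.array(pts)
    return arr - arr.mean(axis=0)


def make_toy_molecule(
    seed: int, n_atoms: int, mw_target: float,
    mol_id: str | None = None, charge_scale: float = 1.0,
) -> Molecule:
    """One random rigid charged cluster with mass close to ``mw_target``.

    Atoms are drawn from {C, N, O, S, Cl} with positions inside a ball
    (never larger than 12 Å) and zero-sum partial charges in
    ±0.5*charge_scale e. Deterministic in ``seed``.
    """
    if n_atoms < 3:
        raise ValueError("toy molecules need at least 3 atoms")
    rng = np.random.default_rng(seed)
    elements = _composition(n_atoms, mw_target)
    rng.shuffle(elements)
    radius = min(12.0, max(1.8, 0.9 * n_atoms ** (1.0 / 3.0) * 1.6))
    pos = _cluster_positions(rng, n_atoms, radius)
    charges = rng.uniform(-0.5, 0.5, size=n_atoms) * charge_scale
    charges -= charges.mean()
    atoms = [Atom(e, p, float(q)) for e, p, q in zip(elements, pos, charges)]
    return Molecule(id=mol_id or f"toy{seed}", atoms=atoms)


def _band_atom_count(subset_index: int) -> int:
    low, high = subset_bounds(subset_index)
    return int(round((low + high) / 2.0 / 19.0))


@dataclass
class SyntheticDataset:
    """In-memory benchmark: molecules, activities and the ground truth."""

    spec: SyntheticSpec
    molecules: list[Molecule]
    activities: pd.DataFrame       # columns id, mw, pic50
    truth: dict = field(default_factory=dict)


def make_benchmark(spec: SyntheticSpec) -> SyntheticDataset:
    """Build the full synthetic benchmark defined by ``spec``.

    Defaults produce 490 molecules, 70 per 50-amu band. Activities apply
    the teacher to the leading PCA scores of each band's canonical-pose
    ESP descriptors, rescaled into ``spec.pic50_range``, plus Gaussian
    noise of ``spec.noise_sd``.
    """
    from .descriptors import descriptor_matrix, pca_fit, pca_project

    master = np.random.default_rng(spec.seed)
    subset_seeds = master.integers(0, 2**31 - 1, size=spec.n_subsets)
    noise_base = spec.noise_seed if spec.noise_seed is not None else spec.seed
    noise_rng = np.random.default_rng(
        np.random.default_rng(noise_base + 7_654_321).integers(0, 2**31 - 1)
    )
    backend = PromoleculeBackend()
    molecules: list[Molecule] = []
    act_rows = []
    truth: dict = {"subsets": {}, "spec_seed": spec.seed}

    for k in range(1, spec.n_subsets + 1):
        rng = np.random.default_rng(subset_seeds[k - 1])
        low, high = subset_bounds(k)
        n_atoms = (
            _band_atom_count(k)
            if spec.atoms_per_molecule is None
            else int(rng.integers(*spec.atoms_per_molecule))
        )
        radius = 1.9 + 0.13 * (k - 1)
        scaffold_pos = _cluster_positions(rng, n_atoms, radius)
        scaffold_q = rng.uniform(-0.5, 0.5, size=n_atoms) * spec.charge_scale
        scaffold_q -= scaffold_q.mean()
        sub_order = rng.permutation(n_atoms)

        nm = spec.members_per_subset
        mw_targets = low + 6.0 + (high - low - 12.0) * np.arange(nm) / max(nm - 1, 1)
        members = []
        for j in range(nm):
            elements = _composition(n_atoms, mw_targets[j])
            # substitute scaffold atoms in one fixed order so members form
            # an incremental series
            ordered = ["C"] * n_atoms
            subs = [e for e in elements if e != "C"]
            for s_i, e in enumerate(subs):
                ordered[sub_order[s_i]] = e
            jitter = rng.normal(0.0, 0.03, size=(n_atoms, 3))
            dq = rng.uniform(-0.15, 0.15, size=n_atoms) * spec.charge_scale
            dq -= dq.mean()
            atoms = [
                Atom(e, scaffold_pos[i] + jitter[i], float(scaffold_q[i] + dq[i]))
                for i, e in enumerate(ordered)
            ]
            members.append(Molecule(id=f"S{k}M{j:03d}", atoms=atoms))

        # ground-truth descriptors in the canonical (as-generated) pose
        grid = build_common_box(members, spec.truth_spacing, spec.margin)
        desc = descriptor_matrix(members, grid.coarsen(2), backend)
        n_scores = min(spec.n_teacher_scores, nm)
        pca = pca_fit(desc, n_comp=n_scores)
        scores = pca_project(pca, desc.rows)
        if spec.teacher == "linear":
            w = rng.normal(size=n_scores)
            raw = scores @ w
        elif spec.teacher == "network":
            w1 = rng.uniform(-0.5, 0.5, size=(n_scores, 8))
            w2 = rng.uniform(-0.5, 0.5, size=8)
            s_scale = np.sqrt(np.mean(scores**2, axis=0))
            s_scale[s_scale == 0] = 1.0
            from scipy.special import expit

            raw = expit((scores / s_scale) @ w1) @ w2
        else:
            raise ValueError(f"unknown teacher kind {spec.teacher!r}")
        span = raw.max() - raw.min()
        if span == 0:
            span = 1.0
        lo_p, hi_p = spec.pic50_range
        clean = lo_p + (raw - raw.min()) / span * (hi_p - lo_p)
        noise = noise_rng.normal(0.0, spec.noise_sd, size=nm) if spec.noise_sd else np.zeros(nm)
        pic50 = clean + noise

        if spec.hard_mode:
            members = [
                _random_rigid(rng, m) if j != int(np.argmax([m.mw for m in members])) else m
                for j, m in enumerate(members)
            ]

        for m, y in zip(members, pic50):
            m.pic50 = float(y)
            act_rows.append({"id": m.id, "mw": m.mw, "pic50": float(y)})
        molecules.extend(members)
        truth["subsets"][k] = {
            "teacher": spec.teacher,
            "teacher_weights": np.asarray(w if spec.teacher == "linear" else w2).tolist(),
            "scores": scores.tolist(),
            "clean_pic50": clean.tolist(),
            "noise": noise.tolist(),
            "scaffold_atoms": n_atoms,
        }

    activities = pd.DataFrame(act_rows, columns=["id", "mw", "pic50"])
    return SyntheticDataset(
        spec=spec, molecules=molecules, activities=activities, truth=truth
    )


def _random_rigid(rng: np.random.Generator, mol: Molecule) -> Molecule:
    from .align import rotate_molecule

    v = rng.normal(size=4)
    q = v / np.linalg.norm(v)
    shift = rng.uniform(-1.0, 1.0, size=3)
    rotated = rotate_molecule(mol, q, center=mol.coords.mean(axis=0))
    return rotated.with_coords(rotated.coords + shift)


def write_benchmark(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Emit structures (XYZ-with-charges), activities CSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "structures": outdir / "molecules.xyz",
        "activities": outdir / "activities.csv",
        "truth": outdir / "truth.json",
    }
    write_xyz_charges(dataset.molecules, paths["structures"])
    dataset.activities.to_csv(paths["activities"], index=False, float_format="%.10f")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"spec": asdict(dataset.spec), "truth": dataset.truth},
            fh, indent=1, sort_keys=True,
        )
    return paths


def plant_transform(
    molecule: Molecule,
    rotation_index: int,
    shift_cells: tuple[int, int, int],
    rotations,
    grid: GridSpec,
) -> tuple[Molecule, dict]:
    """Re-pose a molecule so the alignment search should undo the move.

    The molecule — expected to already sit in the template-pinning pose
    (see ``align.center_in_box``) — is shifted by an integer number of
    grid cells and then rotated by the INVERSE of sampled rotation
    ``rotation_index`` about the grid centre. Aligning the planted
    molecule back against the original then selects that rotamer and the
    negated shift; the truth record carries both, plus the affine map for
    composition checks.
    """
    from .align import _quat_to_matrix

    q = rotations.quaternions[rotation_index]
    R_inv = _quat_to_matrix(q).T
    s = np.asarray(shift_cells, dtype=float) * grid.spacing
    c = grid.center
    coords = (molecule.coords + s - c) @ R_inv.T + c
    planted = molecule.with_coords(coords)
    from .chemio import vdw_radius

    radii = np.array([vdw_radius(e) for e in planted.elements])
    lo = (planted.coords - radii[:, None]).min(axis=0)
    hi = (planted.coords + radii[:, None]).max(axis=0)
    ax = grid.axes()
    box_lo = np.array([a[0] for a in ax])
    box_hi = np.array([a[-1] for a in ax])
    if np.any(lo < box_lo) or np.any(hi > box_hi):
        raise ValueError("planted pose leaves the grid box")
    truth = {
        "expected_rotamer": int(rotation_index),
        "expected_translation_cells": tuple(-int(x) for x in shift_cells),
        "R": R_inv,
        "t": c - R_inv @ c + R_inv @ s,
    }
    return planted, truth
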