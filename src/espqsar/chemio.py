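"""Molecule and activity-table I/O, molecular-weight partitioning and splits.

Molecules are rigid point-charge clouds: each atom carries an element
symbol, Cartesian coordinates in Å and a partial charge in units of the
elementary charge e. Activities are pIC50 values (−log10 of the molar
IC50 against the hERG channel). Datasets are partitioned into seven
50-amu molecular-weight bands covering 250–600 amu, each band is split
train:test (default 4:1), and the heaviest member of a band serves as
the alignment template.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Molecule",
    "SubsetTable",
    "BONDI_RADII",
    "atomic_mass",
    "vdw_radius",
    "compute_mw",
    "read_dataset",
    "read_xyz_charges",
    "write_xyz_charges",
    "read_sdf_charges",
    "write_sdf_charges",
    "read_activities",
    "partition_by_mw",
    "split_train_test",
    "select_template",
]

# Bondi (1964) van der Waals radii in Å, extended with common defaults.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "As": 1.85,
    "Se": 1.90,
    "Br": 1.85,
    "Kr": 2.02,
    "Te": 2.06,
    "I": 1.98,
    "Xe": 2.16,
}

_MW_LOW = 250.0
_MW_HIGH = 600.0
_BAND_WIDTH = 50.0
_N_SUBSETS = 7


def _periodic_table():
    from rdkit import Chem

    return Chem.GetPeriodicTable()


def atomic_mass(element: str) -> float:
    """Standard atomic weight of ``element`` in amu."""
    try:
        mass = _periodic_table().GetAtomicWeight(element)
    except Exception:
        mass = 0.0
    if mass <= 0:
        raise ValueError(f"unknown element symbol: {element!r}")
    return float(mass)


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius in Å (falls back to the RDKit table)."""
    if element in BONDI_RADII:
        return BONDI_RADII[element]
    try:
        r = float(_periodic_table().GetRvdw(element))
    except Exception:
        raise ValueError(f"no van der Waals radius for element {element!r}")
    if r <= 0:
        raise ValueError(f"no van der Waals radius for element {element!r}")
    return r


@dataclass(frozen=True)
class Atom:
    """A point atom: element symbol, position (Å) and partial charge (e)."""

    element: str
    position: np.ndarray
    charge: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        atomic_mass(self.element)  # validates the symbol


@dataclass
class Molecule:
    """An identified molecule: ordered atoms, molecular weight, optional pIC50."""

    id: str
    atoms: list[Atom]
    pic50: float | None = None
    mw: float = field(default=0.0)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if self.pic50 is not None and not math.isfinite(self.pic50):
            raise ValueError(f"molecule {self.id!r} has non-finite pIC50")
        computed = compute_mw(self)
        if self.mw:
            if abs(self.mw - computed) > 0.5:
                raise ValueError(
                    f"molecule {self.id!r}: declared mw {self.mw} differs from "
                    f"atomic-mass sum {computed:.3f} by more than 0.5 amu"
                )
        self.mw = computed

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Molecule(id=self.id, atoms=atoms, pic50=self.pic50)


@dataclass
class SubsetTable:
    """Membership and train/test labels of one molecular-weight band."""

    subset_index: int
    mw_range: tuple[float, float]
    members: list[str]
    split: dict[str, str] = field(default_factory=dict)

    def train_ids(self) -> list[str]:
        return [m for m in self.members if self.split.get(m) == "train"]

    def test_ids(self) -> list[str]:
        return [m for m in self.members if self.split.get(m) == "test"]


def compute_mw(molecule: Molecule) -> float:
    """Sum of standard atomic weights over the molecule's atoms, in amu."""
    return float(sum(atomic_mass(a.element) for a in molecule.atoms))


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_xyz_charges(molecules: Iterable[Molecule], path) -> None:
    """Multi-record XYZ with a 5th per-atom column holding the partial charge."""
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{len(mol.atoms)}\n{mol.id}\n")
            for a in mol.atoms:
                x, y, z = a.position
                fh.write(
                    f"{a.element} {x: .10f} {y: .10f} {z: .10f} {a.charge: .10f}\n"
                )


def read_xyz_charges(path) -> list[Molecule]:
    """Read the multi-record XYZ-with-charge dialect written by this package."""
    molecules: list[Molecule] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    record = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        record += 1
        try:
            natoms = int(lines[i].split()[0])
            mol_id = lines[i + 1].strip()
            atoms = []
            for j in range(natoms):
                parts = lines[i + 2 + j].split()
                atoms.append(
                    Atom(
                        element=parts[0],
                        position=np.array([float(p) for p in parts[1:4]]),
                        charge=float(parts[4]) if len(parts) > 4 else 0.0,
                    )
                )
        except (IndexError, ValueError) as exc:
            raise ValueError(f"unparsable XYZ record #{record} in {path}: {exc}")
        molecules.append(Molecule(id=mol_id, atoms=atoms))
        i += 2 + natoms
    return molecules


_CHARGE_PROP = "PARTIAL_CHARGES"


def write_sdf_charges(molecules: Iterable[Molecule], path) -> None:
    """Write molecules to an SDF (V2000); partial charges go into the
    ``PARTIAL_CHARGES`` SD property, one value per atom per line."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    try:
        for mol in molecules:
            rw = Chem.RWMol()
            for a in mol.atoms:
                rw.AddAtom(Chem.Atom(a.element))
            conf = Chem.Conformer(len(mol.atoms))
            for i, a in enumerate(mol.atoms):
                conf.SetAtomPosition(i, Point3D(*map(float, a.position)))
            m = rw.GetMol()
            m.AddConformer(conf)
            m.SetProp("_Name", mol.id)
            m.SetProp(_CHARGE_PROP, "\n".join(f"{a.charge:.10f}" for a in mol.atoms))
            m.UpdatePropertyCache(strict=False)
            writer.write(m)
    finally:
        writer.close()


def read_sdf_charges(path) -> list[Molecule]:
    """Read an SDF with per-atom partial charges in ``PARTIAL_CHARGES``."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    molecules = []
    for idx, m in enumerate(supplier):
        if m is None:
            raise ValueError(f"unparsable SDF record index {idx} in {path}")
        if m.GetNumConformers() == 0:
            raise ValueError(f"SDF record index {idx} has no coordinates")
        conf = m.GetConformer()
        coords = conf.GetPositions()
        if np.allclose(coords[:, 2], 0.0) and not conf.Is3D():
            raise ValueError(
                f"SDF record index {idx} lacks 3D coordinates (flat 2D depiction)"
            )
        if m.HasProp(_CHARGE_PROP):
            charges = [float(v) for v in m.GetProp(_CHARGE_PROP).split()]
            if len(charges) != m.GetNumAtoms():
                raise ValueError(
                    f"SDF record index {idx}: {len(charges)} charges for "
                    f"{m.GetNumAtoms()} atoms"
                )
        else:
            charges = [0.0] * m.GetNumAtoms()
        atoms = [
            Atom(
                element=atom.GetSymbol(),
                position=np.asarray(coords[i], dtype=float),
                charge=charges[i],
            )
            for i, atom in enumerate(m.GetAtoms())
        ]
        name = m.GetProp("_Name") if m.HasProp("_Name") else f"mol{idx}"
        molecules.append(Molecule(id=name, atoms=atoms))
    return molecules


def read_structures(path) -> list[Molecule]:
    path = Path(path)
    if path.suffix.lower() in {".sdf", ".sd", ".mol"}:
        return read_sdf_charges(path)
    return read_xyz_charges(path)


def read_activities(path) -> pd.DataFrame:
    """Activity CSV with columns ``id`` and ``pic50`` (``mw`` optional)."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "pic50" not in df.columns:
        raise ValueError(f"activity table {path} needs columns id,pic50")
    return df


def read_dataset(structures_path, activities_path) -> list[Molecule]:
    """Join structures with the activity table on exact id match.

    Activity rows whose id has no structure are dropped with a warning;
    duplicate ids on either side are an error. Molecular weights are always
    recomputed from the atoms.
    """
    molecules = read_structures(structures_path)
    ids = [m.id for m in molecules]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule ids in structure file: {dup}")
    activities = read_activities(activities_path)
    if activities["id"].duplicated().any():
        dup = sorted(activities.loc[activities["id"].duplicated(), "id"])
        raise ValueError(f"duplicate ids in activity table: {dup}")
    act = dict(zip(activities["id"], activities["pic50"]))
    unmatched = sorted(set(act) - set(ids))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} activity rows without a structure were "
            f"dropped: {unmatched[:5]}{'...' if len(unmatched) > 5 else ''}"
        )
    out = []
    for mol in molecules:
        pic50 = act.get(mol.id)
        out.append(
            Molecule(id=mol.id, atoms=mol.atoms,
                     pic50=float(pic50) if pic50 is not None else None)
        )
    return out


# ---------------------------------------------------------------------------
# partitioning, splitting, template selection
# ---------------------------------------------------------------------------

def subset_bounds(subset_index: int) -> tuple[float, float]:
    """Half-open band (low, high] of subset k; band 1 is closed at 250 amu."""
    low = _MW_LOW + _BAND_WIDTH * (subset_index - 1)
    return low, low + _BAND_WIDTH


def subset_of_mw(mw: float) -> int | None:
    """Band index 1–7 for a molecular weight, or None when out of range."""
    if mw < _MW_LOW or mw > _MW_HIGH:
        return None
    if mw == _MW_LOW:
        return 1
    return min(_N_SUBSETS, int(math.ceil((mw - _MW_LOW) / _BAND_WIDTH)))


def partition_by_mw(
    molecules: Sequence[Molecule], *, strict: bool = False
) -> list[SubsetTable]:
    """Assign each molecule to one of seven contiguous 50-amu bands.

    The bands are (250,300], (300,350], …, (550,600] with 250 included in
    band 1, so every real-valued weight in [250, 600] lands in exactly one
    band. Out-of-range molecules are excluded with a warning, or raise when
    ``strict`` is set.
    """
    members: dict[int, list[str]] = {k: [] for k in range(1, _N_SUBSETS + 1)}
    excluded = []
    for mol in molecules:
        k = subset_of_mw(mol.mw)
        if k is None:
            excluded.append(mol.id)
        else:
            members[k].append(mol.id)
    if excluded:
        msg = (f"{len(excluded)} molecules outside [250, 600] amu excluded: "
               f"{excluded[:5]}{'...' if len(excluded) > 5 else ''}")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    return [
        SubsetTable(subset_index=k, mw_range=subset_bounds(k), members=members[k])
        for k in range(1, _N_SUBSETS + 1)
    ]


def split_train_test(
    subset: SubsetTable, ratio: tuple[int, int] = (4, 1), seed: int = 0
) -> SubsetTable:
    """Random train/test split at ``ratio`` (default 4:1), seeded.

    For n members the training set gets ceil(train_share * n) molecules,
    e.g. 70 -> 56 train / 14 test. Requires n >= train+test parts.
    """
    n = len(subset.members)
    tr, te = ratio
    if tr <= 0 or te <= 0:
        raise ValueError("split ratio parts must be positive")
    if n < tr + te:
        raise ValueError(
            f"subset {subset.subset_index} has {n} members; cannot honor "
            f"a {tr}:{te} split"
        )
    n_train = math.ceil(n * tr / (tr + te))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())
    split = {
        mid: ("train" if i in train_idx else "test")
        for i, mid in enumerate(subset.members)
    }
    return SubsetTable(
        subset_index=subset.subset_index,
        mw_range=subset.mw_range,
        members=list(subset.members),
        split=split,
    )


def select_template(
    subset: SubsetTable, molecules: Sequence[Molecule]
) -> Molecule:
    """The heaviest member of the band; ties go to the smaller id."""
    by_id = {m.id: m for m in molecules}
    candidates = [by_id[mid] for mid in subset.members if mid in by_id]
    if not candidates:
        raise ValueError(f"subset {subset.subset_index} is empty")
    return min(candidates, key=lambda m: (-m.mw, m.id))


def subsets_to_frame(subsets: Iterable[SubsetTable]) -> pd.DataFrame:
    rows = [
        {"id": mid, "subset": s.subset_index, "split": s.split.get(mid, "")}
        for s in subsets
        for mid in s.members
    ]
    return pd.DataFrame(rows, columns=["id", "subset", "split"])
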