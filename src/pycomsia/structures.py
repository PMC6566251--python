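"""Molecular structures, parameter assignment, and rigid scaffold alignment.

A :class:`Molecule` is an ordered list of atoms with 3D coordinates,
optional partial charges, optional bonds, and an optional activity
(pIC50).  Structures are read from SDF (through RDKit) or MOL2
(TRIPOS text) files; a whole compound series is brought into a common
frame by Kabsch superposition of an explicitly mapped scaffold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import params

try:  # RDKit is a hard dependency, but imported lazily-tolerant for clarity
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
except ImportError as _exc:  # pragma: no cover
    Chem = None
    _RDKIT_ERROR = _exc

SDF_CHARGE_PROPERTY = "PARTIAL_CHARGES"

CHARGE_PROVIDERS = ("file", "gasteiger", "zero")


class FormatError(ValueError):
    """A structure file failed to parse; the message names the record."""


class DegenerateGeometryError(ValueError):
    """Too few or collinear points for a unique rigid superposition."""


@dataclass
class Atom:
    """One atom: element, position (Å) and per-field physicochemical weights."""

    element: str
    position: np.ndarray
    partial_charge: float | None = None
    vdw_radius: float | None = None
    hydrophobicity: float | None = None
    donor_flag: bool = False
    acceptor_flag: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    activity: float | None = None
    subset: str = "unassigned"
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if self.activity is not None and not math.isfinite(self.activity):
            raise ValueError(f"molecule {self.id!r} has non-finite activity")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, coords):
            atom.position = row.copy()

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            activity=self.activity,
            subset=self.subset,
            bonds=list(self.bonds),
        )


@dataclass(frozen=True)
class AlignmentMap:
    """Ordered (reference atom index, mobile atom index) pairs for one compound."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise DegenerateGeometryError("an alignment map needs >= 3 atom pairs")
        for side in (0, 1):
            idx = [p[side] for p in self.pairs]
            if len(set(idx)) != len(idx):
                raise ValueError("alignment map repeats an atom index")


# ---------------------------------------------------------------------------
# File I/O


def _require_rdkit() -> None:
    if Chem is None:  # pragma: no cover
        raise ImportError(f"rdkit is required for SDF I/O: {_RDKIT_ERROR}")


def _molecule_from_rdkit(rdmol, index: int) -> Molecule:
    conf = rdmol.GetConformer()
    charges: list[float | None]
    if rdmol.HasProp(SDF_CHARGE_PROPERTY):
        raw = rdmol.GetProp(SDF_CHARGE_PROPERTY).split()
        if len(raw) != rdmol.GetNumAtoms():
            raise FormatError(
                f"record {index}: {SDF_CHARGE_PROPERTY} lists {len(raw)} values "
                f"for {rdmol.GetNumAtoms()} atoms"
            )
        charges = [float(v) for v in raw]
    else:
        charges = [None] * rdmol.GetNumAtoms()
    atoms = [
        Atom(
            element=a.GetSymbol(),
            position=np.array(conf.GetAtomPosition(a.GetIdx())),
            partial_charge=charges[a.GetIdx()],
        )
        for a in rdmol.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()
    ]
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    activity = None
    if rdmol.HasProp("PIC50"):
        activity = float(rdmol.GetProp("PIC50"))
    mol = Molecule(id=name or f"mol{index}", atoms=atoms, activity=activity, bonds=bonds)
    coords = mol.coordinates
    if len(atoms) > 1 and np.allclose(coords[:, 2], 0.0):
        warnings.warn(
            f"record {index} ({mol.id}): all z coordinates are zero; "
            "structure may be 2D",
            stacklevel=3,
        )
    return mol


def _read_sdf(path: Path) -> list[Molecule]:
    _require_rdkit()
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    molecules = []
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise FormatError(f"{path}: unreadable SDF record at index {i}")
        molecules.append(_molecule_from_rdkit(rdmol, i))
    return molecules


def _read_mol2(path: Path) -> list[Molecule]:
    """Minimal TRIPOS MOL2 reader: MOLECULE, ATOM and BOND sections."""
    molecules: list[Molecule] = []
    blocks = Path(path).read_text().split("@<TRIPOS>MOLECULE")
    for i, block in enumerate(blocks[1:]):
        lines = block.splitlines()
        try:
            name = lines[1].strip() or f"mol{i}"
            atoms: list[Atom] = []
            bonds: list[tuple[int, int]] = []
            section = None
            for line in lines:
                stripped = line.strip()
                if stripped.startswith("@<TRIPOS>"):
                    section = stripped[9:]
                    continue
                if not stripped:
                    continue
                if section == "ATOM":
                    fields = stripped.split()
                    element = fields[5].split(".")[0]
                    charge = float(fields[8]) if len(fields) > 8 else None
                    atoms.append(
                        Atom(
                            element=element,
                            position=np.array([float(v) for v in fields[2:5]]),
                            partial_charge=charge,
                        )
                    )
                elif section == "BOND":
                    fields = stripped.split()
                    bonds.append((int(fields[1]) - 1, int(fields[2]) - 1))
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed MOL2 record at index {i}: {exc}")
        molecules.append(Molecule(id=name, atoms=atoms, bonds=bonds))
    if not molecules:
        raise FormatError(f"{path}: no MOL2 records found")
    return molecules


def read_structures(path: str | Path) -> list[Molecule]:
    """Read an SDF or MOL2 multi-record file into a list of molecules.

    Partial charges come from the MOL2 charge column or the SDF property
    ``PARTIAL_CHARGES`` when present; otherwise they are left unassigned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        return _read_sdf(path)
    if suffix == ".mol2":
        return _read_mol2(path)
    raise FormatError(f"unrecognized structure format: {path.suffix}")


def _to_rdkit(mol: Molecule):
    _require_rdkit()
    rw = Chem.RWMol()
    for atom in mol.atoms:
        a = Chem.Atom(atom.element if atom.element != "X" else "C")
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j in mol.bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    conf = Chem.Conformer(len(mol.atoms))
    for idx, atom in enumerate(mol.atoms):
        conf.SetAtomPosition(idx, atom.position.tolist())
    rdmol = rw.GetMol()
    rdmol.AddConformer(conf)
    rdmol.SetProp("_Name", mol.id)
    if all(a.partial_charge is not None for a in mol.atoms):
        rdmol.SetProp(
            SDF_CHARGE_PROPERTY,
            " ".join(f"{a.partial_charge:.6f}" for a in mol.atoms),
        )
    if mol.activity is not None:
        rdmol.SetProp("PIC50", f"{mol.activity:.6f}")
    return rdmol


def write_structures(molecules: Sequence[Molecule], path: str | Path) -> None:
    """Write molecules as SDF (V2000) or MOL2 depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() in (".sdf", ".sd"):
        _require_rdkit()
        writer = Chem.SDWriter(str(path))
        writer.SetKekulize(False)
        for mol in molecules:
            writer.write(_to_rdkit(mol))
        writer.close()
    elif path.suffix.lower() == ".mol2":
        with open(path, "w") as fh:
            for mol in molecules:
                fh.write("@<TRIPOS>MOLECULE\n")
                fh.write(f"{mol.id}\n")
                fh.write(f"{len(mol.atoms)} {len(mol.bonds)} 0 0 0\n")
                fh.write("SMALL\nUSER_CHARGES\n")
                fh.write("@<TRIPOS>ATOM\n")
                for i, atom in enumerate(mol.atoms, start=1):
                    q = atom.partial_charge if atom.partial_charge is not None else 0.0
                    x, y, z = atom.position
                    fh.write(
                        f"{i:>4} {atom.element}{i} {x:>10.4f} {y:>10.4f} "
                        f"{z:>10.4f} {atom.element} 1 LIG {q:>10.6f}\n"
                    )
                fh.write("@<TRIPOS>BOND\n")
                for n, (i, j) in enumerate(mol.bonds, start=1):
                    fh.write(f"{n:>4} {i + 1:>4} {j + 1:>4} 1\n")
    else:
        raise FormatError(f"unrecognized structure format: {path.suffix}")


# ---------------------------------------------------------------------------
# Parameter assignment


def infer_bonds(mol: Molecule) -> list[tuple[int, int]]:
    """Distance-based connectivity: bond if d < r_cov(i) + r_cov(j) + 0.45 Å."""
    coords = mol.coordinates
    radii = np.array(
        [params.COVALENT_RADII.get(a.element, 0.77) for a in mol.atoms]
    )
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    cutoff = radii[:, None] + radii[None, :] + 0.45
    bonded = (dist < cutoff) & (dist > 1e-6)
    return [(i, j) for i in range(len(mol.atoms)) for j in range(i + 1, len(mol.atoms)) if bonded[i, j]]


def _donor_acceptor_flags(mol: Molecule) -> list[tuple[bool, bool]]:
    """Rule-table donor/acceptor typing.

    Donor: a hydrogen bonded to N or O (the polar H carries the flag).
    Acceptor: N or O with available lone pairs — O always (including
    carbonyl and hydroxyl), N unless it is an amide nitrogen (bonded to a
    carbonyl carbon) or a nitro nitrogen (bonded to two oxygens).
    """
    bonds = mol.bonds if mol.bonds else infer_bonds(mol)
    nbrs: dict[int, list[int]] = {i: [] for i in range(len(mol.atoms))}
    for i, j in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    elem = [a.element for a in mol.atoms]

    def is_carbonyl_carbon(idx: int) -> bool:
        if elem[idx] != "C":
            return False
        return any(
            elem[k] == "O" and len(nbrs[k]) == 1 for k in nbrs[idx]
        )

    flags = []
    for i, atom in enumerate(mol.atoms):
        donor = atom.element == "H" and any(elem[k] in ("N", "O") for k in nbrs[i])
        acceptor = False
        if atom.element == "O":
            acceptor = not (
                any(elem[k] == "N" and sum(elem[m] == "O" for m in nbrs[k]) >= 2 for k in nbrs[i])
            )
        elif atom.element == "N":
            n_ox = sum(elem[k] == "O" for k in nbrs[i])
            amide = any(is_carbonyl_carbon(k) for k in nbrs[i])
            acceptor = n_ox < 2 and not amide
        flags.append((donor, acceptor))
    return flags


def _gasteiger_charges(mol: Molecule) -> list[float]:
    _require_rdkit()
    rdmol = _to_rdkit(mol)
    try:
        Chem.SanitizeMol(rdmol)
        AllChem.ComputeGasteigerCharges(rdmol)
        charges = [float(a.GetProp("_GasteigerCharge")) for a in rdmol.GetAtoms()]
        if all(math.isfinite(c) for c in charges):
            return charges
    except Exception:
        pass
    # pseudo-atom molecules without a sanitizable valence model: fall back
    # to electronegativity-difference increments over inferred bonds
    en = {"H": 2.2, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98, "S": 2.58,
          "Cl": 3.16, "Br": 2.96, "I": 2.66, "P": 2.19, "X": 2.55}
    bonds = mol.bonds if mol.bonds else infer_bonds(mol)
    charges = [0.0] * len(mol.atoms)
    for i, j in bonds:
        delta = 0.1 * (en.get(mol.atoms[j].element, 2.5) - en.get(mol.atoms[i].element, 2.5))
        charges[i] += delta
        charges[j] -= delta
    return charges


def assign_atom_parameters(
    mol: Molecule,
    scheme: str = params.DEFAULT_SCHEME,
    charge_provider: str = "file",
) -> Molecule:
    """Populate vdW radius, hydrophobicity, donor/acceptor flags and charges.

    ``charge_provider`` is one of ``"file"`` (keep charges read from the
    structure file; error if absent), ``"gasteiger"`` (compute), or
    ``"zero"``.
    """
    if charge_provider not in CHARGE_PROVIDERS:
        raise ValueError(f"unknown charge provider {charge_provider!r}")
    out = mol.copy()
    flags = _donor_acceptor_flags(out)
    if charge_provider == "gasteiger":
        charges = _gasteiger_charges(out)
    elif charge_provider == "zero":
        charges = [0.0] * len(out.atoms)
    else:
        charges = [a.partial_charge for a in out.atoms]
        if any(c is None for c in charges):
            raise ValueError(
                f"compound {mol.id}: charge provider 'file' but the input "
                "carries no partial charges"
            )
    for atom, (donor, acceptor), charge in zip(out.atoms, flags, charges):
        atom.vdw_radius = (
            atom.vdw_radius
            if atom.element == "X" and atom.vdw_radius is not None
            else params.lookup(scheme, "vdw", atom.element, mol.id)
        )
        atom.hydrophobicity = (
            atom.hydrophobicity
            if atom.element == "X" and atom.hydrophobicity is not None
            else params.lookup(scheme, "hydrophobicity", atom.element, mol.id)
        )
        if atom.element == "X":
            # pseudo-atoms keep generator-planted flags
            atom.partial_charge = charge if atom.partial_charge is None else atom.partial_charge
            continue
        atom.donor_flag = donor
        atom.acceptor_flag = acceptor
        atom.partial_charge = charge
    return out


# ---------------------------------------------------------------------------
# Rigid alignment


def kabsch_superpose(
    reference: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    root-mean-square sense.  The rotation is proper (det = +1).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("paired Nx3 coordinate arrays required")
    if len(ref) < 3:
        raise DegenerateGeometryError("need >= 3 point pairs")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # collinearity: rank of either centered set < 2
    if (
        np.linalg.matrix_rank(ref_c, tol=1e-8) < 2
        or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2
    ):
        raise DegenerateGeometryError("collinear points give no unique rotation")
    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum() / len(ref)))
    return R, t, rmsd


def align_set(
    molecules: Sequence[Molecule],
    reference_id: str,
    maps: dict[str, AlignmentMap],
) -> list[Molecule]:
    """Superpose each molecule's mapped scaffold atoms onto the reference.

    The reference molecule is returned unchanged; every other molecule is
    rigidly transformed, so intramolecular geometry is preserved exactly.
    """
    by_id = {m.id: m for m in molecules}
    if reference_id not in by_id:
        raise KeyError(f"reference compound {reference_id!r} not in set")
    reference = by_id[reference_id]
    aligned = []
    for mol in molecules:
        if mol.id == reference_id:
            aligned.append(mol.copy())
            continue
        amap = maps.get(mol.id)
        if amap is None:
            raise KeyError(f"no alignment map for compound {mol.id!r}")
        ref_pts = reference.coordinates[[p[0] for p in amap.pairs]]
        mob_pts = mol.coordinates[[p[1] for p in amap.pairs]]
        R, t, _ = kabsch_superpose(ref_pts, mob_pts)
        moved = mol.copy()
        moved.set_coordinates(mol.coordinates @ R.T + t)
        aligned.append(moved)
    return aligned
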