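"""CoMSIA similarity-index fields on a 3D lattice.

Aligned molecules are embedded in a common cubic lattice (default 2 Å
spacing, 4 Å margin).  At every grid point ``q`` and for every field
kind, the similarity index of compound ``m`` is

    A(q) = - sum_atoms  w_probe * w_atom * exp(-alpha * r^2)

with ``r`` the atom–gridpoint distance in Å and ``alpha`` the Gaussian
attenuation factor (default 0.3).  The atomic weight ``w_atom`` is the
cubed van der Waals radius (steric), the partial charge (electrostatic),
the atomic hydrophobicity increment (hydrophobic), or a 0/1 flag
(donor / acceptor).  Columns of the descriptor matrix are (field, grid
point) pairs, grid points linearized x-fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .structures import Molecule

FIELD_ORDER = "SEHDA"
FIELD_NAMES = {
    "S": "steric",
    "E": "electrostatic",
    "H": "hydrophobic",
    "D": "donor",
    "A": "acceptor",
}


@dataclass(frozen=True)
class FieldConfig:
    """Lattice and probe settings for the similarity-field calculation."""

    spacing: float = 2.0
    margin: float = 4.0
    alpha: float = 0.3
    fields: str = FIELD_ORDER
    # probe atom: charge +1.0, radius 1.0 Å, hydrophobicity +1.0,
    # H-bond donor +1.0, H-bond acceptor +1.0
    probe: dict = field(
        default_factory=lambda: {
            "S": 1.0,  # probe radius 1 Å -> r^3 = 1
            "E": 1.0,
            "H": 1.0,
            "D": 1.0,
            "A": 1.0,
        }
    )
    min_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        canonical = "".join(k for k in FIELD_ORDER if k in set(self.fields))
        if not canonical:
            raise ValueError("at least one field kind required")
        object.__setattr__(self, "fields", canonical)


@dataclass(frozen=True)
class Lattice:
    origin: np.ndarray  # corner of the expanded bounding box, Å
    spacing: float
    counts: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def grid_points(self) -> np.ndarray:
        """All grid-point coordinates, x index varying fastest."""
        nx, ny, nz = self.counts
        ix = np.arange(nx)
        iy = np.arange(ny)
        iz = np.arange(nz)
        # index j = ix + nx*(iy + ny*iz)  (x fastest)
        gz, gy, gx = np.meshgrid(iz, iy, ix, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
        return self.origin + pts * self.spacing

    def point(self, j: int) -> np.ndarray:
        nx, ny, nz = self.counts
        ix = j % nx
        iy = (j // nx) % ny
        iz = j // (nx * ny)
        return self.origin + np.array([ix, iy, iz]) * self.spacing


def build_lattice(molecules: Sequence[Molecule], config: FieldConfig) -> Lattice:
    """Axis-aligned lattice covering every atom of every compound plus margin."""
    if not molecules:
        raise ValueError("cannot build a lattice from an empty molecule set")
    coords = np.vstack([m.coordinates for m in molecules])
    lo = coords.min(axis=0) - config.margin
    hi = coords.max(axis=0) + config.margin
    extent = hi - lo
    counts = tuple(int(np.floor(e / config.spacing + 1e-9)) + 1 for e in extent)
    return Lattice(origin=lo, spacing=config.spacing, counts=counts)


def _atom_weights(mol: Molecule, kind: str) -> np.ndarray:
    if kind == "S":
        vals = [a.vdw_radius for a in mol.atoms]
    elif kind == "E":
        vals = [a.partial_charge for a in mol.atoms]
    elif kind == "H":
        vals = [a.hydrophobicity for a in mol.atoms]
    elif kind == "D":
        vals = [1.0 if a.donor_flag else 0.0 for a in mol.atoms]
    elif kind == "A":
        vals = [1.0 if a.acceptor_flag else 0.0 for a in mol.atoms]
    else:
        raise ValueError(f"unknown field kind {kind!r}")
    if any(v is None for v in vals):
        raise ValueError(
            f"compound {mol.id}: atom parameters unassigned for field "
            f"{FIELD_NAMES[kind]}; call assign_atom_parameters first"
        )
    w = np.asarray(vals, dtype=float)
    return w**3 if kind == "S" else w


def comsia_field(
    mol: Molecule, lattice: Lattice, kind: str, config: FieldConfig
) -> np.ndarray:
    """Similarity-index values of one field over the whole lattice."""
    weights = _atom_weights(mol, kind) * config.probe[kind]
    pts = lattice.grid_points()
    coords = mol.coordinates
    # (G, n) squared distances in manageable chunks
    out = np.zeros(len(pts))
    chunk = 65536
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        d2 = ((block[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        out[start : start + chunk] = -(np.exp(-config.alpha * d2) @ weights)
    return out


@dataclass
class DescriptorMatrix:
    """Compounds × (field, grid point) similarity indices with pruning mask."""

    ids: list[str]
    field_kinds: np.ndarray  # per-column field letter
    grid_indices: np.ndarray  # per-column lattice linear index
    values: np.ndarray  # (n_compounds, n_columns)
    lattice: Lattice
    config: FieldConfig
    mask: np.ndarray | None = None  # True = retained
    train_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor matrix contains non-finite entries")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def retained(self) -> np.ndarray:
        """Value matrix restricted to unmasked columns."""
        if self.mask is None:
            return self.values
        return self.values[:, self.mask]

    def columns_for(self, kind: str) -> np.ndarray:
        return self.field_kinds == kind

    def subset_fields(self, fields: str) -> "DescriptorMatrix":
        keep = np.isin(self.field_kinds, list(fields))
        return DescriptorMatrix(
            ids=list(self.ids),
            field_kinds=self.field_kinds[keep],
            grid_indices=self.grid_indices[keep],
            values=self.values[:, keep],
            lattice=self.lattice,
            config=replace(self.config, fields=fields),
            mask=None if self.mask is None else self.mask[keep],
            train_sd=None if self.train_sd is None else self.train_sd[keep],
        )


def assemble_descriptor_matrix(
    molecules: Sequence[Molecule],
    lattice: Lattice | None = None,
    config: FieldConfig | None = None,
) -> DescriptorMatrix:
    """Compute all configured fields for all compounds.

    Rows follow input order; columns are grouped by field in canonical
    S, E, H, D, A order, then by grid index (x fastest).
    """
    config = config or FieldConfig()
    if lattice is None:
        lattice = build_lattice(molecules, config)
    n_pts = lattice.n_points
    blocks = []
    for kind in config.fields:
        block = np.empty((len(molecules), n_pts))
        for i, mol in enumerate(molecules):
            block[i] = comsia_field(mol, lattice, kind, config)
        blocks.append(block)
    values = np.hstack(blocks)
    field_kinds = np.concatenate(
        [np.full(n_pts, kind) for kind in config.fields]
    )
    grid_indices = np.concatenate([np.arange(n_pts)] * len(config.fields))
    return DescriptorMatrix(
        ids=[m.id for m in molecules],
        field_kinds=field_kinds,
        grid_indices=grid_indices,
        values=values,
        lattice=lattice,
        config=config,
    )


def prune_columns(
    matrix: DescriptorMatrix,
    training_rows: Sequence[int],
    min_sigma: float | None = None,
) -> DescriptorMatrix:
    """Mask columns whose training-set standard deviation falls below
    ``min_sigma``; the mask applies identically to train and test rows."""
    if len(training_rows) == 0:
        raise ValueError("training rows must be non-empty")
    if min_sigma is None:
        min_sigma = matrix.config.min_sigma
    sd = matrix.values[list(training_rows)].std(axis=0, ddof=0)
    mask = sd >= min_sigma
    if not mask.any():
        raise ValueError(
            f"all columns masked at min_sigma={min_sigma}; lower the threshold"
        )
    out = DescriptorMatrix(
        ids=list(matrix.ids),
        field_kinds=matrix.field_kinds,
        grid_indices=matrix.grid_indices,
        values=matrix.values,
        lattice=matrix.lattice,
        config=matrix.config,
        mask=mask,
        train_sd=sd,
    )
    return out


# ---------------------------------------------------------------------------
# Serialization: delimited text with a lattice-metadata header


def save_matrix(matrix: DescriptorMatrix, path) -> None:
    with open(path, "w") as fh:
        ox, oy, oz = (float(v) for v in matrix.lattice.origin)
        nx, ny, nz = matrix.lattice.counts
        fh.write(
            f"# lattice origin {ox!r} {oy!r} {oz!r} spacing "
            f"{float(matrix.lattice.spacing)!r} counts {nx} {ny} {nz}\n"
        )
        fh.write(
            f"# fields {matrix.config.fields} alpha {float(matrix.config.alpha)!r}\n"
        )
        cols = "\t".join(
            f"{k}:{g}" for k, g in zip(matrix.field_kinds, matrix.grid_indices)
        )
        fh.write(f"id\t{cols}\n")
        for cid, row in zip(matrix.ids, matrix.values):
            fh.write(cid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_matrix(path) -> DescriptorMatrix:
    with open(path) as fh:
        header1 = fh.readline().split()
        header2 = fh.readline().split()
        origin = np.array([float(v) for v in header1[3:6]])
        spacing = float(header1[7])
        counts = tuple(int(v) for v in header1[9:12])
        fields = header2[2]
        alpha = float(header2[4])
        colnames = fh.readline().rstrip("\n").split("\t")[1:]
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    kinds = np.array([c.split(":")[0] for c in colnames])
    grid = np.array([int(c.split(":")[1]) for c in colnames])
    return DescriptorMatrix(
        ids=ids,
        field_kinds=kinds,
        grid_indices=grid,
        values=np.array(rows),
        lattice=Lattice(origin=origin, spacing=spacing, counts=counts),
        config=FieldConfig(spacing=spacing, alpha=alpha, fields=fields),
    )
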