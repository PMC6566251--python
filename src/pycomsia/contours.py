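"""StDev*Coeff contour grids and volumetric export.

The standard way to visualize a field-based QSAR model is the
StDev*Coeff map: at every grid point the PLS coefficient of that
(field, point) column multiplied by the column's training-set standard
deviation.  Large positive values mark regions where increasing the
field property favors activity, large negative values where it is
detrimental.  Grids export to Gaussian cube and OpenDX scalar formats
(both written per their own conventions, z index fastest).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fields import FIELD_NAMES, Lattice
from .pls import ComsiaModel

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

# Display conventions for the five maps (metadata only; no rendering here):
# favored/disfavored polyhedron colors as conventionally drawn.
COLOR_SEMANTICS = {
    "S": {"favored": "green", "disfavored": "yellow"},
    "E": {"favored": "blue (electropositive)", "disfavored": "red (electronegative)"},
    "H": {"favored": "yellow", "disfavored": "gray"},
    "D": {"favored": "cyan", "disfavored": "purple"},
    "A": {"favored": "magenta", "disfavored": "red"},
}


@dataclass
class ContourGrid:
    lattice: Lattice
    field_kind: str
    values: np.ndarray  # linearized x-fastest, length lattice.n_points
    favored_level: float | None = None
    disfavored_level: float | None = None

    @property
    def colors(self) -> dict[str, str]:
        return COLOR_SEMANTICS[self.field_kind]

    def as_array(self) -> np.ndarray:
        """Values reshaped to (nx, ny, nz)."""
        nx, ny, nz = self.lattice.counts
        return self.values.reshape(nz, ny, nx).transpose(2, 1, 0)


def stdev_coeff_grid(model: ComsiaModel, field_kind: str) -> ContourGrid:
    """Per-gridpoint coefficient x training-sd values for one field."""
    matrix = model.matrix
    if field_kind not in matrix.config.fields:
        raise ValueError(
            f"field {field_kind!r} ({FIELD_NAMES.get(field_kind, '?')}) "
            "absent from the fitted model"
        )
    if matrix.train_sd is None:
        raise ValueError("model matrix carries no training standard deviations")
    mask = matrix.mask if matrix.mask is not None else np.ones(matrix.n_columns, bool)
    # coefficients live in retained-column space; scatter them back
    coef_full = np.zeros(matrix.n_columns)
    coef_full[mask] = model.pls.coefficients
    sel = matrix.field_kinds == field_kind
    values = np.zeros(matrix.lattice.n_points)
    values[matrix.grid_indices[sel]] = (coef_full * matrix.train_sd * mask)[sel]
    return ContourGrid(
        lattice=matrix.lattice, field_kind=field_kind, values=values
    )


def contour_levels(
    grid: ContourGrid, favored_pct: float = 80.0, disfavored_pct: float = 20.0
) -> tuple[float, float]:
    """Iso levels at percentiles of the nonzero StDev*Coeff distribution."""
    nonzero = grid.values[grid.values != 0.0]
    if nonzero.size == 0:
        raise ValueError("all-zero grid: no contours to draw")
    favored = float(np.percentile(nonzero, favored_pct))
    disfavored = float(np.percentile(nonzero, disfavored_pct))
    grid.favored_level = favored
    grid.disfavored_level = disfavored
    return favored, disfavored


def top_points(grid: ContourGrid, n: int = 10) -> list[tuple[float, np.ndarray]]:
    """The n grid points with largest |StDev*Coeff|, with coordinates."""
    order = np.argsort(-np.abs(grid.values), kind="stable")[:n]
    return [(float(grid.values[j]), grid.lattice.point(int(j))) for j in order]


# ---------------------------------------------------------------------------
# Volumetric writers/readers


def export_grid(grid: ContourGrid, fmt: str, path) -> None:
    if fmt == "cube":
        _write_cube(grid, path)
    elif fmt == "dx":
        _write_dx(grid, path)
    else:
        raise ValueError(f"unknown volumetric format {fmt!r}; use 'cube' or 'dx'")


def _write_cube(grid: ContourGrid, path) -> None:
    """Gaussian cube: lengths in Bohr, one dummy atom, z fastest."""
    nx, ny, nz = grid.lattice.counts
    o = grid.lattice.origin * BOHR_PER_ANGSTROM
    step = grid.lattice.spacing * BOHR_PER_ANGSTROM
    vol = grid.as_array()  # (nx, ny, nz)
    with open(path, "w") as fh:
        fh.write(f"StDev*Coeff {FIELD_NAMES[grid.field_kind]} field\n")
        fh.write("generated by pycomsia\n")
        fh.write(f"{1:>5}{o[0]:>12.6f}{o[1]:>12.6f}{o[2]:>12.6f}\n")
        fh.write(f"{nx:>5}{step:>12.6f}{0.0:>12.6f}{0.0:>12.6f}\n")
        fh.write(f"{ny:>5}{0.0:>12.6f}{step:>12.6f}{0.0:>12.6f}\n")
        fh.write(f"{nz:>5}{0.0:>12.6f}{0.0:>12.6f}{step:>12.6f}\n")
        fh.write(f"{1:>5}{0.0:>12.6f}{o[0]:>12.6f}{o[1]:>12.6f}{o[2]:>12.6f}\n")
        for ix in range(nx):
            for iy in range(ny):
                row = vol[ix, iy]
                for start in range(0, nz, 6):
                    fh.write(
                        "".join(f"{v: .5E} " for v in row[start : start + 6]).rstrip()
                        + "\n"
                    )


def _write_dx(grid: ContourGrid, path) -> None:
    """OpenDX scalar field: lengths in Å, last index (z) fastest."""
    nx, ny, nz = grid.lattice.counts
    o = grid.lattice.origin
    d = grid.lattice.spacing
    flat = grid.as_array().ravel()  # C order: z fastest
    with open(path, "w") as fh:
        fh.write(f"# StDev*Coeff {FIELD_NAMES[grid.field_kind]} field\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
        fh.write(f"delta {d:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {d:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} data follows\n"
        )
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.10e}" for v in flat[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_grid(path, fmt: str, field_kind: str = "S") -> ContourGrid:
    """Re-import a cube or dx file written by :func:`export_grid`."""
    path = Path(path)
    if fmt == "cube":
        return _read_cube(path, field_kind)
    if fmt == "dx":
        return _read_dx(path, field_kind)
    raise ValueError(f"unknown volumetric format {fmt!r}")


def _read_cube(path: Path, field_kind: str) -> ContourGrid:
    lines = path.read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = np.array([float(v) for v in lines[2].split()[1:4]]) / BOHR_PER_ANGSTROM
    nx = int(lines[3].split()[0])
    ny = int(lines[4].split()[0])
    nz = int(lines[5].split()[0])
    spacing = float(lines[3].split()[1]) / BOHR_PER_ANGSTROM
    data = []
    for line in lines[6 + natoms :]:
        data.extend(float(v) for v in line.split())
    vol = np.array(data).reshape(nx, ny, nz)
    values = vol.transpose(2, 1, 0).ravel()  # back to x-fastest
    return ContourGrid(
        lattice=Lattice(origin=origin, spacing=spacing, counts=(nx, ny, nz)),
        field_kind=field_kind,
        values=values,
    )


def _read_dx(path: Path, field_kind: str) -> ContourGrid:
    lines = path.read_text().splitlines()
    counts = None
    origin = None
    deltas = []
    data: list[float] = []
    in_data = False
    for line in lines:
        if line.startswith("#"):
            continue
        if line.startswith("object 1"):
            counts = tuple(int(v) for v in line.split()[-3:])
        elif line.startswith("origin"):
            origin = np.array([float(v) for v in line.split()[1:4]])
        elif line.startswith("delta"):
            deltas.append([float(v) for v in line.split()[1:4]])
        elif "data follows" in line:
            in_data = True
        elif line.startswith("attribute") or line.startswith("object"):
            in_data = False
        elif in_data and line.strip():
            data.extend(float(v) for v in line.split())
    assert counts is not None and origin is not None
    nx, ny, nz = counts
    spacing = deltas[0][0]
    vol = np.array(data).reshape(nx, ny, nz)
    values = vol.transpose(2, 1, 0).ravel()
    return ContourGrid(
        lattice=Lattice(origin=origin, spacing=spacing, counts=counts),
        field_kind=field_kind,
        values=values,
    )


def write_summary(grids: list[ContourGrid], path, n: int = 10) -> None:
    """Text summary: top-|StDev*Coeff| grid points per field."""
    with open(path, "w") as fh:
        fh.write("field\trank\tvalue\tx\ty\tz\n")
        for grid in grids:
            for rank, (value, xyz) in enumerate(top_points(grid, n), start=1):
                fh.write(
                    f"{grid.field_kind}\t{rank}\t{value:.6g}\t"
                    f"{xyz[0]:.3f}\t{xyz[1]:.3f}\t{xyz[2]:.3f}\n"
                )
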