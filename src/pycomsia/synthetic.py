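"""Synthetic molecule sets with planted field–activity relationships.

The real inhibitor series behind the packaged prediction table exists in
print only as structure drawings, so the field/PLS machinery is
exercised on generated pseudo-atom molecules instead: a fixed rigid
scaffold shared by every compound (pre-aligned by construction) plus a
few substituent sites whose atomic properties — partial charge, van der
Waals radius, hydrophobicity, donor/acceptor flags — vary randomly per
compound.  Activity is a planted linear functional of the compound's
true field values at designated probe points plus Gaussian noise, so a
correct pipeline must recover both the predictivity (q2) and the
locus of the signal (field contributions).

The module also ships the printed prediction table of the source data
set (90 experimental/predicted pIC50 pairs, 73 train / 17 test) and the
reference statistic tables as checksummed delimited-text fixtures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import Atom, Molecule

# ---------------------------------------------------------------------------
# Generator


def _default_scaffold() -> np.ndarray:
    """A rigid planar hexagon (1.4 Å bond radius) plus two out-of-plane
    anchors — enough geometry to make superposition non-degenerate."""
    angles = np.linspace(0.0, 2.0 * np.pi, 6, endpoint=False)
    ring = np.column_stack(
        [1.4 * np.cos(angles), 1.4 * np.sin(angles), np.zeros(6)]
    )
    anchors = np.array([[0.0, 0.0, 1.2], [2.8, 0.0, -0.8]])
    return np.vstack([ring, anchors])


def _default_sites() -> np.ndarray:
    """Substituent positions: radially extended from three ring atoms."""
    angles = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])
    return np.column_stack(
        [2.9 * np.cos(angles), 2.9 * np.sin(angles), np.full(3, 0.4)]
    )


@dataclass
class GeneratorSpec:
    """Stated world of the generator; defaults mirror a small, rigid
    congeneric series with one signal-carrying field."""

    n_compounds: int = 50
    seed: int = 0
    scaffold: np.ndarray = field(default_factory=_default_scaffold)
    sites: np.ndarray = field(default_factory=_default_sites)
    charge_range: tuple[float, float] = (-0.5, 0.5)
    radius_range: tuple[float, float] = (1.4, 2.0)
    hydrophobicity_range: tuple[float, float] = (-1.0, 1.0)
    donor_probability: float = 0.3
    acceptor_probability: float = 0.3
    # planted linear effect: field letter -> weight on the summed field
    # values at the probe points
    effect_weights: dict = field(default_factory=lambda: {"E": 2.0})
    probe_points: np.ndarray | None = None  # default: the site positions
    noise_sd: float = 0.3  # pIC50 units
    baseline: float = 7.0  # typical series midpoint, pIC50
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.effect_weights and len(self.sites) == 0:
            raise ValueError("nonzero effect weights require substituent sites")
        for w in self.effect_weights.values():
            if not np.isfinite(w):
                raise ValueError("effect weights must be finite")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    spec: GeneratorSpec
    probe_points: np.ndarray
    noiseless_activity: np.ndarray
    noise: np.ndarray
    field_terms: pd.DataFrame  # per compound, per field: summed probe value


def _gaussian_field_value(
    points: np.ndarray, coords: np.ndarray, weights: np.ndarray, alpha: float
) -> float:
    """Similarity-index sum at the probe points (generator-local copy of
    the closed form, kept independent of the field engine)."""
    d2 = ((points[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return float(-(np.exp(-alpha * d2) * weights[None, :]).sum())


def generate_set(spec: GeneratorSpec) -> tuple[list[Molecule], GroundTruth]:
    """Draw a reproducible aligned compound set with planted activities."""
    rng = np.random.default_rng(spec.seed)
    probes = spec.probe_points if spec.probe_points is not None else spec.sites
    n_scaffold = len(spec.scaffold)
    molecules: list[Molecule] = []
    terms: list[dict[str, float]] = []
    for i in range(spec.n_compounds):
        atoms = [
            Atom(
                element="X",
                position=pos.copy(),
                partial_charge=0.0,
                vdw_radius=1.7,
                hydrophobicity=0.5,
            )
            for pos in spec.scaffold
        ]
        for site in spec.sites:
            atoms.append(
                Atom(
                    element="X",
                    position=site.copy(),
                    partial_charge=float(rng.uniform(*spec.charge_range)),
                    vdw_radius=float(rng.uniform(*spec.radius_range)),
                    hydrophobicity=float(rng.uniform(*spec.hydrophobicity_range)),
                    donor_flag=bool(rng.random() < spec.donor_probability),
                    acceptor_flag=bool(rng.random() < spec.acceptor_probability),
                )
            )
        mol = Molecule(id=f"syn{i + 1}", atoms=atoms)
        coords = mol.coordinates
        per_field = {}
        for kind in "SEHDA":
            if kind == "S":
                w = np.array([a.vdw_radius**3 for a in atoms])
            elif kind == "E":
                w = np.array([a.partial_charge for a in atoms])
            elif kind == "H":
                w = np.array([a.hydrophobicity for a in atoms])
            elif kind == "D":
                w = np.array([1.0 if a.donor_flag else 0.0 for a in atoms])
            else:
                w = np.array([1.0 if a.acceptor_flag else 0.0 for a in atoms])
            per_field[kind] = _gaussian_field_value(probes, coords, w, spec.alpha)
        terms.append(per_field)
        molecules.append(mol)
    field_terms = pd.DataFrame(terms)
    noiseless = spec.baseline + sum(
        w * field_terms[kind].to_numpy() for kind, w in spec.effect_weights.items()
    )
    noiseless = np.asarray(noiseless, dtype=float)
    noise = rng.normal(0.0, spec.noise_sd, spec.n_compounds) if spec.noise_sd else np.zeros(spec.n_compounds)
    for mol, a in zip(molecules, noiseless + noise):
        mol.activity = float(a)
    truth = GroundTruth(
        spec=spec,
        probe_points=np.asarray(probes),
        noiseless_activity=noiseless,
        noise=noise,
        field_terms=field_terms,
    )
    return molecules, truth


def stratified_split(
    molecules: Sequence[Molecule], test_fraction: float = 0.19, seed: int = 0
) -> None:
    """Assign train/test flags in place, sampling the test fraction from
    each activity tertile so both sets span high, medium and low activity."""
    with_act = [m for m in molecules if m.activity is not None]
    if len(with_act) < 6:
        raise ValueError("too few compounds with activity for a stratified split")
    acts = np.array([m.activity for m in with_act])
    cuts = np.quantile(acts, [1 / 3, 2 / 3])
    strata = np.digitize(acts, cuts)
    rng = np.random.default_rng(seed)
    for m in molecules:
        if m.activity is not None:
            m.subset = "train"
    for level in range(3):
        members = [m for m, s in zip(with_act, strata) if s == level]
        n_test = max(1, round(test_fraction * len(members)))
        for idx in rng.choice(len(members), size=min(n_test, len(members)), replace=False):
            members[idx].subset = "test"


# ---------------------------------------------------------------------------
# Fixtures


def pic50_from_ic50(ic50: float) -> float:
    """pIC50 = -log10(IC50 / (mol/L))."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    return float(-np.log10(ic50))


_FIXTURE_FILES = {
    "table4": "table4_predictions.csv",
    "table2": "table2_validation_reference.csv",
    "table1": "table1_combination_reference.csv",
}


class FixtureIntegrityError(RuntimeError):
    pass


def _data_text(filename: str) -> str:
    return (
        resources.files("pycomsia").joinpath("data", filename).read_text()
    )


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table (``table4``, ``table2`` or
    ``table1``), verifying its checksum against the shipped manifest."""
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}")
    filename = _FIXTURE_FILES[name]
    text = _data_text(filename)
    manifest = json.loads(_data_text("checksums.json"))
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != manifest[filename]:
        raise FixtureIntegrityError(
            f"fixture {filename} checksum mismatch: expected "
            f"{manifest[filename]}, got {digest}"
        )
    import io

    return pd.read_csv(io.StringIO(text))
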