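"""Lattice construction and the similarity-field engine."""

import numpy as np
import pytest

import pycomsia as pc
from pycomsia.fields import FIELD_ORDER, load_matrix, save_matrix


def unit_atom(position, **kw):
    defaults = dict(
        partial_charge=1.0, vdw_radius=1.0, hydrophobicity=1.0,
        donor_flag=True, acceptor_flag=True,
    )
    defaults.update(kw)
    return pc.Atom("X", position, **defaults)


def naive_field(mol, lattice, kind, config):
    """Brute-force double loop over grid points and atoms — the oracle."""
    if kind == "S":
        w = [a.vdw_radius**3 for a in mol.atoms]
    elif kind == "E":
        w = [a.partial_charge for a in mol.atoms]
    elif kind == "H":
        w = [a.hydrophobicity for a in mol.atoms]
    elif kind == "D":
        w = [1.0 if a.donor_flag else 0.0 for a in mol.atoms]
    else:
        w = [1.0 if a.acceptor_flag else 0.0 for a in mol.atoms]
    out = np.zeros(lattice.n_points)
    for j in range(lattice.n_points):
        q = lattice.point(j)
        total = 0.0
        for atom, wa in zip(mol.atoms, w):
            r2 = float(((atom.position - q) ** 2).sum())
            total += config.probe[kind] * wa * np.exp(-config.alpha * r2)
        out[j] = -total
    return out


class TestLattice:
    def test_single_atom_margin(self):
        mol = pc.Molecule(id="a", atoms=[unit_atom([0.0, 0.0, 0.0])])
        config = pc.FieldConfig(spacing=2.0, margin=4.0)
        lat = pc.build_lattice([mol], config)
        assert lat.counts == (5, 5, 5)
        np.testing.assert_allclose(lat.origin, [-4.0, -4.0, -4.0])
        # grid is centered on the atom
        np.testing.assert_allclose(lat.grid_points().mean(axis=0), [0.0, 0.0, 0.0])

    def test_translation_equivariance(self, synthetic_set):
        mols, _ = synthetic_set
        config = pc.FieldConfig()
        lat0 = pc.build_lattice(mols[:5], config)
        shifted = []
        for m in mols[:5]:
            c = m.copy()
            c.set_coordinates(m.coordinates + np.array([10.0, 0.0, 0.0]))
            shifted.append(c)
        lat1 = pc.build_lattice(shifted, config)
        assert lat1.counts == lat0.counts
        np.testing.assert_allclose(lat1.origin - lat0.origin, [10.0, 0.0, 0.0])

    def test_counts_closed_form(self):
        # atoms spanning [0, 3] x [0, 1] x [0, 0], margin 2, spacing 1
        mol = pc.Molecule(
            id="box", atoms=[unit_atom([0.0, 0, 0]), unit_atom([3.0, 1.0, 0.0])]
        )
        lat = pc.build_lattice([mol], pc.FieldConfig(spacing=1.0, margin=2.0))
        assert lat.counts == (8, 6, 5)  # floor(extent/spacing)+1

    def test_empty_set(self):
        with pytest.raises(ValueError):
            pc.build_lattice([], pc.FieldConfig())

    def test_linearization_x_fastest(self):
        lat = pc.Lattice(origin=np.zeros(3), spacing=1.0, counts=(2, 3, 4))
        pts = lat.grid_points()
        np.testing.assert_allclose(pts[1] - pts[0], [1.0, 0.0, 0.0])
        for j in range(lat.n_points):
            np.testing.assert_allclose(lat.point(j), pts[j])


class TestField:
    def test_atom_on_grid_point(self):
        mol = pc.Molecule(id="a", atoms=[unit_atom([0.0, 0.0, 0.0])])
        config = pc.FieldConfig(spacing=2.0, margin=4.0)
        lat = pc.build_lattice([mol], config)
        vals = pc.comsia_field(mol, lat, "E", config)
        center = np.argmin(np.abs(lat.grid_points()).sum(axis=1))
        assert vals[center] == pytest.approx(-1.0)

    def test_closed_form_at_distance(self):
        mol = pc.Molecule(id="a", atoms=[unit_atom([0.0, 0.0, 0.0])])
        config = pc.FieldConfig(spacing=2.0, margin=4.0, alpha=0.3)
        lat = pc.build_lattice([mol], config)
        vals = pc.comsia_field(mol, lat, "E", config)
        pts = lat.grid_points()
        j = int(np.argmin(np.abs(pts - np.array([2.0, 0.0, 0.0])).sum(axis=1)))
        assert vals[j] == pytest.approx(-np.exp(-1.2), abs=1e-12)
        assert -np.exp(-1.2) == pytest.approx(-0.3012, abs=5e-5)

    @pytest.mark.parametrize("kind", list(FIELD_ORDER))
    def test_engine_equals_naive_oracle(self, kind, synthetic_set):
        mols, _ = synthetic_set
        subset = mols[:3]
        config = pc.FieldConfig(spacing=2.0, margin=3.0)
        lat = pc.build_lattice(subset, config)
        for mol in subset:
            engine = pc.comsia_field(mol, lat, kind, config)
            oracle = naive_field(mol, lat, kind, config)
            np.testing.assert_allclose(engine, oracle, atol=1e-10)

    def test_symmetric_atoms_double_value(self):
        pair = pc.Molecule(
            id="pair", atoms=[unit_atom([-1.5, 0, 0]), unit_atom([1.5, 0, 0])]
        )
        single = pc.Molecule(id="one", atoms=[unit_atom([1.5, 0.0, 0.0])])
        config = pc.FieldConfig(spacing=1.0, margin=3.0)
        # lattice with a grid point exactly at the symmetry center
        lat = pc.Lattice(origin=np.array([-3.0, -3.0, -3.0]), spacing=1.0, counts=(7, 7, 7))
        center = int(np.argmin(np.abs(lat.grid_points()).sum(axis=1)))
        np.testing.assert_allclose(lat.grid_points()[center], 0.0)
        v_pair = pc.comsia_field(pair, lat, "E", config)[center]
        v_single = pc.comsia_field(single, lat, "E", config)[center]
        assert v_pair == pytest.approx(2 * v_single, abs=1e-12)

    def test_unassigned_parameters_error(self):
        bare = pc.Molecule(id="bare", atoms=[pc.Atom("C", [0.0, 0.0, 0.0])])
        config = pc.FieldConfig()
        lat = pc.build_lattice([bare], config)
        with pytest.raises(ValueError, match="bare"):
            pc.comsia_field(bare, lat, "E", config)

    def test_bound_and_decay(self, synthetic_set):
        """|A(q)| <= sum |w| everywhere and vanishes far from the molecule."""
        mols, _ = synthetic_set
        mol = mols[0]
        config = pc.FieldConfig(spacing=2.0, margin=8.0)
        lat = pc.build_lattice([mol], config)
        vals = pc.comsia_field(mol, lat, "S", config)
        bound = sum(a.vdw_radius**3 for a in mol.atoms)
        assert np.abs(vals).max() <= bound + 1e-12
        pts = lat.grid_points()
        far = np.linalg.norm(pts - mol.coordinates.mean(0), axis=1) > 7.0
        assert np.abs(vals[far]).max() < np.abs(vals).max() * 0.05


class TestDescriptorMatrix:
    def test_shapes(self, synthetic_set):
        mols, _ = synthetic_set
        config = pc.FieldConfig(fields="S")
        m1 = pc.assemble_descriptor_matrix(mols[:1], config=config)
        assert m1.values.shape == (1, m1.lattice.n_points)
        config5 = pc.FieldConfig()
        m5 = pc.assemble_descriptor_matrix(mols[:4], config=config5)
        assert m5.values.shape == (4, 5 * m5.lattice.n_points)

    def test_column_order_canonical(self, synthetic_set):
        mols, _ = synthetic_set
        matrix = pc.assemble_descriptor_matrix(mols[:2], config=pc.FieldConfig(fields="ADS"))
        kinds = matrix.field_kinds
        n = matrix.lattice.n_points
        assert matrix.config.fields == "SDA"
        assert list(dict.fromkeys(kinds)) == ["S", "D", "A"]
        assert (kinds[:n] == "S").all()

    def test_row_permutation(self, synthetic_set):
        mols, _ = synthetic_set
        subset = mols[:4]
        lat = pc.build_lattice(subset, pc.FieldConfig())
        m_fwd = pc.assemble_descriptor_matrix(subset, lattice=lat)
        m_rev = pc.assemble_descriptor_matrix(subset[::-1], lattice=lat)
        np.testing.assert_allclose(m_rev.values, m_fwd.values[::-1], atol=0)

    def test_translation_invariance(self, synthetic_set):
        """Translating molecules and lattice together leaves values identical."""
        mols, _ = synthetic_set
        subset = [m.copy() for m in mols[:3]]
        config = pc.FieldConfig()
        lat = pc.build_lattice(subset, config)
        base = pc.assemble_descriptor_matrix(subset, lattice=lat, config=config)
        shift = np.array([3.0, -2.0, 5.0])
        for m in subset:
            m.set_coordinates(m.coordinates + shift)
        lat2 = pc.Lattice(origin=lat.origin + shift, spacing=lat.spacing, counts=lat.counts)
        moved = pc.assemble_descriptor_matrix(subset, lattice=lat2, config=config)
        # identical up to float addition reordering (last-ulp level)
        np.testing.assert_allclose(moved.values, base.values, atol=1e-12)

    def test_sign_conventions(self, synthetic_set):
        mols, _ = synthetic_set
        matrix = pc.assemble_descriptor_matrix(mols[:5])
        for kind in "SDA":
            block = matrix.values[:, matrix.field_kinds == kind]
            assert (block <= 0).all(), f"{kind} field must be <= 0"

    def test_serialization_round_trip(self, tmp_path, synthetic_set):
        mols, _ = synthetic_set
        matrix = pc.assemble_descriptor_matrix(mols[:3], config=pc.FieldConfig(fields="SE"))
        path = tmp_path / "matrix.tsv"
        save_matrix(matrix, path)
        back = load_matrix(path)
        np.testing.assert_array_equal(back.values, matrix.values)
        assert back.lattice.counts == matrix.lattice.counts
        np.testing.assert_array_equal(back.lattice.origin, matrix.lattice.origin)
        assert back.config.fields == "SE"


class TestPruning:
    def make_matrix(self, values):
        values = np.asarray(values, dtype=float)
        n_cols = values.shape[1]
        return pc.DescriptorMatrix(
            ids=[f"m{i}" for i in range(len(values))],
            field_kinds=np.array(["S"] * n_cols),
            grid_indices=np.arange(n_cols),
            values=values,
            lattice=pc.Lattice(origin=np.zeros(3), spacing=1.0, counts=(n_cols, 1, 1)),
            config=pc.FieldConfig(fields="S"),
        )

    def test_constant_column_masked(self):
        m = self.make_matrix([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        pruned = pc.prune_columns(m, [0, 1, 2], min_sigma=1e-9)
        assert list(pruned.mask) == [False, True]

    def test_zero_threshold_keeps_all(self):
        m = self.make_matrix([[1.0, 0.0], [1.0, 1.0]])
        pruned = pc.prune_columns(m, [0, 1], min_sigma=0.0)
        assert pruned.mask.all()

    def test_planted_sd_threshold(self):
        # two-level column: values ±0.5 -> sd exactly 0.5; companion column
        # with sd 5 keeps the matrix non-empty above the threshold
        col = np.array([0.5, -0.5, 0.5, -0.5])
        wide = np.array([5.0, -5.0, 5.0, -5.0])
        m = self.make_matrix(np.column_stack([col, wide]))
        assert pc.prune_columns(m, range(4), min_sigma=0.4).mask[0]
        assert not pc.prune_columns(m, range(4), min_sigma=0.6).mask[0]

    def test_mask_from_training_rows_only(self):
        # column varies only in the test rows -> masked
        values = np.array([[1.0, 1.0], [1.0, 2.0], [9.0, 3.0], [-9.0, 4.0]])
        pruned = pc.prune_columns(self.make_matrix(values), [0, 1], min_sigma=0.01)
        assert list(pruned.mask) == [False, True]

    def test_all_masked_error(self):
        m = self.make_matrix(np.ones((3, 2)))
        with pytest.raises(ValueError, match="threshold"):
            pc.prune_columns(m, [0, 1, 2], min_sigma=0.5)
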