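"""Formula arithmetic, configuration enumeration, ensembles and I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stereonmr.chem import (
    Atom,
    Conformer,
    ConformerEnsemble,
    boltzmann_weights,
    degrees_of_unsaturation,
    enumerate_relative_configurations,
    filter_low_population,
    internuclear_vector,
    monoisotopic_mass,
    parse_formula,
    read_ensemble,
    write_ensemble,
)
from stereonmr.constants import R_KCAL


class TestFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C28H28O6N4", {"C": 28, "H": 28, "O": 6, "N": 4}),
            ("", {}),
            ("CH4", {"C": 1, "H": 4}),
            ("C6H6", {"C": 6, "H": 6}),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_formula(text).element_counts == expected

    @pytest.mark.parametrize("bad", ["Xx4", "C28H-2", "28C", "c6h6"])
    def test_parse_rejects(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    def test_protonated_ion_mass_matches_hresims(self):
        # [M+H]+ of the C28H28O6N4 natural product: one electron lighter
        # than the neutral-atom sum
        assert monoisotopic_mass("C28H29O6N4", charge=1) == pytest.approx(
            517.2082, abs=5e-5
        )

    def test_neutral_masses(self):
        assert monoisotopic_mass(parse_formula("")) == 0.0
        assert monoisotopic_mass("H") == pytest.approx(1.00783, abs=1e-5)

    @pytest.mark.parametrize(
        "formula,dbe", [("C28H28O6N4", 17), ("CH4", 0), ("C6H6", 4)]
    )
    def test_degrees_of_unsaturation(self, formula, dbe):
        assert degrees_of_unsaturation(formula) == dbe

    def test_dbe_rejects_unsupported_valence(self):
        with pytest.raises(ValueError):
            degrees_of_unsaturation("NaCl")


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(1, 1), (3, 4), (5, 16)])
    def test_counts(self, n, count):
        cfgs = enumerate_relative_configurations([f"C{i}" for i in range(n)])
        assert len(cfgs) == count
        assert len({c.parities for c in cfgs}) == count

    @given(st.integers(min_value=1, max_value=8))
    def test_first_center_pinned_and_distinct(self, n):
        cfgs = enumerate_relative_configurations([f"C{i}" for i in range(n)])
        assert len(cfgs) == 2 ** (n - 1)
        assert all(c.parities[0] == "R*" for c in cfgs)
        assert len({c.parities for c in cfgs}) == len(cfgs)

    def test_names_are_sequential(self):
        cfgs = enumerate_relative_configurations(["a", "b", "c"])
        assert [c.name for c in cfgs] == ["RC1", "RC2", "RC3", "RC4"]

    def test_empty_center_list_rejected(self):
        with pytest.raises(ValueError):
            enumerate_relative_configurations([])


class TestBoltzmann:
    def test_equal_energies(self):
        np.testing.assert_allclose(boltzmann_weights([0.0, 0.0]), [0.5, 0.5])
        np.testing.assert_allclose(boltzmann_weights([3.7]), [1.0])

    def test_rt_ln2_closed_form(self):
        de = R_KCAL * 300.0 * np.log(2.0)
        np.testing.assert_allclose(
            boltzmann_weights([0.0, de], 300.0), [2 / 3, 1 / 3], rtol=1e-12
        )

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
        st.floats(-20, 20),
    )
    def test_invariant_under_energy_offset(self, energies, offset):
        base = boltzmann_weights(energies)
        shifted = boltzmann_weights([e + offset for e in energies])
        np.testing.assert_allclose(base, shifted, atol=1e-12)


def _toy_ensemble(weights):
    atoms = [Atom(1, "C", [0, 0, 0]), Atom(2, "H", [0, 0, 1.09])]
    confs = [Conformer(atoms, 0.0, f"c{i}") for i in range(len(weights))]
    return ConformerEnsemble(None, confs, np.asarray(weights, float))


class TestPopulationFilter:
    def test_worked_example(self):
        ens = _toy_ensemble([0.90, 0.06, 0.04])
        out = filter_low_population(ens, 0.05)
        assert len(out) == 2
        np.testing.assert_allclose(out.weights, [0.9375, 0.0625])

    def test_threshold_zero_keeps_all(self):
        ens = _toy_ensemble([0.7, 0.3])
        assert len(filter_low_population(ens, 0.0)) == 2

    def test_strictly_leq_rule_and_renormalisation(self):
        out = filter_low_population(_toy_ensemble([0.96, 0.04]), 0.05)
        assert len(out) == 1
        np.testing.assert_allclose(out.weights, [1.0])

    def test_idempotent(self):
        ens = _toy_ensemble([0.90, 0.06, 0.04])
        once = filter_low_population(ens, 0.05)
        twice = filter_low_population(once, 0.05)
        np.testing.assert_allclose(once.weights, twice.weights)

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError):
            filter_low_population(_toy_ensemble([0.5, 0.5]), 0.6)


WATER_XYZ = """3
conf1  E=0.0
O 0.000000 0.000000 0.117300
H 0.000000 0.757200 -0.469200
H 0.000000 -0.757200 -0.469200
3
conf2  E=0.4
O 0.000000 0.000000 0.127300
H 0.000000 0.761200 -0.479200
H 0.000000 -0.761200 -0.469200
"""


class TestEnsembleIO:
    def test_xyz_two_records(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text(WATER_XYZ)
        ens = read_ensemble(p)
        assert len(ens) == 2
        assert all(len(c.atoms) == 3 for c in ens.conformers)
        assert ens.conformers[1].relative_energy == pytest.approx(0.4)
        # Boltzmann weights from the comment-line energies
        assert ens.weights[0] > ens.weights[1]

    def test_roundtrip_coordinates(self, tmp_path, clean_study):
        ens = next(iter(clean_study.ensembles.values()))
        p = tmp_path / "ens.xyz"
        write_ensemble(ens, p)
        back = read_ensemble(p)
        for a, b in zip(ens.conformers, back.conformers):
            np.testing.assert_allclose(
                a.coordinates(), b.coordinates(), atol=1e-4
            )
            assert b.relative_energy == pytest.approx(a.relative_energy, abs=1e-6)

    def test_inconsistent_atom_order_rejected(self, tmp_path):
        bad = WATER_XYZ.replace(
            "O 0.000000 0.000000 0.127300\nH 0.000000 0.761200 -0.479200",
            "H 0.000000 0.761200 -0.479200\nO 0.000000 0.000000 0.127300",
        )
        p = tmp_path / "bad.xyz"
        p.write_text(bad)
        with pytest.raises(ValueError):
            read_ensemble(p)

    def test_sdf_with_energy_property(self, tmp_path):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("C"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        mol.SetProp("energy_kcal", "1.25")
        p = tmp_path / "m.sdf"
        with Chem.SDWriter(str(p)) as w:
            w.write(mol)
        ens = read_ensemble(p)
        assert len(ens) == 1
        assert ens.conformers[0].relative_energy == pytest.approx(1.25)
        assert sum(a.element == "H" for a in ens.conformers[0].atoms) == 4


class TestInternuclearVector:
    def test_axis_aligned(self):
        c = Conformer([Atom(1, "C", [0, 0, 0]), Atom(2, "H", [0, 0, 1.09])])
        u, r = internuclear_vector(c, "C1", "H2")
        np.testing.assert_allclose(u, [0, 0, 1])
        assert r == pytest.approx(1.09)

    def test_reversal_negates(self):
        c = Conformer([Atom(1, "C", [0, 0, 0]), Atom(2, "H", [0.4, -0.2, 1.0])])
        u1, r1 = internuclear_vector(c, "C1", "H2")
        u2, r2 = internuclear_vector(c, "H2", "C1")
        np.testing.assert_allclose(u1, -u2)
        assert r1 == r2

    def test_coincident_atoms_error(self):
        c = Conformer([Atom(1, "C", [0, 0, 0]), Atom(2, "H", [0, 0, 0])])
        with pytest.raises(ValueError):
            internuclear_vector(c, "C1", "H2")

    def test_generated_scaffold_ch_lengths(self, clean_study):
        conf = next(iter(clean_study.ensembles.values())).conformers[0]
        c_lab, h_lab = clean_study.info.stereo_ch[0]
        _, r = internuclear_vector(conf, c_lab, h_lab)
        assert r == pytest.approx(1.09, abs=0.01)
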