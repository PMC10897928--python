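"""ISPA distances, r^-6 ensemble averaging, Karplus couplings, shift scoring."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stereonmr.chem import Atom, Conformer, ConformerEnsemble
from stereonmr.isotropic import (
    NOERecord,
    ShiftRecord,
    dihedral_angle,
    ensemble_j,
    ensemble_noe_distance,
    filter_noe_records,
    ispa_distance,
    karplus_j,
    score_noe,
    score_shifts,
)


class TestIspa:
    @pytest.mark.parametrize(
        "intensity,expected",
        [(1.0, 1.78), (1.0 / 64.0, 3.56), (64.0, 0.89)],
    )
    def test_worked_values(self, intensity, expected):
        assert ispa_distance(intensity, 1.0, 1.78) == pytest.approx(
            expected, rel=1e-12
        )

    @given(st.floats(1.5, 6.0))
    def test_roundtrip_from_intensity(self, r):
        intensity = (1.78 / r) ** 6
        assert ispa_distance(intensity, 1.0, 1.78) == pytest.approx(r, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ispa_distance(0.0, 1.0, 1.78)


def two_distance_ensemble(r1, r2, w):
    confs = [
        Conformer([Atom(1, "H", [0, 0, 0]), Atom(2, "H", [0, 0, r])], 0.0, f"c{i}")
        for i, r in enumerate((r1, r2))
    ]
    return ConformerEnsemble(None, confs, np.array([w, 1 - w]))


class TestEnsembleDistance:
    def test_single_conformer_is_geometric(self):
        ens = two_distance_ensemble(2.0, 3.0, 1.0)
        assert ensemble_noe_distance(ens, ("H1", "H2")) == pytest.approx(2.0)

    def test_half_half_average(self):
        ens = two_distance_ensemble(2.0, 3.0, 0.5)
        expected = (0.5 * 2.0**-6 + 0.5 * 3.0**-6) ** (-1 / 6)
        got = ensemble_noe_distance(ens, ("H1", "H2"))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.214, abs=2e-3)

    @given(st.floats(0.0, 1.0), st.floats(1.8, 4.0), st.floats(1.8, 4.0))
    def test_bounded_by_extremes(self, w, r1, r2):
        ens = two_distance_ensemble(r1, r2, w)
        d = ensemble_noe_distance(ens, ("H1", "H2"))
        assert min(r1, r2) - 1e-9 <= d <= max(r1, r2) + 1e-9

    def test_r3_option_differs(self):
        ens = two_distance_ensemble(2.0, 3.0, 0.5)
        r6 = ensemble_noe_distance(ens, ("H1", "H2"), "r6")
        r3 = ensemble_noe_distance(ens, ("H1", "H2"), "r3")
        assert r3 > r6  # r^-6 weights the short distance harder


class TestNoeFilter:
    def test_bond_and_distance_rules(self, clean_study):
        study = clean_study
        ens = study.ensembles[study.true_configuration.name]
        from stereonmr.chem import bond_graph

        graph = bond_graph(ens.conformers[0])
        for rec in study.observables.noe:
            n = nx.shortest_path_length(graph, rec.pair[0], rec.pair[1])
            assert n > 5
            assert ensemble_noe_distance(
                ConformerEnsemble(
                    ens.configuration, ens.conformers, study.true_populations
                ),
                rec.pair,
            ) < 5.0

    def test_short_range_record_excluded(self):
        conf = Conformer(
            [
                Atom(1, "H", [0, 0, 0]),
                Atom(2, "C", [0, 0, 1.09]),
                Atom(3, "H", [0, 1.0, 1.4]),
            ]
        )
        ens = ConformerEnsemble(None, [conf], np.ones(1))
        g = nx.Graph([("H1", "C2"), ("C2", "H3")])
        recs = [NOERecord(("H1", "H3"), 1.0)]
        assert filter_noe_records(recs, g, ens) == []


class TestScoreNoe:
    def test_exact_distances_give_zero_rss(self, clean_study):
        study = clean_study
        ens = study.ensembles[study.true_configuration.name]
        ens_w = ConformerEnsemble(
            ens.configuration, ens.conformers, study.true_populations
        )
        sc = score_noe(ens_w, study.observables.noe)
        assert sc.rss == pytest.approx(0.0, abs=1e-16)
        assert sc.n_params == len(study.true_populations) - 1

    def test_true_configuration_minimises_noe_aic(self, clean_study):
        study = clean_study
        aics = {}
        for name, ens in study.ensembles.items():
            ens_w = ConformerEnsemble(
                ens.configuration, ens.conformers, study.true_populations
            )
            aics[name] = score_noe(ens_w, study.observables.noe).aic
        assert min(aics, key=aics.get) == study.true_configuration.name

    def test_empty_records_rejected(self, clean_study):
        ens = next(iter(clean_study.ensembles.values()))
        with pytest.raises(ValueError):
            score_noe(ens, [])


class TestKarplus:
    @pytest.mark.parametrize(
        "theta,expected",
        [(90.0, 1.8), (0.0, 9.5 - 1.6 + 1.8), (180.0, 9.5 + 1.6 + 1.8)],
    )
    def test_closed_forms(self, theta, expected):
        assert karplus_j(theta) == pytest.approx(expected, abs=1e-9)

    def test_ensemble_average_and_dihedral(self, clean_study):
        study = clean_study
        ens = study.ensembles[study.true_configuration.name]
        path = study.info.j_paths[0]
        ens_w = ConformerEnsemble(
            ens.configuration, ens.conformers, study.true_populations
        )
        expected = sum(
            w * karplus_j(dihedral_angle(c, path))
            for w, c in zip(study.true_populations, ens.conformers)
        )
        assert ensemble_j(ens_w, path) == pytest.approx(expected, rel=1e-12)
        rec = next(r for r in study.observables.j if r.dihedral_path == path)
        assert rec.value == pytest.approx(expected, rel=1e-9)


def make_shift_records(computed, experimental, label="c1"):
    return [
        ShiftRecord(f"C{i}", e, {label: c})
        for i, (c, e) in enumerate(zip(computed, experimental), start=1)
    ]


def single_conformer_ensemble(label="c1"):
    conf = Conformer(
        [Atom(1, "C", [0, 0, 0]), Atom(2, "H", [0, 0, 1.09])], 0.0, label
    )
    return ConformerEnsemble(None, [conf], np.ones(1))


class TestScoreShifts:
    def test_perfect_agreement(self):
        vals = [10.0, 50.0, 120.0, 160.0]
        sc = score_shifts(single_conformer_ensemble(), make_shift_records(vals, vals))
        assert sc.slope == pytest.approx(1.0)
        assert sc.intercept == pytest.approx(0.0, abs=1e-10)
        assert sc.corrected_mae == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_absorbed(self):
        comp = [10.0, 50.0, 120.0, 160.0]
        exp = [v + 7.0 for v in comp]
        sc = score_shifts(single_conformer_ensemble(), make_shift_records(comp, exp))
        assert sc.intercept == pytest.approx(7.0, abs=1e-9)
        assert sc.corrected_mae == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(0.2, 5.0), st.floats(-50.0, 50.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(4)
        comp = rng.uniform(10, 180, 8)
        exp = comp + rng.normal(0, 2.0, 8)
        base = score_shifts(
            single_conformer_ensemble(),
            make_shift_records(comp, exp),
        )
        transformed = score_shifts(
            single_conformer_ensemble(),
            make_shift_records(a * comp + b, exp),
        )
        assert transformed.corrected_mae == pytest.approx(
            base.corrected_mae, rel=1e-6, abs=1e-9
        )
        assert transformed.aic == pytest.approx(base.aic, rel=1e-6, abs=1e-6)

    def test_true_configuration_minimises_shift_aic(self, clean_study):
        study = clean_study
        aics = {}
        for name, ens in study.ensembles.items():
            ens_w = ConformerEnsemble(
                ens.configuration, ens.conformers, study.true_populations
            )
            aics[name] = score_shifts(ens_w, study.observables.shifts[name]).aic
        assert min(aics, key=aics.get) == study.true_configuration.name

    def test_degenerate_regression_rejected(self):
        recs = make_shift_records([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            score_shifts(single_conformer_ensemble(), recs)
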