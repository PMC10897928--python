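"""Saupe-tensor fitting, RDC prediction, Q factor and AIC."""

import numpy as np
import pytest

from stereonmr.chem import Atom, Conformer, ConformerEnsemble
from stereonmr.constants import GAMMA, H_PLANCK, MU0
from stereonmr.rdc import (
    RDCRecord,
    SaupeTensor,
    SingleTensorRDCModel,
    aic,
    dipolar_constant,
    fit_ensemble_single_tensor,
    fit_saupe_svd,
    predict_rdc,
    q_factor,
)
from stereonmr.synthetic import NoiseSpec, make_study, random_tensor


def random_ch_conformer(rng, n_pairs=15):
    """Conformer of isolated C-H pairs pointing in random directions."""
    atoms = []
    for i in range(n_pairs):
        c = rng.uniform(-5, 5, 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        atoms.append(Atom(2 * i + 1, "C", c))
        atoms.append(Atom(2 * i + 2, "H", c + 1.09 * u))
    return Conformer(atoms, 0.0, "c1")


def records_for(conformer, n_pairs=15):
    return [
        RDCRecord((f"C{2 * i + 1}", f"H{2 * i + 2}"), 0.0) for i in range(n_pairs)
    ]


def synthesize(conformer, records, tensor):
    ens = ConformerEnsemble(None, [conformer], np.ones(1))
    vals = predict_rdc(ens, np.ones(1), tensor, records)
    return [
        RDCRecord(r.pair, float(v), r.error, r.include, r.is_methyl)
        for r, v in zip(records, vals)
    ]


class TestDipolarConstant:
    def test_matches_independent_unit_computation(self):
        # same physics assembled differently: b/2pi with hbar in SI
        hbar = H_PLANCK / (2 * np.pi)
        r = 1.09e-10
        expected = -MU0 * GAMMA["1H"] * GAMMA["13C"] * hbar / (
            8 * np.pi**2 * r**3
        )
        got = dipolar_constant(GAMMA["13C"], GAMMA["1H"], 1.09)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-23.33e3, rel=2e-3)  # known C-H value

    def test_inverse_cube_law(self):
        d1 = dipolar_constant(GAMMA["13C"], GAMMA["1H"], 1.0)
        d2 = dipolar_constant(GAMMA["13C"], GAMMA["1H"], 2.0)
        assert d1 == pytest.approx(8 * d2, rel=1e-12)

    def test_zero_gamma(self):
        assert dipolar_constant(GAMMA["13C"], 0.0, 1.09) == 0.0

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            dipolar_constant(GAMMA["13C"], GAMMA["1H"], 0.0)


class TestPredict:
    def test_axial_tensor_closed_form(self):
        s = 1e-3
        tensor = SaupeTensor.from_matrix(np.diag([-s / 2, -s / 2, s]))
        conf = Conformer([Atom(1, "C", [0, 0, 0]), Atom(2, "H", [0, 0, 1.09])])
        ens = ConformerEnsemble(None, [conf], np.ones(1))
        rec = [RDCRecord(("C1", "H2"), 0.0)]
        dmax = dipolar_constant(GAMMA["13C"], GAMMA["1H"], 1.09)
        got = predict_rdc(ens, np.ones(1), tensor, rec)[0]
        assert got == pytest.approx(dmax * s, rel=1e-12)

    def test_magic_angle_null(self):
        s = 1e-3
        tensor = SaupeTensor.from_matrix(np.diag([-s / 2, -s / 2, s]))
        theta = np.arccos(1 / np.sqrt(3))
        u = np.array([np.sin(theta), 0.0, np.cos(theta)])
        conf = Conformer([Atom(1, "C", [0, 0, 0]), Atom(2, "H", 1.09 * u)])
        ens = ConformerEnsemble(None, [conf], np.ones(1))
        got = predict_rdc(ens, np.ones(1), tensor, [RDCRecord(("C1", "H2"), 0.0)])[0]
        assert abs(got) < 1e-10

    def test_degenerate_weights_reduce_to_single_conformer(self, rng):
        c1 = random_ch_conformer(rng)
        c2 = random_ch_conformer(rng)
        c2 = Conformer(c2.atoms, 0.0, "c2")
        ens = ConformerEnsemble(None, [c1, c2], np.array([0.5, 0.5]))
        recs = records_for(c1)
        t = random_tensor(5)
        single = predict_rdc(
            ConformerEnsemble(None, [c1], np.ones(1)), np.ones(1), t, recs
        )
        both = predict_rdc(ens, np.array([1.0, 0.0]), t, recs)
        np.testing.assert_allclose(both, single, atol=1e-12)

    def test_linear_in_tensor(self, rng):
        conf = random_ch_conformer(rng)
        recs = records_for(conf)
        ens = ConformerEnsemble(None, [conf], np.ones(1))
        t = random_tensor(3)
        d1 = predict_rdc(ens, np.ones(1), t, recs)
        d3 = predict_rdc(ens, np.ones(1), SaupeTensor(3.0 * t.params), recs)
        np.testing.assert_allclose(d3, 3.0 * d1, rtol=1e-12)


class TestSvdFit:
    def test_exact_recovery_noise_free(self, rng):
        conf = random_ch_conformer(rng)
        recs = records_for(conf)
        true = random_tensor(17)
        data = synthesize(conf, recs, true)
        fitted = fit_saupe_svd(conf, data)
        np.testing.assert_allclose(fitted.params, true.params, atol=1e-10)

    def test_all_zero_rdcs_give_zero_tensor(self, rng):
        conf = random_ch_conformer(rng)
        fitted = fit_saupe_svd(conf, records_for(conf))
        np.testing.assert_allclose(fitted.params, 0.0, atol=1e-12)

    def test_too_few_records_rejected(self, rng):
        conf = random_ch_conformer(rng, n_pairs=4)
        with pytest.raises(ValueError):
            fit_saupe_svd(conf, records_for(conf, n_pairs=4))

    def test_error_scales_linearly_with_noise(self, rng):
        """Monte-Carlo: median componentwise error grows ~linearly in the
        noise level for small noise."""
        conf = random_ch_conformer(rng)
        recs = records_for(conf)
        true = random_tensor(29)
        clean = np.array([r.value for r in synthesize(conf, recs, true)])
        errs = {}
        for frac in (0.01, 0.02):
            trials = []
            for _ in range(150):
                noisy = clean + rng.normal(0, frac * np.ptp(clean), len(clean))
                data = [
                    RDCRecord(r.pair, v) for r, v in zip(recs, noisy)
                ]
                fit = fit_saupe_svd(conf, data)
                trials.append(np.abs(fit.params - true.params).max())
            errs[frac] = np.median(trials)
        ratio = errs[0.02] / errs[0.01]
        assert 1.5 < ratio < 2.6

    def test_fitted_tensor_traceless_symmetric(self, rng):
        conf = random_ch_conformer(rng)
        recs = records_for(conf)
        data = synthesize(conf, recs, random_tensor(31))
        m = fit_saupe_svd(conf, data).matrix
        assert abs(np.trace(m)) < 1e-10
        np.testing.assert_allclose(m, m.T, atol=1e-14)


class TestEnsembleFit:
    def test_single_conformer_reduces_to_svd(self, rng):
        conf = random_ch_conformer(rng)
        recs = records_for(conf)
        data = synthesize(conf, recs, random_tensor(41))
        ens = ConformerEnsemble(None, [conf], np.ones(1))
        res = fit_ensemble_single_tensor(ens, data)
        svd = fit_saupe_svd(conf, data)
        np.testing.assert_allclose(res.tensor.params, svd.params, atol=1e-9)
        np.testing.assert_allclose(res.populations, [1.0])
        assert res.n_params == 5

    def test_two_conformer_weight_recovery(self, clean_study):
        study = clean_study
        ens = study.ensembles[study.true_configuration.name]
        res = fit_ensemble_single_tensor(
            ens, study.observables.rdc, seed=study.seed
        )
        np.testing.assert_allclose(
            res.populations, study.true_populations, atol=0.02
        )
        np.testing.assert_allclose(
            res.tensor.params, study.true_tensor.params,
            atol=1e-6 * np.abs(study.true_tensor.params).max(),
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_wrong_configuration_fits_worse(self, seed):
        study = make_study(100 + seed, noise=NoiseSpec(rdc_frac=0.0))
        true_name = study.true_configuration.name
        fits = {
            name: fit_ensemble_single_tensor(
                ens, study.observables.rdc, seed=seed
            ).rss
            for name, ens in study.ensembles.items()
        }
        assert all(
            fits[true_name] < rss
            for name, rss in fits.items()
            if name != true_name
        )

    def test_model_results_summary(self, clean_study):
        study = clean_study
        model = SingleTensorRDCModel(
            study.ensembles[study.true_configuration.name],
            study.observables.rdc,
        )
        res = model.fit(seed=study.seed)
        text = res.summary()
        assert "Q factor" in text and "AIC" in text
        tj = res.tensor_json()
        assert len(tj["params"]) == 5 and len(tj["eigenvalues"]) == 3


class TestQFactor:
    def test_identical(self):
        assert q_factor([1.0, -2.0], [1.0, -2.0]) == 0.0

    def test_zero_calc(self):
        assert q_factor([0.0, 0.0], [3.0, -4.0]) == 1.0

    def test_ten_percent_scale(self):
        exp = np.array([5.0, -3.0, 8.0])
        assert q_factor(1.1 * exp, exp) == pytest.approx(0.1, rel=1e-12)

    def test_all_zero_experimental_rejected(self):
        with pytest.raises(ValueError):
            q_factor([1.0], [0.0])


class TestAIC:
    def test_closed_form(self):
        assert aic(15.0, 15, 5) == pytest.approx(10.0)

    def test_monotone_in_rss(self):
        vals = [aic(r, 15, 5) for r in (1.0, 2.0, 5.0, 50.0)]
        assert vals == sorted(vals)

    def test_parameter_penalty(self):
        assert aic(7.0, 20, 6) - aic(7.0, 20, 5) == pytest.approx(2.0)

    def test_rss_floor_keeps_finite(self):
        assert np.isfinite(aic(0.0, 15, 5))
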