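"""SVD diagnostics, IRF-convolved exponentials, global fits, and KCA."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pepc import (
    ConcentrationMatrix,
    ConditioningError,
    Curve,
    KineticModel,
    ScatteringDataset,
    SVDResult,
    autocorrelation,
    concentration_profiles,
    extract_sads,
    global_fit_rsvs,
    irf_exp,
    low_rank_approximation,
    select_rank,
    svd_decompose,
)
from pepc.sads import SADSSet

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _ds(matrix, q=None, t=None):
    matrix = np.asarray(matrix, dtype=float)
    q = np.arange(1.0, matrix.shape[0] + 1.0) if q is None else q
    t = np.arange(1.0, matrix.shape[1] + 1.0) if t is None else t
    return ScatteringDataset(q, t, matrix)


class TestSVD:
    def test_rank_one_matrix(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, -1.0, 0.5])
        svd = svd_decompose(_ds(np.outer(u, v)))
        assert np.sum(svd.sv > 1e-10 * svd.sv[0]) == 1

    def test_identity_singular_values(self):
        svd = svd_decompose(_ds(np.eye(2)))
        np.testing.assert_allclose(svd.sv, [1.0, 1.0])

    def test_orthonormality_and_reconstruction(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((40, 7))
        svd = svd_decompose(_ds(M))
        np.testing.assert_allclose(svd.lsv.T @ svd.lsv, np.eye(7), atol=1e-10)
        np.testing.assert_allclose(svd.rsv.T @ svd.rsv, np.eye(7), atol=1e-10)
        np.testing.assert_allclose(low_rank_approximation(svd, 7), M, atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        M = rng.standard_normal((30, 5))
        svd = svd_decompose(_ds(M))
        for i in range(5):
            j = np.argmax(np.abs(svd.lsv[:, i]))
            assert svd.lsv[j, i] > 0

    def test_three_species_rank(self):
        """A noiseless product of rank-3 factors has exactly 3 significant SVs."""
        from pepc import pepc_multi, scenario_gtc_like, simulate_dataset

        cfg = scenario_gtc_like(n_q=100, n_t=40)
        out = simulate_dataset(cfg)
        res = pepc_multi(out.dataset, cfg.solvent_basis)
        svd = svd_decompose(res.pepc)
        assert np.sum(svd.sv > 1e-9 * svd.sv[0]) == 3


class TestAutocorrelation:
    def test_constant_vector(self):
        assert autocorrelation(np.full(5, 3.0)) == pytest.approx(4.0 / 5.0)

    def test_alternating(self):
        assert autocorrelation(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(-0.75)

    def test_length_two(self):
        assert autocorrelation(np.array([1.0, 0.0])) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.zeros(4))


class TestSelectRank:
    def test_noiseless_rank_two(self):
        t = np.linspace(0, 10, 30)
        q = np.linspace(1, 5, 50)
        M = np.outer(np.sin(q), np.exp(-t)) + np.outer(np.cos(q), np.exp(-t / 5))
        svd = svd_decompose(_ds(M, q=q, t=t))
        assert select_rank(svd) == 2

    def test_pure_noise_rejected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            svd = svd_decompose(_ds(rng.standard_normal((80, 30))))
            hits += select_rank(svd) == 0
        assert hits >= 18  # noise vectors have near-zero autocorrelation

    def test_override_wins(self):
        rng = np.random.default_rng(1)
        svd = svd_decompose(_ds(rng.standard_normal((20, 10))))
        assert select_rank(svd, override=3) == 3


class TestIrfExp:
    def test_pure_exponential_limit(self):
        np.testing.assert_allclose(irf_exp(np.array([10.0]), 10.0), [math.exp(-1)])
        np.testing.assert_allclose(irf_exp(np.array([-0.1]), 10.0), [0.0])

    def test_half_height_at_t0(self):
        sigma = 0.48 * FWHM_TO_SIGMA
        val = irf_exp(np.array([0.0]), 1e6 * sigma, 0.0, 0.48)
        assert val[0] == pytest.approx(0.5, abs=1e-4)

    def test_step_limit(self):
        val = irf_exp(np.array([0.0, 100.0]), math.inf, 0.0, 0.48)
        np.testing.assert_allclose(val, [0.5, 1.0], atol=1e-12)

    @pytest.mark.parametrize("tau,fwhm", [(1.3, 0.48), (0.2, 1.0), (50.0, 0.1)])
    def test_matches_quadrature_convolution(self, tau, fwhm):
        sigma = fwhm * FWHM_TO_SIGMA
        t = np.linspace(-1.0, 5 * tau, 40)
        u = np.linspace(0.0, 5 * tau + 14 * sigma + 8 * tau, 200001)
        ker = np.exp(-u / tau)
        num = np.array(
            [
                np.trapezoid(
                    ker * np.exp(-((x - u) ** 2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi)),
                    u,
                )
                for x in t
            ]
        )
        ana = irf_exp(t, tau, 0.0, fwhm)
        mask = num > 1e-12 * num.max()
        np.testing.assert_allclose(ana[mask], num[mask], rtol=1e-6)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            irf_exp(np.array([0.0]), -1.0)


class TestGlobalFit:
    def _svd_from_profiles(self, t, profiles, sv=None):
        Y = np.column_stack(profiles)
        Q, _ = np.linalg.qr(Y)
        k = Y.shape[1]
        sv = np.ones(k) if sv is None else np.asarray(sv)
        return SVDResult(
            q=np.linspace(1, 2, 4), t=t, lsv=np.zeros((4, k)), sv=sv,
            rsv=Y / np.linalg.norm(Y, axis=0),
            lsv_autocorr=np.ones(k), rsv_autocorr=np.ones(k),
        )

    def test_single_exponential_recovery(self):
        t = np.geomspace(0.1, 5000, 60)
        svd = self._svd_from_profiles(t, [irf_exp(t, 50.0, 0.0, 0.48)])
        fit = global_fit_rsvs(svd, k=1, n_exp=1, irf_fwhm=0.48)
        assert fit.taus[0] == pytest.approx(50.0, rel=1e-3)

    def test_two_shared_constants(self):
        t = np.geomspace(0.1, 50000, 80)
        e1 = irf_exp(t, 5.0, 0.0, 0.48)
        e2 = irf_exp(t, 500.0, 0.0, 0.48)
        svd = self._svd_from_profiles(t, [2 * e1 - e2, 0.5 * e1 + 3 * e2])
        fit = global_fit_rsvs(svd, k=2, n_exp=2, irf_fwhm=0.48)
        np.testing.assert_allclose(fit.taus, [5.0, 500.0], rtol=5e-3)

    def test_taus_reported_ascending_with_amplitudes_permuted(self):
        t = np.geomspace(0.1, 50000, 80)
        e1 = irf_exp(t, 5.0, 0.0, 0.0)
        e2 = irf_exp(t, 500.0, 0.0, 0.0)
        svd = self._svd_from_profiles(t, [3 * e2 + 1 * e1])
        fit = global_fit_rsvs(svd, k=1, n_exp=2)
        assert fit.taus[0] < fit.taus[1]
        # amplitude of the slower constant must be ~3x the faster one (both scaled)
        ratio = fit.amplitudes[0, 1] / fit.amplitudes[0, 0]
        assert ratio == pytest.approx(3.0, rel=1e-3)

    def test_determinism(self):
        t = np.geomspace(0.1, 5000, 50)
        rng = np.random.default_rng(9)
        y = irf_exp(t, 30.0, 0.0, 0.48) + 0.02 * rng.standard_normal(t.size)
        svd = self._svd_from_profiles(t, [y])
        f1 = global_fit_rsvs(svd, k=1, n_exp=1, irf_fwhm=0.48)
        f2 = global_fit_rsvs(svd, k=1, n_exp=1, irf_fwhm=0.48)
        assert f1.taus[0] == f2.taus[0]
        assert f1.residual_norm == f2.residual_norm


class TestConcentrationProfiles:
    def test_two_state_textbook(self):
        model = KineticModel(species=["A", "B"], taus=np.array([10.0, 1e9]))
        t = np.linspace(0.0, 50.0, 40)
        conc = concentration_profiles(model, t)
        np.testing.assert_allclose(conc.C[:, 0], np.exp(-t / 10.0), atol=1e-9)
        # B decays with tau=1e9 ~ infinity on this window
        np.testing.assert_allclose(conc.C[:, 1], 1 - np.exp(-t / 10.0), atol=1e-6)

    def test_bateman_matches_ode(self):
        model = KineticModel(species=["A", "B", "C"], taus=np.array([10.0, 1000.0, 4000.0]))
        t = np.linspace(0.0, 8000.0, 60)
        conc = concentration_profiles(model, t)
        K = model.rate_matrix()
        sol = solve_ivp(
            lambda _, y: K @ y, (0, t[-1]), [1.0, 0.0, 0.0], t_eval=t, rtol=1e-11, atol=1e-13
        )
        np.testing.assert_allclose(conc.C, sol.y.T, atol=1e-8)

    def test_mass_conservation_with_irf(self):
        model = KineticModel(
            species=["A", "B", "C"], taus=np.array([1.7, 1000.0, 114000.0]), irf_fwhm=0.48
        )
        t = np.geomspace(0.1, 1e6, 50)
        conc = concentration_profiles(model, t)
        total = conc.C.sum(axis=1)
        assert np.all(total <= 1.0 + 1e-9)
        # ground state barely forms before ~10 ps (leakage through the chain)
        early = t < 10.0
        np.testing.assert_allclose(total[early], irf_exp(t[early], math.inf, 0.0, 0.48), atol=1e-6)

    def test_degenerate_rates_fall_back_to_ode(self):
        model = KineticModel(species=["A", "B"], taus=np.array([10.0, 10.0]))
        t = np.linspace(0.0, 40.0, 25)
        conc = concentration_profiles(model, t)
        # analytic degenerate chain: f_B = (t/tau) exp(-t/tau)
        np.testing.assert_allclose(conc.C[:, 1], (t / 10.0) * np.exp(-t / 10.0), atol=1e-7)

    def test_rate_matrix_scheme_matches_sequential(self):
        taus = np.array([5.0, 300.0])
        seq = KineticModel(species=["A", "B"], taus=taus, irf_fwhm=0.3)
        K = seq.rate_matrix()
        net = KineticModel(species=["A", "B"], scheme="rate_matrix", K=K, irf_fwhm=0.3)
        t = np.geomspace(0.05, 3000, 40)
        np.testing.assert_allclose(
            concentration_profiles(net, t).C, concentration_profiles(seq, t).C, atol=1e-9
        )


class TestExtractSads:
    def _make(self, seed=0, n_q=60):
        rng = np.random.default_rng(seed)
        q = np.linspace(1, 6, n_q)
        t = np.geomspace(0.1, 1e5, 30)
        model = KineticModel(species=["A", "B"], taus=np.array([5.0, 2000.0]), irf_fwhm=0.3)
        conc = concentration_profiles(model, t)
        conc = ConcentrationMatrix(t=t, C=conc.C, R=50.0, species=conc.species)
        S = rng.standard_normal((n_q, 2))
        ds = ScatteringDataset(q, t, (S @ conc.C.T) / conc.R)
        return ds, conc, S

    def test_noiseless_recovery(self):
        ds, conc, S = self._make()
        sads = extract_sads(ds, conc)
        np.testing.assert_allclose(sads.as_matrix(), S, rtol=1e-8, atol=1e-10)

    def test_single_species_algebra(self):
        q = np.linspace(1, 4, 20)
        t = np.geomspace(1.0, 100.0, 10)
        model = KineticModel(species=["A"], taus=np.array([30.0]))
        conc = concentration_profiles(model, t)
        conc = ConcentrationMatrix(t=t, C=conc.C, R=10.0, species=["A"])
        s_true = np.sin(q)
        ds = ScatteringDataset(q, t, np.outer(s_true, conc.C[:, 0]) / 10.0)
        sads = extract_sads(ds, conc)
        np.testing.assert_allclose(sads.curves[0].values, s_true, rtol=1e-10)

    def test_species_permutation_symmetry(self):
        ds, conc, S = self._make(seed=2)
        flipped = ConcentrationMatrix(
            t=conc.t, C=conc.C[:, ::-1], R=conc.R, species=list(conc.species[::-1])
        )
        sads = extract_sads(ds, conc)
        sads_f = extract_sads(ds, flipped)
        np.testing.assert_allclose(sads_f.as_matrix()[:, ::-1], sads.as_matrix(), atol=1e-10)

    def test_svd_rank_constrains_to_lsv_span(self):
        ds, conc, S = self._make(seed=3)
        rng = np.random.default_rng(99)
        noisy = ScatteringDataset(ds.q, ds.t, ds.matrix + 1e-3 * rng.standard_normal(ds.matrix.shape))
        sads = extract_sads(noisy, conc, svd_rank=2)
        svd = svd_decompose(noisy)
        U = svd.lsv[:, :2]
        for cv in sads.curves:
            resid = cv.values - U @ (U.T @ cv.values)
            assert np.linalg.norm(resid) < 1e-9 * np.linalg.norm(cv.values)

    def test_rank_deficient_concentrations_rejected(self):
        ds, conc, _ = self._make()
        bad = ConcentrationMatrix(
            t=conc.t, C=np.column_stack([0.5 * conc.C[:, 0], 0.5 * conc.C[:, 0]]), R=conc.R,
            species=["A", "B"],
        )
        with pytest.raises(ConditioningError):
            extract_sads(ds, bad)
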