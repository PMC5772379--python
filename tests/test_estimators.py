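"""BFM and SAIF estimators, delay search, bootstrap classifier."""

import itertools

import numpy as np
import pytest

from leupet.kinetics import (
    FrameSchedule,
    HomogeneousParams,
    TissueTAC,
    heterogeneous_tac,
    homogeneous_tac,
)
from leupet.estimators import (
    BasisFunctionModel,
    BasisSet,
    SpectralIterativeFilter,
    beta_grid,
    bfm_fit,
    bootstrap_heterogeneity,
    fit_delay,
    nonneg_lstsq,
    saif_fit,
    weights_from_variance,
)
from leupet.simulate import derive_heterogeneous


def brute_force_nnls(A, b):
    """Exhaustive active-set oracle: the NNLS optimum is the least-RSS
    feasible unconstrained solution over all column subsets."""
    n = A.shape[1]
    best_rss, best_x = np.dot(b, b), np.zeros(n)
    for r in range(1, n + 1):
        for idx in itertools.combinations(range(n), r):
            sol, *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
            if np.any(sol < -1e-12):
                continue
            x = np.zeros(n)
            x[list(idx)] = np.clip(sol, 0.0, None)
            rss = float(np.sum((b - A @ x) ** 2))
            if rss < best_rss - 1e-14:
                best_rss, best_x = rss, x
    return best_x, best_rss


class TestBetaGrid:
    def test_printed_grid(self):
        g = beta_grid()
        assert g.size == 100
        assert g[0] == pytest.approx(0.0037, rel=1e-12)
        assert g[-1] == pytest.approx(1.33, rel=1e-12)
        assert g[1] == pytest.approx(0.0039266, abs=5e-8)
        # constant ratio between consecutive values
        assert np.allclose(np.diff(np.log(g)), np.log(g[1] / g[0]))


class TestWeights:
    def test_uniform_tac_weights_follow_duration(self, schedule):
        tac = TissueTAC(schedule, np.full(42, 10.0))
        w = weights_from_variance(tac, gamma=0.0)
        assert np.allclose(w / w[0], schedule.durations / schedule.durations[0])

    def test_longer_frame_heavier(self, schedule):
        tac = TissueTAC(schedule, np.full(42, 10.0))
        w = weights_from_variance(tac, gamma=0.0)
        assert w[-1] > w[0]  # 300 s frame vs 15 s frame

    def test_floor_keeps_weights_finite(self, schedule):
        vals = np.full(42, 10.0)
        vals[3] = 0.0
        w = weights_from_variance(TissueTAC(schedule, vals))
        assert np.all(np.isfinite(w)) and w[3] > 0


class TestNNLSOracle:
    def test_matches_brute_force(self, rng):
        """scipy-backed solver vs exhaustive active-set enumeration on
        small (<=5-column, <=10-row) problems."""
        for _ in range(60):
            m = rng.integers(4, 11)
            n = rng.integers(2, 6)
            A = rng.standard_normal((m, n))
            b = rng.standard_normal(m)
            x, rss = nonneg_lstsq(A, b)
            x_ref, rss_ref = brute_force_nnls(A, b)
            assert rss == pytest.approx(rss_ref, abs=1e-8)
            assert np.allclose(x, x_ref, atol=1e-8)


class TestBFM:
    def test_exact_recovery_on_grid(self, inputs, schedule, basis):
        """Noise-free homogeneous TAC with true beta on the grid is
        recovered to 1e-6 relative."""
        beta = basis.grid[50]
        p = HomogeneousParams(0.05, 0.7 * beta, 0.3 * beta, Vb=0.05)
        tac = homogeneous_tac(p, inputs, schedule)
        res = bfm_fit(tac, basis)
        assert res.beta_hat == pytest.approx(beta, rel=1e-12)
        assert res.K1 == pytest.approx(p.K1, rel=1e-6)
        assert res.lam == pytest.approx(p.lam, rel=1e-6)
        assert res.rcps == pytest.approx(p.rcps(120.0), rel=1e-6)
        assert res.Vb == pytest.approx(0.05, rel=1e-6)

    def test_off_grid_quantization_small(self, inputs, schedule, basis, library):
        """Round-trip bias from grid quantization stays below 2%."""
        for p in library:
            tac = homogeneous_tac(p, inputs, schedule)
            res = bfm_fit(tac, basis)
            assert res.rcps == pytest.approx(p.rcps(120.0), rel=0.02)
            assert res.K1 == pytest.approx(p.K1, rel=0.02)
            assert res.lam == pytest.approx(p.lam, rel=0.02)

    def test_pure_blood_tac(self, inputs, schedule, basis):
        p = HomogeneousParams(0.0, 0.0, 0.0, Vb=0.05)
        tac = homogeneous_tac(p, inputs, schedule)
        res = bfm_fit(tac, basis)
        assert res.K1 == pytest.approx(0.0, abs=1e-10)
        assert res.rcps == pytest.approx(0.0, abs=1e-10)
        assert res.Vb == pytest.approx(0.05, abs=1e-6)

    def test_all_zero_tac(self, schedule, basis):
        res = bfm_fit(np.zeros(42), basis)
        assert res.K1 == 0.0 and res.rcps == 0.0 and res.degenerate_flag

    def test_nonnegativity_guaranteed(self, basis, rng):
        """Even on adversarial noise the reported estimates are >= 0."""
        for _ in range(20):
            y = rng.standard_normal(42) * 5.0
            res = bfm_fit(y, basis)
            assert res.K1 >= 0 and res.lam >= 0 and res.rcps >= 0 and res.Vb >= 0

    def test_wrss_minimal_at_true_beta(self, inputs, schedule, basis):
        """On noise-free on-grid data the winning grid point is the truth."""
        beta = basis.grid[40]
        p = HomogeneousParams(0.04, 0.75 * beta, 0.25 * beta, Vb=0.05)
        tac = homogeneous_tac(p, inputs, schedule)
        res = bfm_fit(tac, basis)
        assert res.beta_hat == pytest.approx(beta, rel=1e-12)
        assert res.wrss < 1e-12


class TestSAIF:
    def test_homogeneous_round_trip(self, inputs, schedule, basis):
        """Noise-free one-component TAC inside the band: one merged
        component, macros within 2%."""
        p = HomogeneousParams(0.05, 0.1, 0.04, Vb=0.05)  # beta = 0.14, in band
        tac = homogeneous_tac(p, inputs, schedule)
        res = saif_fit(tac, basis)
        assert res.n_components == 1
        assert res.K1 == pytest.approx(p.K1, rel=0.02)
        assert res.lam == pytest.approx(p.lam, rel=0.02)
        assert res.rcps == pytest.approx(p.rcps(120.0), rel=0.02)

    def test_two_component_detection(self, inputs, schedule, basis):
        """Noise-free two-subregion TAC with well-separated in-band rates."""
        h = HomogeneousParams(0.05, 0.1, 0.04, Vb=0.05)
        mix = derive_heterogeneous(h)  # betas 0.2333 and 0.0467, both in band
        tac = heterogeneous_tac(mix, inputs, schedule)
        res = saif_fit(tac, basis)
        assert res.n_components == 2
        assert res.rcps == pytest.approx(h.rcps(120.0), rel=0.02)

    def test_trap_only_degenerate(self, inputs, schedule, basis):
        p = HomogeneousParams(0.05, 0.0, 0.04, Vb=0.05)
        tac = homogeneous_tac(p, inputs, schedule)
        res = saif_fit(tac, basis)
        assert res.degenerate_flag
        assert res.lam == 0.0

    def test_spectral_mass_reproduces_tac(self, inputs, schedule, basis):
        """Fitted trap + in-band + blood decomposition reproduces in-model
        noise-free data with WRSS ~ 0."""
        h = HomogeneousParams(0.04, 0.08, 0.03, Vb=0.05)
        tac = heterogeneous_tac(derive_heterogeneous(h), inputs, schedule)
        res = saif_fit(tac, basis)
        assert res.wrss < 1e-10 * float(np.sum(tac.values**2))
        assert np.allclose(res.fittedvalues, tac.values, rtol=1e-4, atol=1e-8)

    def test_empty_band_rejected(self, inputs, schedule, basis):
        with pytest.raises(ValueError):
            SpectralIterativeFilter(np.zeros(42), basis, band=(0.3, 0.02))

    def test_nonnegativity_guaranteed(self, basis, rng):
        for _ in range(20):
            y = rng.standard_normal(42) * 5.0
            res = saif_fit(y, basis)
            assert res.K1 >= 0 and res.lam >= 0 and res.rcps >= 0 and res.Vb >= 0

    def test_bfm_overestimates_on_heterogeneous(self, inputs, schedule, basis, library):
        """Model-mismatch asymmetry on noise-free heterogeneous TACs:
        BFM rCPS >= SAIF rCPS, BFM overestimates truth, for every entry."""
        for h in library:
            tac = heterogeneous_tac(derive_heterogeneous(h), inputs, schedule)
            rb = bfm_fit(tac, basis)
            rs = saif_fit(tac, basis)
            truth = h.rcps(120.0)
            assert rb.rcps >= rs.rcps
            assert rb.rcps > truth
            assert abs(rs.rcps - truth) < abs(rb.rcps - truth)

    def test_summary_smoke(self, inputs, schedule, basis):
        p = HomogeneousParams(0.05, 0.1, 0.04, Vb=0.05)
        res = saif_fit(homogeneous_tac(p, inputs, schedule), basis)
        text = res.summary()
        assert "SAIF" in text and "rCPS" in text


class TestDelay:
    def test_zero_shift_recovered(self, inputs, schedule):
        p = HomogeneousParams(0.05, 0.1, 0.04, Vb=0.05)
        tac = homogeneous_tac(p, inputs, schedule)
        d = fit_delay(tac, inputs, candidates_s=np.arange(0.0, 21.0, 5.0))
        assert d == 0.0

    def test_ten_second_shift_recovered(self, inputs, schedule):
        p = HomogeneousParams(0.05, 0.1, 0.04, Vb=0.05)
        shifted = inputs.shifted(10.0 / 60.0)
        tac = homogeneous_tac(p, shifted, schedule)
        d = fit_delay(tac, inputs, candidates_s=np.arange(0.0, 21.0, 1.0))
        assert d == 10.0


class TestBootstrap:
    def test_noise_free_homogeneous_not_flagged(self, inputs, schedule, basis):
        p = HomogeneousParams(0.05, 0.1, 0.04, Vb=0.05)
        tac = homogeneous_tac(p, inputs, schedule)
        flag, prob = bootstrap_heterogeneity(tac, basis, n_boot=20, seed=3)
        assert prob <= 0.05
        assert not flag

    def test_deterministic_under_seed(self, inputs, schedule, basis, library):
        from leupet.simulate import add_noise, noise_model_for_level

        tac0 = homogeneous_tac(library[4], inputs, schedule)
        noise = noise_model_for_level("voxel", inputs, schedule, seed=9)
        y = add_noise(tac0, noise, 1)[0]
        tac = TissueTAC(schedule, y)
        r1 = bootstrap_heterogeneity(tac, basis, n_boot=25, seed=11)
        r2 = bootstrap_heterogeneity(tac, basis, n_boot=25, seed=11)
        assert r1 == r2

    def test_rejects_bad_n_boot(self, inputs, schedule, basis):
        p = HomogeneousParams(0.05, 0.1, 0.04, Vb=0.05)
        tac = homogeneous_tac(p, inputs, schedule)
        with pytest.raises(ValueError):
            bootstrap_heterogeneity(tac, basis, n_boot=0)
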