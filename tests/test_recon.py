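import numpy as np
import pytest

from batmap.phantom import TruthMaps, build_neck_phantom, simulate_multiecho
from batmap.protocol import AcquisitionProtocol, FatSpectrum
from batmap.recon import (
    DegenerateBasisError,
    ReconOptions,
    estimate_fieldmap_multiscale,
    estimate_r2s,
    fat_modulation,
    reconstruct_maps,
    solve_wf,
)

TE6 = AcquisitionProtocol().echo_times


class TestFatModulation:
    def test_on_resonance_single_peak_is_unity(self):
        s = FatSpectrum.single_peak(0.0)
        assert np.allclose(fat_modulation(s, TE6), 1.0)

    def test_half_period_phase_gives_minus_one(self):
        s = FatSpectrum.single_peak(-217.0)
        te = 1.0 / (2 * 217.0)
        assert fat_modulation(s, [te])[0] == pytest.approx(-1.0 + 0j, abs=1e-12)

    def test_zero_echo_time_gives_one(self, nine_peak):
        assert fat_modulation(nine_peak, [0.0])[0] == pytest.approx(1.0 + 0j)

    def test_magnitude_bounded_by_one(self, nine_peak):
        te = np.linspace(0, 30e-3, 301)
        assert np.all(np.abs(fat_modulation(nine_peak, te)) <= 1 + 1e-12)

    def test_empty_echo_times_rejected(self, nine_peak):
        with pytest.raises(ValueError):
            fat_modulation(nine_peak, [])


def _model_signal(spectrum, w, f, psi, r2s, te=TE6):
    c = fat_modulation(spectrum, te)
    return (w + f * c) * np.exp((2j * np.pi * psi - r2s) * te)


class TestSolveWf:
    def test_self_consistency_at_truth(self, nine_peak):
        s = _model_signal(nine_peak, 0.2, 0.8, 33.0, 21.0)
        w, f, res = solve_wf(s, TE6, nine_peak, 33.0, 21.0)
        assert w == pytest.approx(0.2, abs=1e-12)
        assert f == pytest.approx(0.8, abs=1e-12)
        assert res == pytest.approx(0.0, abs=1e-12)

    def test_zero_signal_gives_zero_amplitudes(self, nine_peak):
        w, f, res = solve_wf(np.zeros(6, complex), TE6, nine_peak, 10.0, 5.0)
        assert w == 0 and f == 0 and res == 0

    def test_pure_fat_recovers_ff_one(self, nine_peak):
        s = _model_signal(nine_peak, 0.0, 1.0, -40.0, 15.0)
        w, f, _ = solve_wf(s, TE6, nine_peak, -40.0, 15.0)
        assert f / (f + w) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_basis_flagged(self):
        s = FatSpectrum.single_peak(0.0)  # c_n == 1 for all echoes
        with pytest.raises(DegenerateBasisError):
            solve_wf(np.ones(6, complex), TE6, s, 0.0, 0.0)

    def test_vectorised_over_voxels(self, nine_peak):
        sig = np.stack(
            [_model_signal(nine_peak, 0.5, 0.5, 10.0, 20.0),
             _model_signal(nine_peak, 0.9, 0.1, 10.0, 20.0)]
        )
        w, f, res = solve_wf(sig, TE6, nine_peak, np.full(2, 10.0), np.full(2, 20.0))
        assert np.allclose(w, [0.5, 0.9], atol=1e-10)
        assert np.allclose(f, [0.5, 0.1], atol=1e-10)


def _uniform_truth(shape, ff, r2s, psi):
    return TruthMaps(
        water=np.full(shape, 1 - ff),
        fat=np.full(shape, ff),
        r2s=np.full(shape, float(r2s)),
        fieldmap=np.full(shape, float(psi)),
        label=np.ones(shape, dtype=np.int16),
    )


def _brute_force_fieldmap(signal2d, te, spectrum, cand):
    """Independent oracle: per-voxel exhaustive search over the candidate
    list (same tie order) using the public linear solver."""
    out = np.empty(signal2d.shape[0])
    for v in range(signal2d.shape[0]):
        best, best_res = 0, np.inf
        for i, psi in enumerate(cand):
            _, _, res = solve_wf(signal2d[v], te, spectrum, psi, 0.0)
            if res < best_res:  # strict: first occurrence keeps the tie order
                best, best_res = i, res
        out[v] = cand[best]
    return out


class TestFieldmap:
    def test_constant_field_recovered(self, nine_peak):
        proto = AcquisitionProtocol(grid_shape=(10, 10, 2))
        truth = _uniform_truth((10, 10, 2), 0.6, 20.0, 40.0)
        img = simulate_multiecho(truth, proto, nine_peak, noise_sd=0.0)
        psi = estimate_fieldmap_multiscale(img, nine_peak, ReconOptions())
        assert np.all(np.abs(psi - 40.0) <= 2.0)

    def test_mu_zero_equals_brute_force(self, nine_peak):
        proto = AcquisitionProtocol(grid_shape=(8, 8, 2))
        # small phantom with a spatially varying field
        truth = _uniform_truth((8, 8, 2), 0.7, 25.0, 0.0)
        truth.fieldmap[:] = np.linspace(-60, 60, 8)[:, None, None]
        img = simulate_multiecho(truth, proto, nine_peak, noise_sd=0.02, seed=3)
        opts = ReconOptions(mu=0.0, n_scales=1)
        psi = estimate_fieldmap_multiscale(img, nine_peak, opts).reshape(-1)
        cand = opts.psi_candidates(proto.delta_te)
        oracle = _brute_force_fieldmap(img.signal.reshape(-1, 6), proto.echo_times,
                                       nine_peak, cand)
        assert np.array_equal(psi, oracle)

    def test_smoothness_penalty_non_increasing_in_mu(self, nine_peak):
        proto = AcquisitionProtocol(grid_shape=(16, 16, 4))
        truth = _uniform_truth((16, 16, 4), 0.8, 20.0, 0.0)
        truth.fieldmap[:] = np.linspace(-50, 50, 16)[:, None, None]
        img = simulate_multiecho(truth, proto, nine_peak, noise_sd=0.05, seed=7)

        def smoothness(psi):
            tot = 0.0
            for ax in range(3):
                d = np.diff(psi, axis=ax)
                tot += float((d * d).sum())
            return tot

        pens = []
        for mu in (0.0, 1.0, 10.0, 100.0):
            psi = estimate_fieldmap_multiscale(img, nine_peak, ReconOptions(mu=mu))
            pens.append(smoothness(psi))
        assert all(a >= b - 1e-9 for a, b in zip(pens, pens[1:]))


class TestEstimateR2s:
    def test_noiseless_voxel_recovered_within_step(self, nine_peak):
        s = _model_signal(nine_peak, 0.17, 0.83, 12.0, 21.0)
        r = estimate_r2s(s[None, :], TE6, nine_peak, np.array([12.0]))
        assert abs(r[0] - 21.0) <= 0.5

    def test_no_decay_voxel_gives_zero(self, nine_peak):
        s = _model_signal(nine_peak, 0.3, 0.7, -25.0, 0.0)
        r = estimate_r2s(s[None, :], TE6, nine_peak, np.array([-25.0]))
        assert r[0] == 0.0

    def test_decoupled_equals_joint_2d_search_noiseless(self, nine_peak):
        """1D R2* search at the true psi matches the exhaustive joint
        (psi, R2*) grid minimiser for noiseless voxels."""
        opts = ReconOptions()
        cand_psi = opts.psi_candidates(2.87e-3)
        cand_r = opts.r2s_candidates()
        for w, f, psi, r2s in [(0.2, 0.8, 40.0, 21.0), (0.8, 0.2, -16.0, 30.0)]:
            s = _model_signal(nine_peak, w, f, psi, r2s)
            best = (None, None, np.inf)
            for p in cand_psi[np.abs(cand_psi - psi) <= 6]:
                for r in cand_r[np.abs(cand_r - r2s) <= 3]:
                    _, _, res = solve_wf(s, TE6, nine_peak, p, r)
                    if res < best[2]:
                        best = (p, r, res)
            r_est = estimate_r2s(s[None, :], TE6, nine_peak, np.array([best[0]]))
            assert r_est[0] == pytest.approx(best[1], abs=0.5)


class TestReconstructMaps:
    def test_noiseless_phantom_exact_inversion(self, truth_small, image_noiseless, nine_peak):
        maps = reconstruct_maps(image_noiseless, nine_peak)
        body = truth_small.label > 0
        assert np.median(np.abs(maps.ff - truth_small.ff)[body]) < 1e-6
        assert np.abs(maps.ff - truth_small.ff)[body].max() < 1e-6
        assert np.abs(maps.r2s - truth_small.r2s)[body].max() < 0.5

    def test_background_voxels_flagged_degenerate(self, truth_small, image_noiseless, nine_peak):
        maps = reconstruct_maps(image_noiseless, nine_peak)
        background = truth_small.label == 0
        assert np.all(maps.degenerate[background])
        assert np.all(maps.ff[background] == 0.0)

    def test_map_invariants(self, image_snr50, nine_peak):
        maps = reconstruct_maps(image_snr50, nine_peak)
        assert np.all((maps.ff >= 0) & (maps.ff <= 1))
        assert np.all(maps.r2s >= 0)
        assert np.all(maps.r2s <= 150.0)
        for name in ("water", "fat", "ff", "r2s", "fieldmap", "residual"):
            assert np.all(np.isfinite(getattr(maps, name)))

    def test_sbat_voi_mean_ff_at_snr50(self, truth_small, image_snr50, nine_peak):
        maps = reconstruct_maps(image_snr50, nine_peak)
        sbat = truth_small.mask("sbat")
        est = 100 * maps.ff[sbat].mean()
        true = 100 * truth_small.ff[sbat].mean()
        assert est == pytest.approx(true, abs=0.5)

    def test_ff_bias_below_1pp_across_ff_r2s_grid(self, nine_peak):
        """Monte-Carlo noise-robustness: |bias| < 1 pp over a grid of true
        FF x R2* at SNR 50 (>=200 voxels per cell)."""
        ffs = [0.1, 0.3, 0.5, 0.7, 0.9]
        r2ss = [10.0, 30.0, 60.0]
        nz = 4
        ncol = 300 // nz  # voxels per cell = 15*5*4 = 300
        shape = (len(ffs) * 15, len(r2ss) * 5, nz)
        ff_map = np.zeros(shape)
        r2s_map = np.zeros(shape)
        for i, ffv in enumerate(ffs):
            ff_map[i * 15:(i + 1) * 15] = ffv
        for j, rv in enumerate(r2ss):
            r2s_map[:, j * 5:(j + 1) * 5] = rv
        truth = TruthMaps(
            water=1 - ff_map, fat=ff_map.copy(), r2s=r2s_map,
            fieldmap=np.full(shape, 17.0), label=np.ones(shape, np.int16),
        )
        proto = AcquisitionProtocol(grid_shape=shape)
        img = simulate_multiecho(truth, proto, nine_peak, noise_sd=0.02, seed=21)
        maps = reconstruct_maps(img, nine_peak)
        for i, ffv in enumerate(ffs):
            for j, rv in enumerate(r2ss):
                cell = (ff_map == ffv) & (r2s_map == rv)
                bias = 100 * (maps.ff[cell] - ffv).mean()
                assert abs(bias) < 1.0, f"FF={ffv} R2*={rv}: bias {bias:.2f} pp"
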