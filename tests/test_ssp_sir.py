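import numpy as np
import pytest

from tmsclean import evaluate, ssp_sir
from tmsclean import artifact_sim as asim
from tmsclean.epochs import EpochedData, epoch_times

TIMES = epoch_times(-50.0, 150.0, 1000.0)
LABELS = tuple(f"ch{i}" for i in range(8))


def _epochs(data, fs=1000.0, times=TIMES):
    labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return EpochedData(data, fs, times, labels)


TIMES_5K = epoch_times(-50.0, 150.0, 5000.0)


def _sine_epochs(freq_hz, n_ch=8, n_tr=3):
    t = TIMES_5K / 1000.0
    x = np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (n_ch, 1))[:, :, None] * np.ones((1, 1, n_tr))
    return EpochedData(
        data, 5000.0, TIMES_5K, tuple(f"ch{i}" for i in range(n_ch))
    )


class TestHighpass:
    core = slice(250, 750)  # away from epoch edges

    def test_stopband_kills_10hz(self):
        inp = _sine_epochs(10.0)
        out = ssp_sir.highpass_filter(inp, 100.0)
        assert np.sqrt((out.data[:, self.core, :] ** 2).mean()) < 0.01 * np.sqrt(
            (inp.data[:, self.core, :] ** 2).mean()
        )

    def test_passband_preserves_200hz(self):
        inp = _sine_epochs(200.0)
        out = ssp_sir.highpass_filter(inp, 100.0)
        rin = np.sqrt((inp.data[:, self.core, :] ** 2).mean())
        rout = np.sqrt((out.data[:, self.core, :] ** 2).mean())
        assert abs(rout - rin) < 0.01 * rin

    def test_ground_truth_mostly_removed(self, small_gt):
        out = ssp_sir.highpass_filter(small_gt, 100.0)
        assert np.sqrt((out.data**2).mean()) < 0.05 * np.sqrt(
            (small_gt.data**2).mean()
        )

    def test_invalid_cutoff(self, small_gt):
        with pytest.raises(ValueError, match="cutoff"):
            ssp_sir.highpass_filter(small_gt, 2000.0)


class TestArtifactBasis:
    def _rank1(self, n_ch=8, n_tr=4):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(n_ch)
        u /= np.linalg.norm(u)
        tc = rng.standard_normal((TIMES.size, n_tr))
        mask = (TIMES >= -10) & (TIMES <= 30)
        tc[~mask] = 0.0
        return _epochs(u[:, None, None] * tc[None]), u

    def test_rank1_recovery(self):
        data, u = self._rank1()
        basis = ssp_sir.estimate_artifact_basis(data)
        assert abs(np.dot(basis.U[:, 0], u)) > 0.999

    def test_orthonormal_and_sorted(self):
        data, _ = self._rank1()
        basis = ssp_sir.estimate_artifact_basis(data)
        n = basis.U.shape[0]
        assert np.linalg.norm(basis.U.T @ basis.U - np.eye(n)) < 1e-9
        assert np.all(np.diff(basis.singular_values) <= 1e-12)

    def test_empty_window(self):
        data, _ = self._rank1()
        with pytest.raises(ValueError, match="no samples"):
            ssp_sir.estimate_artifact_basis(data, window_ms=(500.0, 600.0))


class TestSelect:
    def _basis(self, n=6):
        U = np.linalg.qr(np.random.default_rng(1).standard_normal((n, n)))[0]
        return ssp_sir.ArtifactBasis(U, np.linspace(2.0, 1.0, n))

    def test_exact_match_selects_that_index(self):
        basis = self._basis()
        idx = ssp_sir.select_artifact_dim(basis, basis.U[:, 3])
        assert idx == (3,)

    def test_sign_flip_still_selected(self):
        basis = self._basis()
        assert ssp_sir.select_artifact_dim(basis, -basis.U[:, 2]) == (2,)

    def test_tie_breaks_to_lowest_index(self):
        U = np.eye(4)
        basis = ssp_sir.ArtifactBasis(U, np.ones(4))
        u = np.array([1.0, 1.0, 0.0, 0.0]) / np.sqrt(2)
        assert ssp_sir.select_artifact_dim(basis, u) == (0,)

    def test_general_mode_top_k(self):
        basis = self._basis()
        assert ssp_sir.select_artifact_dim(basis, None, k=2) == (0, 1)

    def test_selection_on_corrupted_data(self, corrupted_small):
        corr, real = corrupted_small
        hp = ssp_sir.highpass_filter(
            corr.copy_with(corr.data - corr.data.mean(axis=0, keepdims=True))
        )
        basis = ssp_sir.estimate_artifact_basis(hp)
        idx = ssp_sir.select_artifact_dim(basis, real.topography)
        cos = abs(np.dot(basis.U[:, idx[0]], real.topography))
        assert cos > 0.95


class TestProjector:
    def _basis(self, n=10):
        U = np.linalg.qr(np.random.default_rng(2).standard_normal((n, n)))[0]
        return ssp_sir.ArtifactBasis(U, np.linspace(2.0, 1.0, n))

    def test_k0_is_identity(self):
        basis = self._basis()
        proj = ssp_sir.make_projector(basis, ())
        assert np.allclose(proj.P, np.eye(10))

    def test_annihilates_selected_vectors(self):
        basis = self._basis()
        proj = ssp_sir.make_projector(basis, (1, 4))
        for i in (1, 4):
            assert np.linalg.norm(proj.P @ basis.U[:, i]) < 1e-9

    def test_algebra_to_1e9(self):
        basis = self._basis()
        proj = ssp_sir.make_projector(basis, (0,))
        P = proj.P
        assert np.linalg.norm(P - P.T) < 1e-9
        assert np.linalg.norm(P @ P - P) < 1e-9
        assert np.trace(P) == pytest.approx(9.0, abs=1e-9)

    def test_all_channels_selected_raises(self):
        basis = self._basis(4)
        with pytest.raises(ValueError, match="every channel"):
            ssp_sir.make_projector(basis, (0, 1, 2, 3))


class TestSIR:
    def test_identity_on_leadfield_range(self, sir_leadfield):
        rng = np.random.default_rng(4)
        L = sir_leadfield.gain
        x = rng.standard_normal((L.shape[1], 50, 2))
        y = np.einsum("cs,stn->ctn", L, x)
        data = EpochedData(
            y, 1000.0, epoch_times(0, 50, 1000.0),
            sir_leadfield.montage.labels,
        )
        P = ssp_sir.Projector(np.eye(60), 0)
        out = ssp_sir.sir_reconstruct(P, sir_leadfield, data)
        err = np.linalg.norm(out.data - y) / np.linalg.norm(y)
        assert err < 1e-3

    def test_linearity(self, sir_leadfield):
        rng = np.random.default_rng(5)
        times = epoch_times(0, 10, 1000.0)
        mk = lambda arr: EpochedData(arr, 1000.0, times, sir_leadfield.montage.labels)
        y = rng.standard_normal((60, times.size, 1))
        z = rng.standard_normal((60, times.size, 1))
        basis = ssp_sir.ArtifactBasis(
            np.linalg.qr(rng.standard_normal((60, 60)))[0], np.linspace(2, 1, 60)
        )
        proj = ssp_sir.make_projector(basis, (0,))
        f = lambda d: ssp_sir.sir_reconstruct(proj, sir_leadfield, mk(d)).data
        assert np.allclose(
            f(2.0 * y + 3.0 * z), 2.0 * f(y) + 3.0 * f(z), atol=1e-9
        )

    def test_rejected_topography_suppressed(
        self, corrupted_small, small_gt, sir_leadfield
    ):
        # residual artifact energy along the rejected direction must be a
        # tiny fraction of what the corruption put there (reconstruction
        # legitimately restores *brain* signal along that direction, so the
        # comparison is against the residual, not the output)
        corr, real = corrupted_small
        res = ssp_sir.clean_dataset_ssp_sir(
            corr, sir_leadfield, known_topography=real.topography
        )
        mask = corr.time_mask(0.0, 25.0)
        u = real.topography
        before = u @ (corr.data - small_gt.data)[:, mask, :].reshape(60, -1)
        after = u @ (res.data.data - small_gt.data)[:, mask, :].reshape(60, -1)
        assert np.linalg.norm(after) < 0.05 * np.linalg.norm(before)

    def test_zero_leadfield_raises(self, sir_leadfield, small_gt):
        import dataclasses

        zero = dataclasses.replace(sir_leadfield, gain=np.zeros_like(sir_leadfield.gain))
        P = ssp_sir.Projector(np.eye(60), 0)
        with pytest.raises(ValueError, match="zero"):
            ssp_sir.sir_reconstruct(P, zero, small_gt)


class TestApplyWindowed:
    def _pair(self):
        rng = np.random.default_rng(6)
        orig = _epochs(rng.standard_normal((4, TIMES.size, 2)))
        cleaned = orig.copy_with(np.zeros_like(orig.data))
        return orig, cleaned

    def test_identical_inputs_identity(self):
        orig, _ = self._pair()
        out = ssp_sir.apply_windowed(orig, orig)
        assert np.array_equal(out.data, orig.data)

    def test_sample_at_100ms_bit_exact(self):
        orig, cleaned = self._pair()
        out = ssp_sir.apply_windowed(orig, cleaned)
        j = int(np.argmin(np.abs(TIMES - 100.0)))
        assert np.array_equal(out.data[:, j, :], orig.data[:, j, :])

    def test_inside_window_is_cleaned(self):
        orig, cleaned = self._pair()
        out = ssp_sir.apply_windowed(orig, cleaned)
        j = int(np.argmin(np.abs(TIMES - 10.0)))  # mid-window, beyond blending
        assert np.array_equal(out.data[:, j, :], cleaned.data[:, j, :])

    def test_blending_reduces_splice_discontinuity(self):
        # a correction that ends abruptly at the window edge (ramp) splices
        # with a jump; the median blend must reduce that jump.  (A constant
        # offset step is edge-preserved by *any* median filter and cannot be
        # reduced; the ramp is the meaningful transient case.)
        orig = _epochs(np.zeros((4, TIMES.size, 2)))
        mask = orig.time_mask(-10.0, 30.0)
        ramp = np.zeros_like(orig.data)
        ramp[:, mask, :] = np.linspace(0.0, 10.0, mask.sum())[None, :, None]
        cleaned = orig.copy_with(orig.data + ramp)
        spliced_raw = orig.data.copy()
        spliced_raw[:, mask, :] = cleaned.data[:, mask, :]
        out = ssp_sir.apply_windowed(orig, cleaned)
        edge = int(np.flatnonzero(mask)[-1])
        d_raw = np.abs(np.diff(spliced_raw[:, edge - 2: edge + 3, :], axis=1)).max()
        d_blend = np.abs(np.diff(out.data[:, edge - 2: edge + 3, :], axis=1)).max()
        assert d_blend < d_raw

    def test_window_outside_epoch_raises(self):
        orig, cleaned = self._pair()
        with pytest.raises(ValueError, match="outside"):
            ssp_sir.apply_windowed(orig, cleaned, window_ms=(400.0, 500.0))


class TestFullCleaning:
    def test_zero_amplitude_artifact_low_distortion(self, small_gt, bank, sir_leadfield):
        # intrinsic cost of projecting one dimension out of clean data
        u = bank.topography(1.0, 3)
        corr = small_gt.copy_with(small_gt.data.copy())
        res = ssp_sir.clean_dataset_ssp_sir(corr, sir_leadfield, known_topography=u)
        re = evaluate.relative_error(res.data, small_gt).mean_re
        assert re < 0.02

    def test_dissimilar_artifact_cleaned_10x(self, corrupted_small, small_gt, sir_leadfield):
        corr, real = corrupted_small
        res = ssp_sir.clean_dataset_ssp_sir(
            corr, sir_leadfield, known_topography=real.topography
        )
        re_corr = evaluate.relative_error(corr, small_gt).mean_re
        re_clean = evaluate.relative_error(res.data, small_gt).mean_re
        assert re_clean < re_corr / 10.0

    def test_late_window_untouched(self, corrupted_small, small_gt, sir_leadfield):
        corr, real = corrupted_small
        res = ssp_sir.clean_dataset_ssp_sir(
            corr, sir_leadfield, known_topography=real.topography
        )
        re_late = evaluate.relative_error(res.data, small_gt, (50.0, 100.0)).mean_re
        assert re_late <= 0.0018

    def test_alpha_insensitivity(self, small_gt, bank, sir_leadfield):
        res_by_alpha = []
        for alpha in (0.0, 0.5, 1.0):
            cond = asim.ArtifactCondition(alpha, 1.0 / 100.0, 250.0, seed=2)
            real = asim.simulate_realization(
                cond, small_gt.times, small_gt.fs, small_gt.n_trials,
                bank=bank, rng=np.random.default_rng(7), source_index=4,
            )
            corr = asim.superpose(small_gt, real)
            res = ssp_sir.clean_dataset_ssp_sir(
                corr, sir_leadfield, known_topography=real.topography
            )
            res_by_alpha.append(evaluate.relative_error(res.data, small_gt).mean_re)
        assert max(res_by_alpha) < 2.0 * min(res_by_alpha)

    def test_provenance_recorded(self, corrupted_small, sir_leadfield):
        corr, real = corrupted_small
        res = ssp_sir.clean_dataset_ssp_sir(
            corr, sir_leadfield, known_topography=real.topography
        )
        assert res.method == "ssp_sir"
        assert res.info["k"] == 1
        assert res.info["projector_rank"] == 59
        assert res.info["selection_abs_cos"] > 0.95
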