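import itertools

import numpy as np
import pytest

from ecogspeech import artalign, syndata
from ecogspeech.tracks import FeatureTrack


def brute_force_dtw(cost):
    """Exhaustive enumeration of all monotone boundary-anchored paths."""
    n, m = cost.shape
    best = (np.inf, None)

    def extend(path, total):
        nonlocal best
        i, j = path[-1]
        if (i, j) == (n - 1, m - 1):
            if total < best[0]:
                best = (total, list(path))
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                path.append((ni, nj))
                extend(path, total + cost[ni, nj])
                path.pop()

    extend([(0, 0)], cost[0, 0])
    return best


class TestMidsagittalProjection:
    def test_output_dimension(self, rng):
        track = FeatureTrack(rng.standard_normal((50, 27)),
                             [f"s{i}" for i in range(27)])
        out = artalign.project_midsagittal(track)
        assert out.n_features == 14

    def test_wrong_sensor_count_rejected(self, rng):
        bad = FeatureTrack(rng.standard_normal((50, 24)),
                           [f"s{i}" for i in range(24)])
        with pytest.raises(ValueError):
            artalign.project_midsagittal(bad)

    def test_planar_motion_fully_preserved(self, rng):
        # one sensor moving in a tilted plane: 2 components keep all variance
        n = 200
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        basis = np.linalg.qr(rng.standard_normal((3, 2)))[0]
        planar = np.column_stack([a, b]) @ basis.T
        data = rng.standard_normal((n, 27)) * 0.01
        data[:, 6:9] = planar  # upper_lip slot (sensor index 2)
        out = artalign.project_midsagittal(
            FeatureTrack(data, [f"s{i}" for i in range(27)])
        )
        recon_var = out.data[:, 0:2].var(axis=0).sum()
        assert recon_var == pytest.approx(planar.var(axis=0).sum(), rel=1e-9)

    def test_reconstruction_error_equals_dropped_component(self, rng):
        n = 500
        xyz = rng.standard_normal((n, 3)) * np.array([3.0, 2.0, 0.5])
        data = np.zeros((n, 27))
        data[:, 6:9] = xyz
        out = artalign.project_midsagittal(
            FeatureTrack(data, [f"s{i}" for i in range(27)])
        )
        # eigendecomposition oracle: variance lost = smallest eigenvalue
        evals = np.linalg.eigvalsh(np.cov(xyz.T))
        lost = xyz.var(axis=0, ddof=1).sum() - out.data[:, 0:2].var(axis=0, ddof=1).sum()
        assert lost == pytest.approx(evals[0], rel=1e-6)


class TestDtwFeatures:
    def test_dimension_and_normalization(self, small_corpora):
        _, ref, _, _, _ = small_corpora
        feats = artalign.build_dtw_features(ref[0])
        assert feats.n_features == 27
        assert np.max(np.abs(feats.data[:, 0])) == pytest.approx(1.0)

    def test_unvoiced_sentence_gives_zero_f0_column(self, small_corpora):
        _, ref, _, _, _ = small_corpora
        s = ref[0]
        silent_f0 = FeatureTrack(np.zeros((s.n_frames, 1)), ["f0"])
        feats = artalign.build_dtw_features(s.with_tracks(f0=silent_f0))
        assert np.all(feats.data[:, 25] == 0)

    def test_f0_column_bounded(self, small_corpora):
        _, ref, _, _, _ = small_corpora
        feats = artalign.build_dtw_features(ref[1])
        assert np.all((feats.data[:, 25] >= 0) & (feats.data[:, 25] <= 1))


class TestResampleToLength:
    def test_same_length_is_identity(self, rng):
        track = FeatureTrack(rng.standard_normal((40, 3)), list("abc"))
        out = artalign.resample_to_length(track, 40)
        assert np.max(np.abs(out.data - track.data)) < 1e-9

    def test_linear_ramp_stays_linear(self):
        ramp = FeatureTrack(np.linspace(0, 1, 20)[:, None], ["x"])
        out = artalign.resample_to_length(ramp, 77)
        assert np.allclose(out.data[:, 0], np.linspace(0, 1, 77), atol=1e-9)

    def test_endpoints_preserved(self, rng):
        track = FeatureTrack(rng.standard_normal((30, 2)), ["a", "b"])
        out = artalign.resample_to_length(track, 55)
        assert np.allclose(out.data[0], track.data[0])
        assert np.allclose(out.data[-1], track.data[-1])

    def test_too_few_frames_rejected(self, rng):
        track = FeatureTrack(rng.standard_normal((30, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            artalign.resample_to_length(track, 1)

    def test_monotone_data_never_overshoots(self):
        step = np.concatenate([np.zeros(10), np.ones(10)])
        out = artalign.resample_to_length(
            FeatureTrack(step[:, None], ["x"]), 97
        )
        assert out.data.min() >= -1e-12 and out.data.max() <= 1 + 1e-12


class TestDtwAlign:
    def test_identical_tracks_diagonal_zero_cost(self, rng):
        t = FeatureTrack(rng.standard_normal((20, 4)), list("abcd"))
        path = artalign.dtw_align(t, t)
        assert path == [(i, i) for i in range(20)]
        assert artalign.path_cost(path, t, t) == 0.0

    def test_length_mismatch_rejected(self, rng):
        a = FeatureTrack(rng.standard_normal((10, 2)), ["a", "b"])
        b = FeatureTrack(rng.standard_normal((11, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            artalign.dtw_align(a, b)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        a = FeatureTrack(rng.standard_normal((n, 2)), ["a", "b"])
        b = FeatureTrack(rng.standard_normal((n, 2)), ["a", "b"])
        path = artalign.dtw_align(a, b)
        cost = artalign.path_cost(path, a, b)
        d = a.data[:, None, :] - b.data[None, :, :]
        best_cost, _ = brute_force_dtw(np.einsum("ijk,ijk->ij", d, d))
        assert cost == pytest.approx(best_cost, rel=1e-12)

    def test_cost_symmetric_under_swap(self, rng):
        a = FeatureTrack(rng.standard_normal((12, 3)), list("abc"))
        b = FeatureTrack(rng.standard_normal((12, 3)), list("abc"))
        c_ab = artalign.path_cost(artalign.dtw_align(a, b), a, b)
        c_ba = artalign.path_cost(artalign.dtw_align(b, a), b, a)
        assert c_ab == pytest.approx(c_ba, rel=1e-12)

    def test_path_is_monotone_and_anchored(self, rng):
        a = FeatureTrack(rng.standard_normal((15, 3)), list("abc"))
        b = FeatureTrack(rng.standard_normal((15, 3)), list("abc"))
        path = artalign.dtw_align(a, b)
        assert path[0] == (0, 0) and path[-1] == (14, 14)
        steps = set(
            (i2 - i1, j2 - j1) for (i1, j1), (i2, j2) in zip(path, path[1:])
        )
        assert steps <= {(1, 0), (0, 1), (1, 1)}


class TestTransfer:
    def test_identity_path_returns_reference(self, rng):
        ema = FeatureTrack(rng.standard_normal((20, 14)),
                           list(artalign.EMA_LABELS))
        path = [(i, i) for i in range(20)]
        out = artalign.transfer_articulation(path, ema, 20)
        assert np.allclose(out.data, ema.data)

    def test_output_within_reference_range(self, rng):
        ema = FeatureTrack(rng.standard_normal((20, 14)),
                           list(artalign.EMA_LABELS))
        path = artalign.dtw_align(
            FeatureTrack(rng.standard_normal((20, 3)), list("abc")),
            FeatureTrack(rng.standard_normal((20, 3)), list("abc")),
        )
        out = artalign.transfer_articulation(path, ema, 20)
        assert np.all(out.data.max(axis=0) <= ema.data.max(axis=0) + 1e-12)
        assert np.all(out.data.min(axis=0) >= ema.data.min(axis=0) - 1e-12)

    def test_inconsistent_path_rejected(self, rng):
        ema = FeatureTrack(rng.standard_normal((5, 14)),
                           list(artalign.EMA_LABELS))
        with pytest.raises(ValueError):
            artalign.transfer_articulation([(0, 0), (9, 4)], ema, 5)


class TestEndToEndAlignment:
    """Cross-speaker transfer on synthetic pairs with known warps."""

    def test_warp_recovery_and_ema_transfer(self, audio_corpora):
        _, ref, _, pat, pat_gt = audio_corpora
        warp_errors, ema_rs, better = [], [], []
        for r, p in zip(ref, pat):
            est, path = artalign.estimate_patient_ema(r, p)
            m = p.tracks["mel"].n_frames
            # estimated reference position per patient frame, mapped back to
            # the original (unresampled) reference frame scale
            pos = artalign.path_to_ref_positions(path, m) * (r.n_frames - 1) / (m - 1)
            warp_errors.append(np.mean(np.abs(pos - pat_gt.true_warps[p.sentence_id])))
            for j in range(est.n_features):
                ema_rs.append(np.corrcoef(est.data[:, j], p.tracks["ema"].data[:, j])[0, 1])
            # DTW-aligned reference mel should beat the identity alignment
            ref_mel_rs = artalign.resample_to_length(r.tracks["mel"], m)
            warped = artalign.warp_reference_track(path, ref_mel_rs, m)
            r_dtw = np.corrcoef(warped.data[:, 0], p.tracks["mel"].data[:, 0])[0, 1]
            r_id = np.corrcoef(ref_mel_rs.data[:, 0], p.tracks["mel"].data[:, 0])[0, 1]
            better.append(r_dtw >= r_id)
        assert np.mean(warp_errors) <= 2.0  # frames
        assert np.min(ema_rs) > 0.95
        assert np.mean(better) > 0.8


class TestSqrtDistanceVariant:
    def test_sqrt_metric_gives_valid_monotone_path(self, rng):
        a = FeatureTrack(rng.standard_normal((12, 3)), list("abc"))
        b = FeatureTrack(rng.standard_normal((12, 3)), list("abc"))
        path = artalign.dtw_align(a, b, use_sqrt=True)
        assert path[0] == (0, 0) and path[-1] == (11, 11)
        cost = artalign.path_cost(path, a, b, use_sqrt=True)
        assert cost >= 0
        # on identical tracks both metrics agree on the diagonal
        same = artalign.dtw_align(a, a, use_sqrt=True)
        assert same == [(i, i) for i in range(12)]
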