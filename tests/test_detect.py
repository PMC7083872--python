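"""Detection chain: flattening, discoidal filter, thresholding, linking."""

import numpy as np
import pandas as pd
import pytest

import intervalkinetics as ik
from intervalkinetics import detect


def brute_force_discoidal(image, r_inner=1, r_outer=3):
    """Double-loop reference: disc mean minus annulus mean, zero padding."""
    h, w = image.shape
    out = np.zeros_like(image, dtype=float)
    offs = [
        (dy, dx)
        for dy in range(-r_outer, r_outer + 1)
        for dx in range(-r_outer, r_outer + 1)
    ]
    inner = [(dy, dx) for dy, dx in offs if dy * dy + dx * dx <= r_inner**2]
    annulus = [
        (dy, dx)
        for dy, dx in offs
        if r_inner**2 < dy * dy + dx * dx <= r_outer**2
    ]
    for y in range(h):
        for x in range(w):
            def mean_over(pts):
                total = 0.0
                for dy, dx in pts:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        total += image[yy, xx]
                return total / len(pts)

            out[y, x] = mean_over(inner) - mean_over(annulus)
    return out


class TestDiscoidalFilter:
    def test_constant_image_maps_to_zero(self):
        img = np.full((32, 32), 7.3)
        filt = detect.discoidal_filter(img)
        # zero-padded boundary breaks the cancellation only near edges
        assert np.allclose(filt[3:-3, 3:-3], 0.0, atol=1e-12)

    def test_impulse_response_peaks_at_impulse(self):
        img = np.zeros((21, 21))
        img[10, 10] = 5.0
        filt = detect.discoidal_filter(img)
        # every pixel whose inner disc contains the impulse ties for the max
        assert filt[10, 10] == filt.max()
        ys, xs = np.nonzero(filt == filt.max())
        assert np.all(np.hypot(ys - 10, xs - 10) <= 1)

    def test_gaussian_spot_centre_and_brute_force_equality(self):
        yy, xx = np.mgrid[0:33, 0:33]
        img = np.exp(-((xx - 16.3) ** 2 + (yy - 15.7) ** 2) / (2 * 1.2**2))
        filt = detect.discoidal_filter(img)
        peak = np.unravel_index(np.argmax(filt), filt.shape)
        assert abs(peak[0] - 15.7) <= 1 and abs(peak[1] - 16.3) <= 1
        np.testing.assert_allclose(filt, brute_force_discoidal(img), atol=1e-10)

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            img = rng.normal(size=(24, 24))
            np.testing.assert_allclose(
                detect.discoidal_filter(img), brute_force_discoidal(img),
                atol=1e-10,
            )

    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            detect.discoidal_filter(np.zeros((32, 32)), r_inner=3, r_outer=3)
        with pytest.raises(ValueError):
            detect.discoidal_filter(np.zeros((4, 4)))


class TestFlattenBackground:
    def test_constant_image_flattens_to_zero(self):
        img = np.full((64, 64), 120.0)
        out = detect.flatten_background(img)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_planar_gradient_removed(self):
        yy, xx = np.mgrid[0:128, 0:128]
        gradient = 50.0 + 0.5 * xx + 0.2 * yy
        out = detect.flatten_background(gradient)
        interior = out[30:-30, 30:-30]
        amplitude = gradient.max() - gradient.min()
        assert np.abs(interior).max() < 0.01 * amplitude

    def test_zero_stack_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="constant-zero"):
            out = detect.flatten_background(np.zeros((2, 16, 16)))
        assert np.all(out == 0)

    def test_detection_robust_to_illumination_gradient(self, small_movie):
        """Recall on a gradient-corrupted movie matches the flat-field one."""
        protocol = small_movie.protocol
        phase2 = small_movie.stack[protocol.n_bleach_frames:].astype(float)
        yy, xx = np.mgrid[0:256, 0:256]
        corrupted = phase2 + (0.8 * xx + 0.3 * yy)[None, :, :]
        d_flat = detect.detect_stack(phase2, cell_masks=small_movie.cell_masks)
        d_corr = detect.detect_stack(corrupted, cell_masks=small_movie.cell_masks)
        assert len(d_corr) >= 0.95 * len(d_flat)


class TestDetectFoci:
    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(1)
        filt = detect.discoidal_filter(rng.normal(0, 1, size=(64, 64)))
        assert detect.detect_foci(filt, threshold_multiple=8) == []

    def test_single_bright_spot_detected_once(self):
        rng = np.random.default_rng(2)
        img = rng.normal(0, 1, size=(64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        img += 60 * np.exp(-((xx - 30.0) ** 2 + (yy - 22.0) ** 2) / (2 * 1.2**2))
        dets = detect.detect_foci(detect.discoidal_filter(img))
        assert len(dets) == 1
        assert abs(dets[0].x_px - 30.0) < 1 and abs(dets[0].y_px - 22.0) < 1

    def test_recall_precision_on_ground_truth(self, small_movie):
        protocol = small_movie.protocol
        dets = detect.detect_stack(
            small_movie.stack[protocol.n_bleach_frames:],
            cell_masks=small_movie.cell_masks,
        )
        gt = small_movie.emitter_table.copy()
        gt["frame"] -= protocol.n_bleach_frames
        matched_det = 0
        for r in dets.itertuples():
            sub = gt[gt["frame"] == r.frame]
            if len(sub) and np.min(
                np.hypot(sub["x_px"] - r.x_px, sub["y_px"] - r.y_px)
            ) < 2:
                matched_det += 1
        matched_gt = 0
        for g in gt.itertuples():
            sub = dets[dets["frame"] == g.frame]
            if len(sub) and np.min(
                np.hypot(sub["x_px"] - g.x_px, sub["y_px"] - g.y_px)
            ) < 2:
                matched_gt += 1
        assert matched_det / len(dets) >= 0.95       # precision
        assert matched_gt / len(gt) >= 0.95          # recall


def _df(rows):
    return pd.DataFrame(
        rows, columns=["frame", "x_px", "y_px", "filtered_intensity",
                       "raw_integrated_intensity"]
    )


class TestLinking:
    def test_static_focus_forms_one_track(self):
        dets = _df([(f, 10.0, 10.0, 5.0, 50.0) for f in range(1, 6)])
        tracks = detect.link_foci(dets)
        assert len(tracks) == 1
        assert tracks[0].duration_frames == 5

    def test_displacement_beyond_radius_splits(self):
        dets = _df([(1, 10.0, 10.0, 5.0, 50.0), (2, 14.0, 10.0, 5.0, 50.0)])
        tracks = detect.link_foci(dets, radius_px=3)
        assert [t.duration_frames for t in tracks] == [1, 1]

    def test_gap_closes_track(self):
        dets = _df([(1, 10.0, 10.0, 5.0, 50.0), (3, 10.0, 10.0, 5.0, 50.0)])
        tracks = detect.link_foci(dets)
        assert [t.duration_frames for t in tracks] == [1, 1]

    def test_conservation_and_order_invariance(self):
        rng = np.random.default_rng(3)
        rows = [
            (f, rng.uniform(0, 50), rng.uniform(0, 50), 5.0, 50.0)
            for f in range(10)
            for _ in range(6)
        ]
        dets = _df(rows)
        tracks = detect.link_foci(dets)
        assert sum(t.duration_frames for t in tracks) == len(dets)
        shuffled = dets.sample(frac=1.0, random_state=0).reset_index(drop=True)
        tracks2 = detect.link_foci(shuffled)
        sig = sorted((t.start_frame, t.duration_frames, round(t.x_px, 6))
                     for t in tracks)
        sig2 = sorted((t.start_frame, t.duration_frames, round(t.x_px, 6))
                      for t in tracks2)
        assert sig == sig2

    def test_track_durations_match_simulated_events(self, small_movie):
        protocol = small_movie.protocol
        dets = detect.detect_stack(
            small_movie.stack[protocol.n_bleach_frames:],
            cell_masks=small_movie.cell_masks,
        )
        tracks = detect.link_foci(dets, radius_px=3, tau_tl=small_movie.tau_tl)
        truth = small_movie.event_table
        matched = 0
        for ev in truth.itertuples():
            # rendering clips events at the end of the movie
            expected = min(ev.n_frames, protocol.n_sm_frames - ev.start_frame)
            ok = any(
                t.start_frame == ev.start_frame
                and abs(t.x_px - ev.x_px) < 2
                and abs(t.y_px - ev.y_px) < 2
                and t.duration_frames == expected
                for t in tracks
            )
            matched += ok
        assert matched / len(truth) >= 0.95


class TestIntensityReadouts:
    def test_zero_cell_has_zero_copies(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        assert detect.estimate_copy_number(mask, np.zeros((32, 32)), 100.0) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            detect.estimate_copy_number(
                np.zeros((8, 8), dtype=bool), np.zeros((8, 8)), 1.0
            )

    def test_copy_number_counts_rendered_emitters(self):
        """20 equal emitters in one cell integrate to ~20 molecules."""
        protocol = ik.AcquisitionProtocol(
            tau_tl_grid=(0.1,), frame_shape=(192, 192), n_bleach_frames=0,
            n_sm_frames=1,
        )
        model = ik.KineticModel(amplitudes=(1.0,), off_rates=(1e-6,), k_b=1e-9)
        movie = ik.simulate_movie(
            model, protocol, cells=1, emitters_per_cell=20, seed=21,
            background_mean=50.0, noise_sd=2.0, spot_flux=2000.0,
            cell_background=0.0,
        )
        frame0 = movie.stack[0].astype(float)
        corrected = frame0 - 50.0  # known synthetic background
        n_rendered = (movie.emitter_table["frame"] == 0).sum()
        assert n_rendered == 20
        copies = detect.estimate_copy_number(
            np.ones_like(frame0, dtype=bool), corrected,
            single_molecule_intensity=2000.0,
        )
        assert copies == pytest.approx(20.0, rel=0.05)

    def test_single_molecule_intensity_is_median(self):
        dets = _df([(0, 1, 1, 5.0, 90.0), (1, 1, 1, 5.0, 100.0),
                    (2, 1, 1, 5.0, 400.0)])
        assert detect.single_molecule_intensity(dets) == 100.0

    def test_timecourse_flat_constant_emitters(self):
        rng = np.random.default_rng(5)
        masks = np.zeros((64, 64), dtype=int)
        masks[20:40, 20:40] = 1
        base = np.full((64, 64), 100.0)
        base[masks > 0] += 50.0
        snaps = [base + rng.normal(0, 1, base.shape) for _ in range(6)]
        tc = detect.intensity_timecourse(snaps, masks, list(range(0, 1800, 300)),
                                         flatten=False)
        # normalise against raw integrated signal: flat within a few percent
        assert np.allclose(tc["norm_intensity"], 1.0, atol=0.05)

    def test_timecourse_ramp_reaches_threefold(self):
        masks = np.zeros((64, 64), dtype=int)
        masks[20:40, 20:40] = 1
        snaps = []
        for level in np.linspace(1.0, 3.0, 7):
            img = np.zeros((64, 64))
            img[masks > 0] = 50.0 * level
            snaps.append(img)
        tc = detect.intensity_timecourse(snaps, masks,
                                         list(np.arange(7) * 300.0),
                                         flatten=False)
        final = tc[tc["time_s"] == tc["time_s"].max()]["norm_intensity"].iloc[0]
        assert final == pytest.approx(3.0, rel=0.10)

    def test_timecourse_step_changepoint(self):
        masks = np.zeros((64, 64), dtype=int)
        masks[10:30, 10:30] = 1
        snaps = []
        for i in range(8):
            img = np.zeros((64, 64))
            img[masks > 0] = 50.0 if i < 4 else 150.0
            snaps.append(img)
        tc = detect.intensity_timecourse(snaps, masks, list(np.arange(8.0)),
                                         flatten=False)
        trace = tc.sort_values("time_s")["norm_intensity"].to_numpy()
        jumps = np.diff(trace)
        assert np.argmax(jumps) == 3
        assert jumps[3] > 5 * np.abs(np.delete(jumps, 3)).max() + 1e-12

    def test_timecourse_requires_timestamps(self):
        masks = np.ones((8, 8), dtype=int)
        with pytest.raises(ValueError):
            detect.intensity_timecourse([np.zeros((8, 8))], masks, [1.0, 2.0])
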