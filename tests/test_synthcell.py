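"""Synthetic-data generator: ground-truth correctness and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from peritrack import synthcell
from peritrack.synthcell import SimulationConfig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_on_per_min": -0.1},
            {"k_off_per_min": 0.0},
            {"n_cells": 0},
            {"bleach_rate_per_frame": 1.0},
            {"bleach_rate_per_frame": -0.2},
            {"pixel_size_nm": 600.0},  # violates PSF sampling bound
            {"nucleoid_l": 0.7},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_error_names_offending_parameter(self):
        with pytest.raises(ValueError, match="k_off_per_min"):
            SimulationConfig(k_off_per_min=-1.0)


class TestTranscriptionCounts:
    def test_population_mean_matches_immigration_death_theory(self):
        """Mean count follows a(1 - e^(-bt)) with a=k_on/k_off, b=k_off.

        Checked at every sampled time against the closed-form M/M/inf mean,
        within 3 standard errors at 10,000 cells; at t=5 min the expected
        value is 0.4107 x (1 - e^(-5.6)) ~ 0.409.
        """
        cfg = SimulationConfig(
            n_cells=10_000, k_on_per_min=0.46, k_off_per_min=1.12,
            duration_s=300.0, frame_interval_s=30.0, seed=7,
        )
        truth = synthcell.simulate_transcription_counts(cfg)
        a = 0.46 / 1.12
        expected = a * (1.0 - np.exp(-1.12 * truth.frame_times_s / 60.0))
        mean = truth.counts.mean(axis=0)
        se = truth.counts.std(axis=0, ddof=1) / np.sqrt(cfg.n_cells)
        assert mean[0] == 0.0  # induction starts empty
        assert np.all(np.abs(mean[1:] - expected[1:]) < 3.0 * se[1:])
        assert abs(mean[-1] - 0.409) < 3.0 * se[-1]

    def test_event_log_is_consistent(self):
        cfg = SimulationConfig(n_cells=50, duration_s=300.0, seed=3)
        truth = synthcell.simulate_transcription_counts(cfg)
        truth.validate()
        for arr, dep in zip(truth.arrivals_s, truth.departures_s):
            assert np.all(dep > arr)

    def test_fixed_seed_reproduces_event_logs(self):
        cfg = SimulationConfig(n_cells=20, duration_s=120.0, seed=11)
        t1 = synthcell.simulate_transcription_counts(cfg)
        t2 = synthcell.simulate_transcription_counts(cfg)
        assert np.array_equal(t1.counts, t2.counts)
        for a1, a2 in zip(t1.arrivals_s, t2.arrivals_s):
            assert np.array_equal(a1, a2)

    def test_fixed_dwell_mode_has_same_mean_curve_plateau(self):
        cfg = SimulationConfig(
            n_cells=5000, duration_s=600.0, frame_interval_s=60.0,
            dwell_mode="fixed", seed=9,
        )
        truth = synthcell.simulate_transcription_counts(cfg)
        plateau = truth.counts[:, -1].mean()
        se = truth.counts[:, -1].std(ddof=1) / np.sqrt(cfg.n_cells)
        assert abs(plateau - 0.46 / 1.12) < 3.0 * se


class TestRenderFrames:
    def test_rendered_flux_is_conserved(self):
        """A single bound polymerase integrates to single_fluor_intensity.

        Background and noise off; tolerance 1% for Gaussian tail truncation.
        """
        cfg = SimulationConfig(
            n_cells=1, background_level=0.0, camera_noise_sd=0.0,
            shot_noise=False, duration_s=10.0, frame_interval_s=10.0, seed=5,
        )
        truth = synthcell.simulate_transcription_counts(cfg)
        truth.counts[:] = 1
        frames, masks, _ = synthcell.render_frames(cfg, truth)
        total = frames[0].sum()
        assert total == pytest.approx(cfg.single_fluor_intensity, rel=0.01)

    def test_zero_polymerases_zero_background_gives_zero_frame(self):
        cfg = SimulationConfig(
            n_cells=2, background_level=0.0, camera_noise_sd=0.0,
            shot_noise=False, duration_s=10.0, frame_interval_s=10.0, seed=6,
        )
        truth = synthcell.simulate_transcription_counts(cfg)
        truth.counts[:] = 0
        frames, _, _ = synthcell.render_frames(cfg, truth)
        assert np.all(frames == 0.0)

    def test_bleaching_survival_matches_geometric_law(self):
        """Mean visible lifetime of a permanently bound fluorophore.

        With per-frame bleaching probability p the number of frames a
        fluorophore stays visible is geometric; the observed mean survival
        over many cells must match the brute-force enumeration of the
        geometric expectation truncated to the movie length.
        """
        p = 0.1
        n_frames = 12
        cfg = SimulationConfig(
            n_cells=400, background_level=0.0, camera_noise_sd=0.0,
            shot_noise=False, bleach_rate_per_frame=p,
            duration_s=(n_frames - 1) * 10.0, frame_interval_s=10.0, seed=8,
        )
        truth = synthcell.simulate_transcription_counts(cfg)
        truth.counts[:] = 1  # permanently bound
        frames, masks, _ = synthcell.render_frames(cfg, truth)
        visible = np.array(
            [
                [frames[f][masks == cid].sum() > 1.0 for f in range(n_frames)]
                for cid in range(1, cfg.n_cells + 1)
            ]
        )
        observed = visible.sum(axis=1).mean()
        # brute-force expectation: visible in frame f iff survived f draws
        expected = sum((1.0 - p) ** f for f in range(n_frames))
        sd = np.sqrt(
            sum((1.0 - p) ** f * (1 - (1.0 - p) ** f) for f in range(n_frames))
        )
        assert abs(observed - expected) < 4.0 * sd / np.sqrt(cfg.n_cells) + 0.05

    def test_locus_outside_mask_rejected(self, small_config):
        truth = synthcell.simulate_transcription_counts(small_config)
        truth.locus_xsec_nm[0, :, 0] = 5000.0  # far outside the cell
        with pytest.raises(ValueError, match="outside"):
            synthcell.render_frames(small_config, truth)

    def test_mask_labels_match_cells(self, small_config):
        truth = synthcell.simulate_transcription_counts(small_config)
        _, masks, layout = synthcell.render_frames(small_config, truth)
        assert set(np.unique(masks)) == set(range(small_config.n_cells + 1))
        assert len(layout) == small_config.n_cells


class TestRadialRelocation:
    def test_zero_step_leaves_positions_unchanged(self):
        cfg = SimulationConfig(n_cells=30, duration_s=100.0, seed=2)
        truth = synthcell.simulate_transcription_counts(cfg)
        moved = synthcell.simulate_radial_relocation(truth, 0.0, onset_s=50.0)
        assert np.array_equal(moved.locus_xsec_nm, truth.locus_xsec_nm)

    def test_mean_radial_displacement_is_the_requested_step(self):
        """Fixed-magnitude relocation moves loci outward by 61 nm on average."""
        cfg = SimulationConfig(n_cells=2000, duration_s=100.0, seed=4)
        truth = synthcell.simulate_transcription_counts(cfg)
        moved = synthcell.simulate_radial_relocation(truth, 61.0, onset_s=50.0, seed=1)
        r_before = np.hypot(*truth.locus_xsec_nm[:, 0, :].T)
        r_after = np.hypot(*moved.locus_xsec_nm[:, -1, :].T)
        assert np.mean(r_after - r_before) == pytest.approx(61.0, abs=0.5)
        assert moved.displacement_nm.mean() == pytest.approx(61.0)

    def test_positions_before_onset_unchanged(self):
        cfg = SimulationConfig(n_cells=10, duration_s=100.0, frame_interval_s=10.0, seed=4)
        truth = synthcell.simulate_transcription_counts(cfg)
        moved = synthcell.simulate_radial_relocation(truth, 61.0, onset_s=55.0, seed=1)
        before = truth.frame_times_s < 55.0
        assert np.array_equal(
            moved.locus_xsec_nm[:, before, :], truth.locus_xsec_nm[:, before, :]
        )

    def test_negative_step_rejected(self):
        cfg = SimulationConfig(n_cells=2, duration_s=50.0, seed=1)
        truth = synthcell.simulate_transcription_counts(cfg)
        with pytest.raises(ValueError):
            synthcell.simulate_radial_relocation(truth, -1.0, onset_s=10.0)

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(n_cells=20, duration_s=100.0, seed=4)
        truth = synthcell.simulate_transcription_counts(cfg)
        m1 = synthcell.simulate_radial_relocation(truth, 30.0, 50.0, "exponential", seed=5)
        m2 = synthcell.simulate_radial_relocation(truth, 30.0, 50.0, "exponential", seed=5)
        assert np.array_equal(m1.locus_xsec_nm, m2.locus_xsec_nm)


class TestDecaySeries:
    def test_half_life_definition(self):
        table = synthcell.simulate_decay_series(5.5, [0.0, 5.5], noise_cv=0.0)
        assert table.abundance.iloc[1] / table.abundance.iloc[0] == pytest.approx(0.5)

    def test_noise_free_values_match_direct_evaluation(self):
        """2^(-t/5.5) at t = 0..10 step 2, frozen to 4 decimals."""
        table = synthcell.simulate_decay_series(
            5.5, [0, 2, 4, 6, 8, 10], noise_cv=0.0, initial_abundance=1.0
        )
        expected = [1.0, 0.7772, 0.6040, 0.4695, 0.3649, 0.2836]
        assert np.allclose(np.round(table.abundance.to_numpy(), 4), expected)

    def test_noisy_series_reproducible_under_seed(self):
        t1 = synthcell.simulate_decay_series(5.5, [0, 2, 4], noise_cv=0.05, seed=3)
        t2 = synthcell.simulate_decay_series(5.5, [0, 2, 4], noise_cv=0.05, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    @pytest.mark.parametrize("bad", [{"half_life_min": 0.0}, {"noise_cv": -0.1}])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = {"half_life_min": 5.5, "sample_times_min": [0, 2], "noise_cv": 0.0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            synthcell.simulate_decay_series(**kwargs)


class TestProbeOnsets:
    def test_onset_difference_is_separation_over_rate(self):
        table = synthcell.simulate_probe_onsets(90.0, [900.0, 2700.0], duration_s=60.0)
        near = table[table.amplicon_1 > 0].time_s.iloc[0]
        far = table[table.amplicon_2 > 0].time_s.iloc[0]
        # sampled onsets straddle the exact 10 s and 30 s delays
        assert near - 10.0 <= 10.0 and far - 10.0 <= 30.0 + 10.0

    def test_duplicate_probe_positions_rejected(self):
        with pytest.raises(ValueError):
            synthcell.simulate_probe_onsets(90.0, [900.0, 900.0])

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            synthcell.simulate_probe_onsets(0.0, [900.0, 2700.0])
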