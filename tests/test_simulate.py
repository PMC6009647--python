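import numpy as np
import pytest

from mtagmap.simulate import (
    NM_PER_BP,
    GroundTruthEmitter,
    MovieConfig,
    SimConfig,
    simulate_kinetics,
    simulate_molecules,
    simulate_movie,
    simulate_plasmid_field,
    traces_from_frame,
    traces_to_frame,
)


class TestSimConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(p_site=1.2)
        with pytest.raises(ValueError):
            SimConfig(rho_off=-1)

    def test_presets(self):
        c = SimConfig.preset("plasmid")
        assert (c.p_site, c.rho_off) == (0.63, 0.37)
        f = SimConfig.preset("combed-fragment")
        assert (f.p_site, f.rho_off) == (0.92, 0.46)
        with pytest.raises(KeyError):
            SimConfig.preset("nope")


class TestSimulateMolecules:
    def test_no_labeling_gives_empty_traces(self, amplicon_map):
        cfg = SimConfig(p_site=0, rho_off=0, n_molecules=20, seed=1)
        traces, truths = simulate_molecules(amplicon_map, cfg)
        assert all(len(t.label_positions) == 0 for t in traces)

    def test_noiseless_limit_maps_sites_exactly(self, amplicon_map):
        cfg = SimConfig(p_site=1, p_second=0, rho_off=0, sigma_loc=0,
                        stretch_tol=0, flip_prob=0, n_molecules=3, seed=0)
        traces, truths = simulate_molecules(amplicon_map, cfg)
        expected = np.array(amplicon_map.positions) * NM_PER_BP * 1.6
        for tr in traces:
            np.testing.assert_allclose(tr.label_positions, expected, atol=1e-9)

    def test_mean_labels_matches_closed_form(self, amplicon_map):
        # E[labels] = sites*p + rho*L_kb = 9*0.92 + 0.46*5 = 10.58
        cfg = SimConfig(p_site=0.92, rho_off=0.46, n_molecules=5000, seed=2)
        traces, _ = simulate_molecules(amplicon_map, cfg)
        counts = np.array([len(t.label_positions) for t in traces])
        expect = 9 * 0.92 + 0.46 * 5
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expect) < 3 * se

    def test_offsite_counts_are_poisson(self, amplicon_map):
        cfg = SimConfig(p_site=0, rho_off=0.46, n_molecules=5000, seed=3)
        _, truths = simulate_molecules(amplicon_map, cfg)
        n_off = np.array([len(t.off_site_labels) for t in truths])
        lam = 0.46 * 5
        se_mean = np.sqrt(lam / len(n_off))
        assert abs(n_off.mean() - lam) < 3 * se_mean
        # Poisson: variance == mean (index of dispersion ~ 1)
        assert abs(n_off.var(ddof=1) / n_off.mean() - 1) < 0.1

    def test_fixed_seed_reproducible(self, amplicon_map):
        cfg = SimConfig(n_molecules=25, seed=11)
        t1, _ = simulate_molecules(amplicon_map, cfg)
        t2, _ = simulate_molecules(amplicon_map, cfg)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.label_positions, b.label_positions)

    def test_double_mirror_is_identity(self, amplicon_map):
        cfg = SimConfig(n_molecules=5, seed=4)
        traces, _ = simulate_molecules(amplicon_map, cfg)
        for tr in traces:
            np.testing.assert_allclose(
                tr.mirrored().mirrored().label_positions,
                tr.label_positions, atol=1e-9)

    def test_positions_sorted_within_molecule_length(self, amplicon_map):
        cfg = SimConfig(n_molecules=50, seed=5)
        traces, _ = simulate_molecules(amplicon_map, cfg)
        for tr in traces:
            p = tr.label_positions
            assert np.all(np.diff(p) >= 0)
            assert np.all((p >= 0) & (p <= tr.molecule_length))

    def test_rejects_nonpositive_n(self, amplicon_map):
        with pytest.raises(ValueError):
            simulate_molecules(amplicon_map, SimConfig(n_molecules=0))

    def test_trace_frame_round_trip(self, amplicon_map):
        cfg = SimConfig(n_molecules=8, seed=6)
        traces, _ = simulate_molecules(amplicon_map, cfg)
        back = traces_from_frame(traces_to_frame(traces))
        assert len(back) == len(traces)
        for a, b in zip(traces, back):
            np.testing.assert_allclose(a.label_positions, b.label_positions)
            assert a.molecule_length == pytest.approx(b.molecule_length)


class TestPlasmidField:
    def test_empty_field(self, plasmid_map):
        field = simulate_plasmid_field(plasmid_map, SimConfig(seed=1), 0)
        assert len(field.truths) == 0 and field.backbone_points.size == 0

    def test_truth_counts_conserve_emitters(self, plasmid_map):
        field = simulate_plasmid_field(
            plasmid_map, SimConfig.preset("plasmid", seed=2), 50,
            field_size=256)
        assert sum(t.n_labels for t in field.truths) == len(field.label_positions)

    def test_decoys_flagged(self, plasmid_map):
        field = simulate_plasmid_field(
            plasmid_map, SimConfig.preset("plasmid", seed=3), 60,
            field_size=300, decoy_fraction=0.3)
        n_decoys = sum(t.is_decoy for t in field.truths)
        assert 0 < n_decoys < 60

    def test_packing_limit_raises(self, plasmid_map):
        with pytest.raises(RuntimeError):
            simulate_plasmid_field(plasmid_map, SimConfig(seed=4), 500,
                                   field_size=64)


class TestSimulateMovie:
    def test_zero_emitters_pure_noise(self):
        mcfg = MovieConfig(field_size=16, n_frames=200, background=30,
                           read_noise=0, seed=1)
        stack, _ = simulate_movie([], mcfg)
        assert abs(stack.mean() - 30) < 0.5

    def test_noiseless_single_emitter_exact(self):
        mcfg = MovieConfig(field_size=16, n_frames=30, background=7,
                           read_noise=0, shot_noise=False, seed=0)
        stack, _ = simulate_movie([GroundTruthEmitter(8.0, 5.0, 300, 10)], mcfg)
        # frames 11+ exactly background
        np.testing.assert_allclose(stack[11:], 7.0)
        # frames 0..10 identical and contain the PSF
        np.testing.assert_allclose(stack[0], stack[10])
        assert stack[0].max() > 7.0
        assert stack[0, 5, 8] == stack[:11].max()

    def test_two_emitter_staircase(self):
        mcfg = MovieConfig(field_size=20, n_frames=200, background=0,
                           read_noise=0, shot_noise=False, seed=0)
        ems = [GroundTruthEmitter(9.0, 9.0, 300, 50),
               GroundTruthEmitter(10.5, 9.0, 300, 150)]
        stack, _ = simulate_movie(ems, mcfg)
        totals = stack.sum(axis=(1, 2))
        assert np.all(np.diff(totals) <= 1e-9)  # non-increasing staircase
        levels = {round(v, 6) for v in totals}
        assert len(levels) == 3  # two-on, one-on, none

    def test_background_photon_statistics(self):
        mcfg = MovieConfig(field_size=12, n_frames=1500, background=20,
                           read_noise=2.0, seed=9)
        stack, _ = simulate_movie([], mcfg)
        pix_var = stack.var(axis=0).mean()
        expected = 20 + 2.0**2  # shot variance + read-noise variance
        assert abs(pix_var - expected) / expected < 0.1

    def test_emitter_outside_field_rejected(self):
        mcfg = MovieConfig(field_size=16, n_frames=10)
        with pytest.raises(ValueError):
            simulate_movie([GroundTruthEmitter(20.0, 5.0)], mcfg)

    def test_tiff_round_trip(self, tmp_path):
        from mtagmap.simulate import read_movie, write_movie

        mcfg = MovieConfig(field_size=12, n_frames=15, seed=3)
        stack, _ = simulate_movie([GroundTruthEmitter(6.0, 6.0, 300, 8)], mcfg)
        path = tmp_path / "movie.tif"
        write_movie(stack, path)
        back = read_movie(path)
        assert back.shape == stack.shape
        np.testing.assert_allclose(back, stack.astype(np.float32), rtol=1e-6)


class TestSimulateKinetics:
    def test_time_zero_only_offsite(self, plasmid_map):
        cfg = SimConfig.preset("plasmid", seed=1)
        samples, truth = simulate_kinetics([0.0], 0.28, 0.63, plasmid_map,
                                           cfg, n_per_time=2000)
        lam = 0.37 * plasmid_map.length_kb
        se = np.sqrt(lam / 2000)
        assert abs(samples[0].mean() - lam) < 3 * se

    def test_saturation_limit(self, plasmid_map):
        cfg = SimConfig.preset("plasmid", seed=2)
        t_inf = 100 / 0.28
        samples, _ = simulate_kinetics([t_inf], 0.28, 0.63, plasmid_map,
                                       cfg, n_per_time=2000)
        expect = 4 * 0.63 + 0.37 * plasmid_map.length_kb
        se = samples[0].std(ddof=1) / np.sqrt(len(samples[0]))
        assert abs(samples[0].mean() - expect) < 3 * se

    def test_intermediate_time_closed_form(self, plasmid_map):
        # k = 0.28/min at t = 10 min: p(t) = p_inf (1 - e^{-2.8})
        cfg = SimConfig.preset("plasmid", seed=3)
        samples, _ = simulate_kinetics([10.0], 0.28, 0.875, plasmid_map,
                                       cfg, n_per_time=3000)
        expect = 4 * 0.875 * (1 - np.exp(-2.8)) + 0.37 * plasmid_map.length_kb
        se = samples[0].std(ddof=1) / np.sqrt(len(samples[0]))
        assert abs(samples[0].mean() - expect) < 3 * se

    def test_invalid_inputs(self, plasmid_map):
        cfg = SimConfig(seed=1)
        with pytest.raises(ValueError):
            simulate_kinetics([-1.0], 0.28, 0.9, plasmid_map, cfg)
        with pytest.raises(ValueError):
            simulate_kinetics([1.0], 0.0, 0.9, plasmid_map, cfg)
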