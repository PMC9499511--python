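"""Radial histograms, membrane/cytosol decomposition, event extraction."""

import numpy as np
import pytest

from srptrack.geometry import NormalizedPosition
from srptrack.hmm import StatePath
from srptrack.spatial import (
    decompose_profile,
    event_positions_normalized,
    event_spatial_stats,
    extract_events,
    membrane_reference_from_tracks,
    mirror_profile,
    radial_histogram,
    sample_event_positions,
    sample_marker_positions,
    sample_two_component_positions,
    synthetic_membrane_reference,
)
from srptrack.tracks import Track


class TestRadialHistogram:
    def test_pole_positions_all_excluded(self):
        pos = NormalizedPosition(x_long=np.full(100, 0.05),
                                 r_short=np.zeros(100))
        prof = radial_histogram(pos)
        assert prof.is_empty
        assert prof.n_excluded_margin == 100

    def test_zero_margin_retains_everything(self):
        rng = np.random.default_rng(0)
        pos = NormalizedPosition(x_long=rng.uniform(0, 1, 500),
                                 r_short=rng.uniform(-1, 1, 500))
        prof = radial_histogram(pos, margin=0.0)
        assert prof.n_total == 500
        assert prof.n_excluded_margin == 0

    def test_midcell_window_excluded(self):
        pos = NormalizedPosition(x_long=np.full(50, 0.5), r_short=np.zeros(50))
        prof = radial_histogram(pos, margin=0.15)
        assert prof.is_empty

    def test_uniform_cytosol_sample_matches_theory(self, geom, cytosol_ref):
        from srptrack.geometry import sample_cytosol_uniform

        rng = np.random.default_rng(1)
        pts = sample_cytosol_uniform(150_000, geom, rng, cylindrical_only=True)
        pos = NormalizedPosition(
            x_long=(pts[:, 0] + geom.total_length / 2) / geom.total_length,
            r_short=pts[:, 1] / geom.cylinder_radius,
        )
        prof = radial_histogram(pos)
        assert prof.check_normalized()
        counts = prof.density * prof.bin_width * prof.n_total
        se = np.sqrt(np.maximum(counts, 1)) / prof.n_total / prof.bin_width
        assert np.all(np.abs(prof.density - cytosol_ref.density) < 3.5 * se)

    def test_mirrored_presentation_normalized(self, membrane_ref):
        m = mirror_profile(membrane_ref.profile)
        assert np.sum(m.density * np.diff(m.bin_edges)) == pytest.approx(1.0)


class TestDecomposition:
    def test_pure_cytosol_gives_zero(self, cytosol_ref, membrane_ref):
        d = decompose_profile(_with_n(cytosol_ref, 10_000), cytosol_ref,
                              membrane_ref, n_boot=50, seed=0)
        assert d.membrane_fraction == pytest.approx(0.0, abs=1e-3)

    def test_pure_membrane_gives_one(self, cytosol_ref, membrane_ref):
        d = decompose_profile(_with_n(membrane_ref.profile, 10_000), cytosol_ref,
                              membrane_ref, n_boot=50, seed=0)
        assert d.membrane_fraction == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_mixture_recovery_within_5_points(self, alpha, geom, cytosol_ref,
                                              membrane_ref):
        """Constructed two-component mixtures of 10,000 positions recover
        the membrane molecule fraction within ±0.05."""
        pos = sample_two_component_positions(10_000, alpha, geom,
                                             rng=1234 + int(alpha * 100))
        prof = radial_histogram(pos)
        d = decompose_profile(prof, cytosol_ref, membrane_ref, n_boot=50, seed=1)
        assert abs(d.membrane_fraction - alpha) < 0.05

    def test_half_mixture_ci_brackets_truth(self, geom, cytosol_ref, membrane_ref):
        pos = sample_two_component_positions(10_000, 0.5, geom, rng=77)
        prof = radial_histogram(pos)
        d = decompose_profile(prof, cytosol_ref, membrane_ref, n_boot=200, seed=2)
        assert d.ci[0] <= 0.5 <= d.ci[1]
        assert d.ci[1] - d.ci[0] < 0.12  # binomial-scale interval at n=10^4

    def test_identical_references_flagged_ill_conditioned(self, cytosol_ref):
        from srptrack.spatial import MembraneReference

        fake = MembraneReference(profile=cytosol_ref)
        d = decompose_profile(_with_n(cytosol_ref, 1000), cytosol_ref, fake,
                              n_boot=10, seed=0)
        assert d.ill_conditioned
        assert d.ci == (0.0, 1.0)  # CI widened to vacuity

    def test_mismatched_bins_rejected(self, geom, cytosol_ref, membrane_ref):
        from srptrack.geometry import theoretical_cytosol_profile

        other = theoretical_cytosol_profile(geom, n_b=12)
        with pytest.raises(ValueError):
            decompose_profile(_with_n(other, 100), cytosol_ref, membrane_ref)


def _with_n(profile, n):
    from dataclasses import replace

    return replace(profile, n_total=n)


class TestMembraneReference:
    def test_noiseless_shell_peaks_at_edges(self, geom):
        pos = sample_marker_positions(30_000, geom, z_jitter_std=0.0,
                                      xy_shift_std=0.0, detection_z_scale=None,
                                      rng=3)
        prof = radial_histogram(pos)
        d = prof.density
        assert d.argmax() in (0, len(d) - 1)

    def test_jitter_broadens_peak(self, geom):
        """Adding the 100 nm z and 80 nm x-y jitters strictly lowers the
        peak bin density of the shell projection."""
        clean = radial_histogram(
            sample_marker_positions(60_000, geom, z_jitter_std=0.0,
                                    xy_shift_std=0.0, detection_z_scale=None,
                                    rng=4))
        jittered = radial_histogram(
            sample_marker_positions(60_000, geom, z_jitter_std=0.10,
                                    xy_shift_std=0.08, rng=4))
        assert jittered.density.max() < clean.density.max()

    def test_reference_symmetric(self, membrane_ref):
        d = membrane_ref.profile.density
        n = membrane_ref.profile.n_total
        half = len(d) // 2
        counts = d * membrane_ref.profile.bin_width * n
        se = np.sqrt(np.maximum(counts, 1))
        diff = np.abs(counts[:half][::-1] - counts[half:])
        assert np.all(diff < 3.5 * np.sqrt(se[:half][::-1] ** 2 + se[half:] ** 2))

    def test_built_from_marker_tracks(self, geom):
        """Shell-confined marker tracks with a slow artifact component:
        the two-state HMM isolates the marker state and the resulting
        profile peaks off-center."""
        rng = np.random.default_rng(8)
        tracks = []
        from srptrack.geometry import sample_membrane_shell

        for tid in range(150):
            n = 12
            start = sample_membrane_shell(1, geom, rng)[0]
            steps = rng.normal(0, np.sqrt(2 * 0.03 * 0.02), (n - 1, 2))
            pos3 = np.vstack([start[:2], start[:2] + np.cumsum(steps, axis=0)])
            tracks.append(Track(tid, tid // 10, np.arange(n), pos3,
                                np.full(n, 0.02)))
        ref = membrane_reference_from_tracks(tracks, geom)
        assert ref.profile.check_normalized()
        d = ref.profile.density
        assert d[:4].sum() + d[-4:].sum() > d[7:11].sum()  # edge-heavy

    def test_insufficient_data_falls_back(self, geom):
        rng = np.random.default_rng(9)
        tracks = [Track(0, 0, np.arange(4), rng.normal(0, 0.1, (4, 2)),
                        np.full(4, 0.02))]
        ref = membrane_reference_from_tracks(tracks, geom)
        assert "fallback" in ref.provenance


def _path(states, track_id=0, cell_id=0):
    states = np.asarray(states)
    post = np.zeros((len(states), int(states.max()) + 1))
    post[np.arange(len(states)), states] = 1.0
    return StatePath(track_id=track_id, cell_id=cell_id, states=states,
                     posteriors=post, ambiguous=np.zeros(len(states), bool))


def _track_for(states, track_id=0, cell_id=0):
    n = len(states)
    pos = np.column_stack([np.linspace(0, 0.1 * (n - 1), n), np.zeros(n)])
    return Track(track_id, cell_id, np.arange(n), pos, np.full(n, 0.02))


class TestEvents:
    def test_constant_path_no_events(self):
        p = _path([1] * 10)
        events, rep = extract_events([p], [_track_for([1] * 10)], slow_state_id=0)
        assert events == []
        assert rep["n_candidates"] == 0

    def test_single_binding_and_release_with_neighbors(self):
        states = [2, 2, 2, 2, 1, 1, 1, 1, 1, 2, 2, 2, 2]
        # relabel: slow state is 1 here
        p = _path(states)
        t = _track_for(states)
        events, rep = extract_events([p], [t], slow_state_id=1)
        kinds = sorted(e.kind for e in events)
        assert kinds == ["binding", "release"]
        b = next(e for e in events if e.kind == "binding")
        r = next(e for e in events if e.kind == "release")
        assert b.frame == 4 and len(b.positions) == 3
        assert np.allclose(b.positions, t.positions[[4, 5, 6]])
        assert r.frame == 8 and len(r.positions) == 3
        assert np.allclose(r.positions, t.positions[[8, 6, 7]])

    def test_three_segment_context_filter(self):
        # transition too close to the start: binding at position 1
        states = [2, 1, 1, 1, 1, 1, 1, 1]
        events, rep = extract_events([_path(states)], [_track_for(states)],
                                     slow_state_id=1)
        assert rep["n_candidates"] == 1
        assert rep["n_filtered_out"] == 1
        assert events == []

    def test_event_fraction_recovery(self, geom, cytosol_ref, membrane_ref):
        """Events placed fully on the membrane decompose to fraction ~1."""
        pos = sample_event_positions(300, 1.0, geom, rng=5)
        prof = radial_histogram(pos)
        d = decompose_profile(prof, cytosol_ref, membrane_ref, n_boot=50, seed=0)
        assert d.membrane_fraction > 0.9

    def test_neighbor_pooling_shifts_decomposition_little(self, geom, cytosol_ref,
                                                          membrane_ref):
        """Pooling the ±2 slow-diffusion neighbors moves the fitted membrane
        fraction by < 0.03 relative to events alone (the slow state barely
        moves between frames)."""
        from srptrack.spatial import (event_component_references,
                                      extended_histogram)

        cyt_ev, mem_ev = event_component_references(geom, seed=12)
        fr = {}
        for n_neigh in (0, 2):
            pos = sample_event_positions(8000, 0.5, geom, n_neighbors=n_neigh,
                                         rng=11)
            prof = extended_histogram(pos)
            fr[n_neigh] = decompose_profile(prof, cyt_ev, mem_ev,
                                            n_boot=2, seed=0).membrane_fraction
        assert abs(fr[2] - fr[0]) < 0.03
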