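"""Generators: Brownian dynamics in the cell and Markov-switching tracks."""

import numpy as np
import pytest

from srptrack.geometry import CellGeometry, axial_distance, compartment_of
from srptrack.simulate import (
    Reaction,
    SimulationConfig,
    SpeciesModel,
    default_srp_model,
    dwells_to_rate_matrix,
    effective_stationary_species,
    markov_switching_tracks,
    observe,
    simulate_cell,
    stationary_distribution,
    wildtype_rate_matrix,
)
from srptrack.tracks import total_steps


class TestBrownianDynamics:
    def test_no_reactions_conserves_species(self):
        m = SpeciesModel(reactions=())
        cfg = SimulationConfig(dt=0.005, n_particles=50, n_replicates=1,
                               t_equilibrate=0.0, t_record=1.0, seed=1)
        trajs = simulate_cell(m, config=cfg)
        assert len(trajs) == 50
        for t in trajs:
            assert (t.species_path == t.species_path[0]).all()

    def test_positions_stay_in_allowed_compartment(self):
        geom = CellGeometry()
        m = default_srp_model()
        cfg = SimulationConfig(dt=0.002, n_particles=40, n_replicates=1,
                               t_equilibrate=0.0, t_record=2.0, seed=2,
                               initial_species="stationary")
        for t in simulate_cell(m, geom, cfg):
            comp = compartment_of(t.positions, geom)
            is_mem = t.species_path == 3  # RM
            assert (comp[is_mem] == "membrane").all()
            assert (comp[~is_mem] == "cytosol").all()

    def test_symmetric_two_state_toy_occupancy(self):
        """A <-> B at equal 1/s rates: stationary occupancy of A is 1/2."""
        m = SpeciesModel(
            species=("A", "B"),
            D={"A": 1.0, "B": 1.0},
            allowed={"A": "cytosol", "B": "cytosol"},
            reactions=(Reaction("A", "B", 1.0), Reaction("B", "A", 1.0)),
        )
        cfg = SimulationConfig(dt=0.005, n_particles=150, n_replicates=1,
                               t_equilibrate=5.0, t_record=10.0, seed=3,
                               initial_species="A")
        occ = np.concatenate([t.species_path for t in simulate_cell(m, config=cfg)])
        frac_a = np.mean(occ == 0)
        # ~150 independent-ish sojourns; allow 3 binomial-scale SE
        assert abs(frac_a - 0.5) < 3 * 0.5 / np.sqrt(150 * 10)

    def test_free_diffusion_einstein_relation(self):
        """Unconfined diffusion: mean squared 3D displacement per step is
        6 D dt within sampling error."""
        big = CellGeometry(cylinder_radius=50.0, cylinder_length=100.0,
                           membrane_thickness=0.0)
        m = SpeciesModel(species=("A",), D={"A": 1.0}, allowed={"A": "cytosol"},
                         reactions=())
        dt = 0.01
        cfg = SimulationConfig(dt=dt, n_particles=200, n_replicates=1,
                               t_equilibrate=0.0, t_record=2.0, seed=4,
                               initial_species="A")
        sq = []
        for t in simulate_cell(m, big, cfg):
            sq.append((np.diff(t.positions, axis=0) ** 2).sum(axis=1))
        sq = np.concatenate(sq)
        expect = 6 * 1.0 * dt
        assert sq.mean() == pytest.approx(expect, rel=4 / np.sqrt(len(sq)))

    def test_default_model_stationary_fractions(self):
        """Species fractions relax to the stationary distribution of the
        effective conversion chain.

        The ungated RNA <-> SRP exchange obeys detailed balance exactly;
        the membrane-gated conversions enter with their effective rates
        (gate volume fraction for the fast, well-mixed SRP; the calibrated
        ~350 ms diffusion-limited mean time for slow RC)."""
        m = default_srp_model()
        rates = {(r.src, r.dst): r.rate for r in m.reactions}
        gate_frac = 1.0 - ((0.42 - 0.05) / 0.42) ** 2
        Q = np.zeros((4, 4))  # RNA, SRP, RC, RM
        Q[0, 1] = rates[("RNA", "SRP")]
        Q[1, 0] = rates[("SRP", "RNA")]
        Q[1, 2] = rates[("SRP", "RC")]
        Q[1, 3] = rates[("SRP", "RM")] * gate_frac
        Q[2, 3] = 1.0 / 0.35  # calibrated diffusion-limited mean time
        Q[3, 1] = rates[("RM", "SRP")]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        pi = stationary_distribution(Q)
        cfg = SimulationConfig(dt=0.002, n_particles=300, n_replicates=2,
                               t_equilibrate=10.0, t_record=15.0, seed=5,
                               initial_species="stationary")
        occ = np.concatenate([t.species_path for t in simulate_cell(m, config=cfg)])
        frac = np.bincount(occ, minlength=4) / len(occ)
        # ~600 particles over ~15 s with ~1 s correlation time
        n_eff = 600 * 8
        for k in range(4):
            se = np.sqrt(pi[k] * (1 - pi[k]) / n_eff)
            assert abs(frac[k] - pi[k]) < 5 * se, (k, frac, pi)
        # detailed-balance check on the ungated RNA <-> SRP pair
        ratio = frac[0] / frac[1]
        assert ratio == pytest.approx(Q[1, 0] / Q[0, 1], rel=0.15)

    def test_binding_split_is_75_25(self):
        """~75% of SRP->ribosome binding events are the cytosolic channel."""
        m = default_srp_model()
        cfg = SimulationConfig(dt=0.002, n_particles=250, n_replicates=2,
                               t_equilibrate=5.0, t_record=20.0, seed=6,
                               initial_species="stationary")
        n_cyt = n_mem = 0
        for t in simulate_cell(m, config=cfg):
            s = t.species_path
            ch = np.flatnonzero(np.diff(s) != 0)
            for i in ch:
                if s[i] == 1 and s[i + 1] == 2:
                    n_cyt += 1
                elif s[i] == 1 and s[i + 1] == 3:
                    n_mem += 1
        frac = n_cyt / (n_cyt + n_mem)
        se = np.sqrt(0.75 * 0.25 / (n_cyt + n_mem))
        assert abs(frac - 0.75) < 4 * se

    def test_membrane_gated_occupancy_monotone_in_rate(self):
        """Raising the membrane-gated conversion rate raises the membrane
        species' occupancy, monotonically over a rate grid."""
        occs = []
        for rate in (0.2, 1.0, 5.0):
            m = SpeciesModel(
                species=("SRP", "RM"),
                D={"SRP": 2.4, "RM": 0.05},
                allowed={"SRP": "cytosol", "RM": "membrane"},
                reactions=(
                    Reaction("SRP", "RM", rate, "membrane_shell"),
                    Reaction("RM", "SRP", 2.0, "membrane_shell"),
                ),
            )
            cfg = SimulationConfig(dt=0.002, n_particles=200, n_replicates=1,
                                   t_equilibrate=4.0, t_record=8.0, seed=7,
                                   initial_species="stationary")
            occ = np.concatenate(
                [t.species_path for t in simulate_cell(m, config=cfg)]
            )
            occs.append(np.mean(occ == 1))
        assert occs[0] < occs[1] < occs[2]

    def test_too_large_dt_rejected(self):
        m = default_srp_model()
        with pytest.raises(ValueError, match="tunnel|sub-stepping"):
            simulate_cell(m, config=SimulationConfig(dt=0.05, n_particles=1,
                                                     n_replicates=1,
                                                     t_equilibrate=0, t_record=0.1))


class TestMarkovSwitchingTracks:
    def test_zero_diffusion_zero_noise_is_static(self):
        tr = markov_switching_tracks([0.0], mean_dwells=[10.0], n_tracks=20,
                                     loc_error=0.0, seed=1)
        for t in tr:
            assert np.allclose(t.displacements, 0.0)

    def test_single_state_step_variance(self):
        """D = 1 µm²/s at 20 ms frames: per-axis displacement variance is
        2 D dt = 0.04 µm²."""
        tr = markov_switching_tracks([1.0], mean_dwells=[1e9], n_tracks=800,
                                     mean_track_len=20, loc_error=0.0, seed=2)
        d = np.vstack([t.displacements for t in tr])
        n = d.size
        assert d.var() == pytest.approx(0.04, rel=5 / np.sqrt(n))

    def test_two_state_renewal_occupancy(self):
        """Dwells (1.9 s, 1.0 s): long-run fraction of frames in state 2 is
        1.0/2.9 by the renewal-reward theorem."""
        tr = markov_switching_tracks(
            [1.7, 0.05], mean_dwells=[1.9, 1.0], n_tracks=3000,
            mean_track_len=25, loc_error=0.0, seed=3,
        )
        states = np.concatenate([t.true_states for t in tr])
        frac = np.mean(states == 1)
        n_sojourns = len(states) * 0.02 / 1.9 + len(states) * 0.02 / 1.0
        se = 0.5 / np.sqrt(n_sojourns)
        assert abs(frac - 1.0 / 2.9) < 3 * se

    def test_wildtype_chain_has_printed_stationary_occupancies(self):
        Q = wildtype_rate_matrix()
        pi = stationary_distribution(Q)
        assert np.allclose(pi, [0.28, 0.56, 0.16], atol=1e-9)
        # free RNA exchanges over an order of magnitude more slowly
        assert Q[1, 2] < 0.1 * Q[1, 0]

    def test_unresolvable_dwell_rejected(self):
        with pytest.raises(ValueError):
            markov_switching_tracks([1.0, 2.0], mean_dwells=[0.01, 1.0],
                                    frame_dt=0.02)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            markov_switching_tracks([1.0], mean_dwells=[1.0, 2.0])


class TestObserve:
    def _truths(self, seed=0):
        m = SpeciesModel(species=("A",), D={"A": 1.0}, allowed={"A": "cytosol"},
                         reactions=())
        cfg = SimulationConfig(dt=0.004, n_particles=30, n_replicates=4,
                               t_equilibrate=0.0, t_record=1.0, seed=seed,
                               initial_species="A")
        return simulate_cell(m, config=cfg)

    def test_noiseless_observation_equals_subsampled_truth(self):
        truths = self._truths()
        obs = observe(truths, frame_dt=0.02, z_jitter_std=0.0, xy_shift_std=0.0,
                      seed=1)
        tr = truths[0]
        src = np.round(np.arange(len(obs[0])) * 0.02 / 0.004).astype(int)
        assert np.allclose(obs[0].positions, tr.positions[src, :2])
        # nearest-index subsampling maps each frame to a unique source point
        assert len(np.unique(src)) == len(src)

    def test_xy_shift_variance_matches_configured_80nm(self):
        truths = self._truths()
        shifts = []
        for rep in range(12):
            obs = observe(truths, frame_dt=0.02, z_jitter_std=0.0,
                          xy_shift_std=0.08, seed=rep)
            clean = observe(truths, frame_dt=0.02, z_jitter_std=0.0,
                            xy_shift_std=0.0, seed=0)
            for a, b in zip(obs, clean):
                shifts.append(a.positions[0] - b.positions[0])
        shifts = np.array(shifts).ravel()
        assert shifts.std() == pytest.approx(0.08, rel=4 / np.sqrt(len(shifts)))

    def test_z_offset_shared_within_cell(self):
        truths = self._truths()
        obs = observe(truths, frame_dt=0.02, z_jitter_std=0.1, xy_shift_std=0.0,
                      seed=5)
        by_cell = {}
        for t, o in zip(truths, obs):
            off = o.true_z - t.positions[
                np.round(np.arange(len(o)) * 0.02 / 0.004).astype(int), 2]
            by_cell.setdefault(o.cell_id, []).append(off)
        offsets = []
        for c, offs in by_cell.items():
            flat = np.concatenate(offs)
            assert np.allclose(flat, flat[0])  # one offset per cell
            offsets.append(flat[0])
        assert len(set(np.round(offsets, 12))) > 1  # but different across cells
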