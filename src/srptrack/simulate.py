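"""Ground-truth generators: reaction-diffusion Brownian dynamics in the cell
and a fast geometry-free Markov-switching track generator.

The Brownian-dynamics simulator propagates independent particles that switch
among four species — RNA (free 4.5S RNA), SRP (4.5S RNA + Ffh), RC
(ribosome-bound SRP diffusing in the cytosol) and RM (ribosome-bound SRP at
the membrane) — with first-order conversions that may be gated to the
membrane-proximal region.  Defaults are calibrated to the wild-type kinetic
picture: SRP finds a ribosome in ~1.5 s on average, ~75% of bindings happen
anywhere in the cytosol, the cytosol-bound complex reaches the membrane in
~350 ms, and SRP leaves the membrane-bound ribosome after ~500 ms.

The geometry-free generator (:func:`markov_switching_tracks`) emits observed
2D tracks directly from a continuous-time Markov chain discretized at the
frame interval — the reference dataset for validating the diffusion HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .geometry import CYTOSOL, MEMBRANE, CellGeometry, axial_distance
from .tracks import Track

ANYWHERE = "anywhere"
MEMBRANE_SHELL = "membrane_shell"


@dataclass(frozen=True)
class Reaction:
    """First-order conversion ``src -> dst`` at ``rate`` (1/s).

    ``gate`` restricts where the reaction may fire: anywhere the species is
    allowed, or only within the membrane-proximal shell (the membrane
    compartment itself, or the outermost ``gate_width`` of the cytosol for
    cytosolic species).
    """

    src: str
    dst: str
    rate: float
    gate: str = ANYWHERE


@dataclass(frozen=True)
class SpeciesModel:
    species: tuple[str, ...] = ("RNA", "SRP", "RC", "RM")
    D: dict[str, float] = field(
        default_factory=lambda: {"RNA": 8.0, "SRP": 2.4, "RC": 0.08, "RM": 0.05}
    )
    allowed: dict[str, str] = field(
        default_factory=lambda: {
            "RNA": CYTOSOL,
            "SRP": CYTOSOL,
            "RC": CYTOSOL,
            "RM": MEMBRANE,
        }
    )
    reactions: tuple[Reaction, ...] = ()
    #: cytosolic reactions gated to the membrane fire within this distance
    #: of the cytosol boundary (µm)
    gate_width: float = 0.05

    def __post_init__(self) -> None:
        for sp in self.species:
            if self.D.get(sp, -1) < 0:
                raise ValueError(f"species {sp} needs a non-negative D")
        for rx in self.reactions:
            if rx.rate < 0:
                raise ValueError("rates must be non-negative")
            if rx.src not in self.species or rx.dst not in self.species:
                raise ValueError("reaction endpoints must be declared species")


def default_srp_model(
    membrane_binding_fraction: float = 0.25,
    search_time: float = 1.5,
    membrane_dwell: float = 0.5,
    rc_to_rm_rate: float = 28.0,
) -> SpeciesModel:
    """Wild-type SRP reaction network with calibrated default rates.

    The total SRP->ribosome binding rate is 1/search_time, split so that
    ``membrane_binding_fraction`` of bindings are the membrane-gated
    SRP->RM channel (the gated channel is active only ~22% of the time, the
    volume fraction of the gate region, so its nominal rate is scaled up
    accordingly).  RC->RM fires only near the membrane at a rate calibrated
    (see :func:`calibrate_membrane_conversion`) to give a ~350 ms mean
    cytosol-binding-to-membrane time at the default D_RC.
    RNA <-> SRP exchange is more than an order of magnitude slower than all
    other reactions, with a ~16% stationary free-RNA fraction.
    """
    geom = CellGeometry()
    r_in = geom.cylinder_radius
    gate_frac = 1.0 - ((r_in - 0.05) / r_in) ** 2  # cylindrical-part volume fraction
    k_bind_total = 1.0 / search_time
    k_cyt = (1.0 - membrane_binding_fraction) * k_bind_total
    k_mem = membrane_binding_fraction * k_bind_total / gate_frac
    reactions = (
        Reaction("SRP", "RC", k_cyt, ANYWHERE),
        Reaction("SRP", "RM", k_mem, MEMBRANE_SHELL),
        Reaction("RC", "RM", rc_to_rm_rate, MEMBRANE_SHELL),
        Reaction("RM", "SRP", 1.0 / membrane_dwell, MEMBRANE_SHELL),
        Reaction("RNA", "SRP", 0.03, ANYWHERE),
        Reaction("SRP", "RNA", 0.16 * 0.03 / 0.56, ANYWHERE),
    )
    return SpeciesModel(reactions=reactions)


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.0057
    n_particles: int = 200
    n_replicates: int = 10
    t_equilibrate: float = 56.0
    t_record: float = 20.0
    seed: int = 0
    initial_species: str = "RNA"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_record <= 0:
            raise ValueError("dt and t_record must be positive")


@dataclass
class GroundTruthTrajectory:
    particle_id: int
    cell_id: int
    times: np.ndarray
    positions: np.ndarray  # (T, 3) µm
    species_path: np.ndarray  # (T,) species index into model.species

    def __len__(self) -> int:
        return len(self.times)


def _reflect_radial(
    pos: np.ndarray, geom: CellGeometry, r_lo: float, r_hi: float
) -> np.ndarray:
    """Fold points radially (about the axis segment) into [r_lo, r_hi].

    Approximates specular reflection for displacement steps small compared
    to the cell radius; iterated until all points are inside.
    """
    half = geom.cylinder_length / 2.0
    for _ in range(8):
        ax = np.clip(pos[:, 0], -half, half)
        rad = pos - np.column_stack([ax, np.zeros(len(pos)), np.zeros(len(pos))])
        d = np.linalg.norm(rad, axis=1)
        d_safe = np.maximum(d, 1e-12)
        bad_hi = d > r_hi
        bad_lo = d < r_lo
        if not (bad_hi.any() or bad_lo.any()):
            return pos
        new_d = np.where(bad_hi, 2 * r_hi - d, np.where(bad_lo, 2 * r_lo - d, d))
        # degenerate on-axis points in a shell region: push outward
        new_d = np.where((d < 1e-9) & (r_lo > 0), r_lo + 1e-6, new_d)
        scale = new_d / d_safe
        pos = np.column_stack([ax, np.zeros(len(pos)), np.zeros(len(pos))]) + rad * scale[:, None]
    # fallback: clamp radially
    ax = np.clip(pos[:, 0], -half, half)
    rad = pos - np.column_stack([ax, np.zeros(len(pos)), np.zeros(len(pos))])
    d = np.maximum(np.linalg.norm(rad, axis=1), 1e-12)
    clamped = np.clip(d, r_lo + 1e-9 if r_lo > 0 else 0.0, r_hi - 1e-9)
    return np.column_stack([ax, np.zeros(len(pos)), np.zeros(len(pos))]) + rad * (
        clamped / d
    )[:, None]


def _region_bounds(species_idx: int, model: SpeciesModel, geom: CellGeometry):
    sp = model.species[species_idx]
    if model.allowed[sp] == MEMBRANE:
        return geom.cylinder_radius, geom.outer_radius
    return 0.0, geom.cylinder_radius


def effective_stationary_species(
    model: SpeciesModel, geom: CellGeometry = CellGeometry()
) -> np.ndarray:
    """Approximate stationary species distribution of the reaction network.

    Membrane-gated reactions of cytosolic species are scaled by the volume
    fraction of the gate region (well-mixed approximation); used to draw
    initial species so short equilibrations start near steady state.
    """
    idx = {s: i for i, s in enumerate(model.species)}
    K = len(model.species)
    Q = np.zeros((K, K))
    r_in = geom.cylinder_radius
    gate_frac = 1.0 - ((r_in - model.gate_width) / r_in) ** 2
    for rx in model.reactions:
        scale = 1.0
        if rx.gate == MEMBRANE_SHELL and model.allowed[rx.src] == CYTOSOL:
            scale = gate_frac
        Q[idx[rx.src], idx[rx.dst]] += rx.rate * scale
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return stationary_distribution(Q)


def simulate_cell(
    model: SpeciesModel,
    geom: CellGeometry = CellGeometry(),
    config: SimulationConfig = SimulationConfig(),
) -> list[GroundTruthTrajectory]:
    """Brownian dynamics with location-gated species conversions.

    Each particle takes isotropic Gaussian steps with per-axis std
    sqrt(2 D dt), reflecting off the envelope of its allowed compartment;
    conversions fire as exponential waiting times at the tagged rates.
    Recording starts after the equilibration period.
    """
    d_max_mem = max(
        model.D[sp] for sp in model.species if model.allowed[sp] == MEMBRANE
    ) if any(model.allowed[sp] == MEMBRANE for sp in model.species) else 0.0
    if np.sqrt(2 * d_max_mem * config.dt) > geom.membrane_thickness > 0:
        raise ValueError(
            "time step too large: membrane species would tunnel through the "
            "shell; reduce dt (sub-stepping) so sqrt(2 D dt) < shell thickness"
        )
    root = np.random.SeedSequence(config.seed)
    out: list[GroundTruthTrajectory] = []
    for cell_id, child in enumerate(root.spawn(config.n_replicates)):
        rng = np.random.default_rng(child)
        out.extend(_simulate_one_cell(model, geom, config, rng, cell_id))
    return out


def _simulate_one_cell(model, geom, config, rng, cell_id) -> list[GroundTruthTrajectory]:
    n = config.n_particles
    sp_index = {s: i for i, s in enumerate(model.species)}
    D = np.array([model.D[s] for s in model.species])
    from .geometry import sample_cytosol_uniform, sample_membrane_shell

    if config.initial_species == "stationary":
        pi0 = effective_stationary_species(model, geom)
        species = rng.choice(len(model.species), size=n, p=pi0)
    else:
        species = np.full(n, sp_index[config.initial_species], dtype=int)
    # start uniform in the allowed compartment of each particle's species
    pos = np.empty((n, 3))
    for si in np.unique(species):
        sel = species == si
        if model.allowed[model.species[si]] == MEMBRANE:
            pos[sel] = sample_membrane_shell(int(sel.sum()), geom, rng,
                                             cylindrical_only=False)
        else:
            pos[sel] = sample_cytosol_uniform(int(sel.sum()), geom, rng)

    n_eq = int(round(config.t_equilibrate / config.dt))
    n_rec = int(round(config.t_record / config.dt)) + 1
    rec_pos = np.empty((n_rec, n, 3))
    rec_sp = np.empty((n_rec, n), dtype=int)

    half = geom.cylinder_length / 2.0
    gate_radius = geom.cylinder_radius - model.gate_width

    # per-species reaction table
    rx_by_src: dict[int, list[Reaction]] = {}
    for rx in model.reactions:
        rx_by_src.setdefault(sp_index[rx.src], []).append(rx)

    for step in range(n_eq + n_rec):
        # diffuse
        sigma = np.sqrt(2.0 * D[species] * config.dt)
        pos = pos + rng.normal(size=(n, 3)) * sigma[:, None]
        for si in np.unique(species):
            sel = species == si
            r_lo, r_hi = _region_bounds(si, model, geom)
            pos[sel] = _reflect_radial(pos[sel], geom, r_lo, r_hi)
        # react
        ax = np.clip(pos[:, 0], -half, half)
        d_axis = np.sqrt((pos[:, 0] - ax) ** 2 + pos[:, 1] ** 2 + pos[:, 2] ** 2)
        in_gate = d_axis >= gate_radius  # membrane shell or outer cytosol rim
        u = rng.random(n)
        pick = rng.random(n)
        # at most one conversion per particle per step: select against the
        # species at step start, not the partially updated array
        species_at_start = species.copy()
        for si, rxs in rx_by_src.items():
            sel = np.flatnonzero(species_at_start == si)
            if len(sel) == 0:
                continue
            rates = np.zeros((len(sel), len(rxs)))
            for j, rx in enumerate(rxs):
                active = np.ones(len(sel), bool) if rx.gate == ANYWHERE else in_gate[sel]
                rates[:, j] = rx.rate * active
            tot = rates.sum(axis=1)
            fire = u[sel] < -np.expm1(-tot * config.dt)
            if not fire.any():
                continue
            idx = sel[fire]
            cum = np.cumsum(rates[fire], axis=1) / tot[fire, None]
            choice = (pick[idx, None] > cum).sum(axis=1)
            for j, rx in enumerate(rxs):
                conv = idx[choice == j]
                if len(conv) == 0:
                    continue
                new_si = sp_index[rx.dst]
                species[conv] = new_si
                r_lo, r_hi = _region_bounds(new_si, model, geom)
                pos[conv] = _reflect_radial(pos[conv], geom, r_lo, r_hi)
        if step >= n_eq:
            k = step - n_eq
            rec_pos[k] = pos
            rec_sp[k] = species

    times = np.arange(n_rec) * config.dt
    return [
        GroundTruthTrajectory(
            particle_id=p,
            cell_id=cell_id,
            times=times.copy(),
            positions=rec_pos[:, p, :].copy(),
            species_path=rec_sp[:, p].copy(),
        )
        for p in range(n)
    ]


def calibrate_membrane_conversion(
    model: SpeciesModel,
    geom: CellGeometry = CellGeometry(),
    target_mean_time: float = 0.35,
    dt: float = 0.002,
    n_particles: int = 400,
    seed: int = 0,
    max_iter: int = 12,
) -> float:
    """Bisect the RC->RM rate so the mean RC birth-to-conversion time hits
    ``target_mean_time`` (s) for the model's D_RC.

    The mean time includes the 3D diffusion to the membrane-proximal gate,
    so the achievable minimum is the mean first-passage time; the target
    must exceed it.
    """
    def mean_time(rate: float, rng: np.random.Generator) -> float:
        from .geometry import sample_cytosol_uniform

        pos = sample_cytosol_uniform(n_particles, geom, rng)
        alive = np.ones(n_particles, bool)
        t_conv = np.full(n_particles, np.nan)
        gate_radius = geom.cylinder_radius - model.gate_width
        half = geom.cylinder_length / 2.0
        sig = np.sqrt(2.0 * model.D["RC"] * dt)
        for step in range(1, int(20.0 / dt)):
            if not alive.any():
                break
            pos[alive] = pos[alive] + rng.normal(size=(int(alive.sum()), 3)) * sig
            pos[alive] = _reflect_radial(pos[alive], geom, 0.0, geom.cylinder_radius)
            ax = np.clip(pos[:, 0], -half, half)
            d = np.sqrt((pos[:, 0] - ax) ** 2 + pos[:, 1] ** 2 + pos[:, 2] ** 2)
            gated = alive & (d >= gate_radius)
            fire = gated & (rng.random(n_particles) < -np.expm1(-rate * dt))
            t_conv[fire] = step * dt
            alive &= ~fire
        t_conv[np.isnan(t_conv)] = 20.0
        return float(np.mean(t_conv))

    lo, hi = 0.5, 400.0
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        if mean_time(mid, np.random.default_rng(rng.integers(2**31))) > target_mean_time:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# geometry-free Markov-switching generator
# ---------------------------------------------------------------------------


def dwells_to_rate_matrix(mean_dwells: Sequence[float]) -> np.ndarray:
    """CTMC generator with the given mean dwell times, jumps uniform among
    the other states."""
    tau = np.asarray(mean_dwells, dtype=float)
    K = len(tau)
    Q = np.zeros((K, K))
    for k in range(K):
        Q[k, :] = 1.0 / tau[k] / max(K - 1, 1)
        Q[k, k] = 0.0
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def wildtype_rate_matrix(
    occupancies: Sequence[float] = (0.28, 0.56, 0.16),
    dwell_bound: float = 1.0,
    dwell_free_srp: float = 1.9,
) -> np.ndarray:
    """Generator for the wild-type three-state chain.

    State order: 0 = ribosome-bound SRP (slow), 1 = free SRP (intermediate),
    2 = free 4.5S RNA (fast).  Bound SRP exchanges only with free SRP; the
    RNA <-> SRP exchange rate follows from detailed balance and is over an
    order of magnitude slower than the others.
    """
    pi = np.asarray(occupancies, dtype=float)
    pi = pi / pi.sum()
    q01 = 1.0 / dwell_bound
    q10 = pi[0] * q01 / pi[1]
    q12 = 1.0 / dwell_free_srp - q10
    if q12 <= 0:
        raise ValueError("free-SRP dwell inconsistent with occupancy ratio")
    q21 = pi[1] * q12 / pi[2]
    Q = np.array([[0.0, q01, 0.0], [q10, 0.0, q12], [0.0, q21, 0.0]])
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC generator (null space of Q^T)."""
    K = Q.shape[0]
    A = np.vstack([Q.T, np.ones(K)])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def markov_switching_tracks(
    D_list: Sequence[float],
    mean_dwells: Sequence[float] | None = None,
    rate_matrix: np.ndarray | None = None,
    frame_dt: float = 0.02,
    n_tracks: int = 1000,
    mean_track_len: int = 30,
    loc_error: float = 0.03,
    seed: int | np.random.Generator = 0,
    initial_distribution: Sequence[float] | None = None,
    tracks_per_cell: int = 10,
) -> list[Track]:
    """Observed 2D tracks from a discrete-time hidden Markov chain.

    The hidden state evolves at the frame interval with transition matrix
    expm(Q * frame_dt); each displacement is Gaussian with per-axis variance
    2 D[state] frame_dt (state at the start of the step); observed positions
    carry additive localization noise of std ``loc_error``; track lengths
    are geometric with the given mean (photobleaching-like), minimum 2.
    """
    D = np.asarray(D_list, dtype=float)
    if rate_matrix is None:
        if mean_dwells is None:
            raise ValueError("provide mean_dwells or rate_matrix")
        if np.min(mean_dwells) < frame_dt:
            raise ValueError("mean dwell below the frame interval is unresolvable")
        Q = dwells_to_rate_matrix(mean_dwells)
    else:
        Q = np.asarray(rate_matrix, dtype=float)
        with np.errstate(divide="ignore"):
            tau = -1.0 / np.diag(Q)
        finite = tau[np.isfinite(tau)]
        if len(finite) and finite.min() < frame_dt:
            raise ValueError("mean dwell below the frame interval is unresolvable")
    if len(D) != Q.shape[0]:
        raise ValueError("D_list and dwell/rate dimensions disagree")
    if mean_track_len < 2:
        raise ValueError("mean_track_len must be >= 2")
    rng = np.random.default_rng(seed)
    A = expm(Q * frame_dt)
    pi0 = (
        np.asarray(initial_distribution, dtype=float)
        if initial_distribution is not None
        else stationary_distribution(Q)
    )
    K = len(D)
    tracks: list[Track] = []
    for tid in range(n_tracks):
        n_pos = max(int(rng.geometric(1.0 / mean_track_len)), 2)
        states = np.empty(n_pos, dtype=int)
        states[0] = rng.choice(K, p=pi0)
        for i in range(1, n_pos):
            states[i] = rng.choice(K, p=A[states[i - 1]])
        step_sigma = np.sqrt(2.0 * D[states[:-1]] * frame_dt)
        disp = rng.normal(size=(n_pos - 1, 2)) * step_sigma[:, None]
        true_pos = np.vstack([np.zeros(2), np.cumsum(disp, axis=0)])
        obs = true_pos + rng.normal(scale=loc_error, size=(n_pos, 2)) if loc_error > 0 else true_pos
        tracks.append(
            Track(
                track_id=tid,
                cell_id=tid // max(tracks_per_cell, 1),
                frames=np.arange(n_pos),
                positions=obs,
                loc_uncertainty=np.full(n_pos, float(loc_error)),
                frame_dt=frame_dt,
                true_states=states,
            )
        )
    return tracks


def observe(
    truths: Sequence[GroundTruthTrajectory],
    frame_dt: float = 0.02,
    z_jitter_std: float = 0.10,
    xy_shift_std: float = 0.08,
    seed: int | np.random.Generator = 0,
    loc_error: float = 0.0,
) -> list[Track]:
    """Subsample ground truth at the frame interval and add the systematic
    observation offsets: one z offset per cell (cells sit at slightly
    different heights on the pad) and one x-y shift per trajectory
    (segmentation imprecision).  Ground-truth species labels are retained.

    Frame times map to the nearest simulation time point; localization
    noise is added only if ``loc_error`` > 0 (the rendering + detection
    stages normally supply it).
    """
    rng = np.random.default_rng(seed)
    cell_ids = sorted({t.cell_id for t in truths})
    z_off = {c: rng.normal(0.0, z_jitter_std) for c in cell_ids}
    out: list[Track] = []
    for t in truths:
        sim_dt = t.times[1] - t.times[0]
        n_frames = int(np.floor(t.times[-1] / frame_dt)) + 1
        if n_frames < 2:
            continue
        src = np.round(np.arange(n_frames) * frame_dt / sim_dt).astype(int)
        src = np.clip(src, 0, len(t.times) - 1)
        shift = rng.normal(0.0, xy_shift_std, size=2) if xy_shift_std > 0 else np.zeros(2)
        xy = t.positions[src, :2] + shift
        if loc_error > 0:
            xy = xy + rng.normal(scale=loc_error, size=xy.shape)
        out.append(
            Track(
                track_id=t.particle_id,
                cell_id=t.cell_id,
                frames=np.arange(n_frames),
                positions=xy,
                loc_uncertainty=np.full(n_frames, float(loc_error)),
                frame_dt=frame_dt,
                true_states=t.species_path[src].copy(),
                true_z=t.positions[src, 2] + z_off[t.cell_id],
            )
        )
    return out


def truncate_bleach(
    tracks: Sequence[Track],
    mean_frames: float = 40.0,
    seed: int | np.random.Generator = 0,
) -> list[Track]:
    """Truncate tracks with geometric photobleaching lifetimes (min 2)."""
    rng = np.random.default_rng(seed)
    out = []
    for t in tracks:
        n = max(int(rng.geometric(1.0 / mean_frames)), 2)
        if n >= len(t):
            out.append(t)
            continue
        out.append(
            Track(
                track_id=t.track_id,
                cell_id=t.cell_id,
                frames=t.frames[:n],
                positions=t.positions[:n],
                loc_uncertainty=t.loc_uncertainty[:n],
                frame_dt=t.frame_dt,
                true_states=None if t.true_states is None else t.true_states[:n],
                true_z=None if t.true_z is None else t.true_z[:n],
            )
        )
    return out
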