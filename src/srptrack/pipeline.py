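"""End-to-end virtual experiments: simulate -> (render -> detect -> link)
-> HMM -> spatial -> kinetics, with scenario presets and a recovery
scorecard.

Scenarios encode the experimental perturbations as parameter changes:

* ``wildtype`` — three diffusion states (ribosome-bound SRP, free SRP, free
  4.5S RNA) with the wild-type occupancies and dwell times.
* ``ftsY_depletion`` — release strongly slowed (bound dwell ~19 s, ~90%
  bound occupancy) and the bound state no longer membrane-localized.
* ``rna_overexpression`` — excess unlabeled 4.5S RNA outcompetes labeling:
  ~90% of molecules in the free-RNA state, free-SRP state empty.
* ``lepB_overexpression`` — excess SRP substrate raises the bound-state
  occupancy to ~60%.
* ``membrane_marker`` — a membrane-confined species (LacY analog) used to
  build the empirical membrane reference profile.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import CellGeometry
from .hmm import (
    COARSE_THRESHOLDS,
    CoarseModel,
    HMMModel,
    coarse_grain,
    decode,
    dwell_and_flux,
    fit_hmm,
)
from .kinetics import build_params
from .simulate import (
    Reaction,
    SimulationConfig,
    SpeciesModel,
    default_srp_model,
    markov_switching_tracks,
    observe,
    simulate_cell,
    truncate_bleach,
    wildtype_rate_matrix,
)
from .spatial import (
    EXTENDED_R_MAX,
    decompose_profile,
    event_spatial_stats,
    extended_cytosol_profile,
    extended_histogram,
    extract_events,
    sample_two_component_positions,
    synthetic_membrane_reference,
)
from .tracks import Track, total_steps, write_tracks

#: datasets below this step count are flagged: the HMM analysis only
#: converges reliably from roughly this size upward
MIN_CONVERGED_STEPS = 40_000


@dataclass(frozen=True)
class Scenario:
    name: str
    D: tuple[float, ...]
    occupancies: tuple[float, ...]
    dwell_bound: float
    dwell_free: float | None  # None when the free-SRP state is absent
    membrane_fraction_slow: float
    membrane_fraction_binding: float
    membrane_fraction_release: float

    def rate_matrix(self) -> np.ndarray:
        if len(self.D) == 1:
            return np.zeros((1, 1))
        if len(self.D) == 3 and self.dwell_free is not None:
            return wildtype_rate_matrix(
                occupancies=self.occupancies,
                dwell_bound=self.dwell_bound,
                dwell_free_srp=self.dwell_free,
            )
        pi = np.asarray(self.occupancies)
        q01 = 1.0 / self.dwell_bound
        q10 = pi[0] * q01 / pi[1]
        Q = np.array([[-q01, q01], [q10, -q10]])
        return Q

    def species_model(self) -> SpeciesModel:
        if self.name == "membrane_marker":
            # LacY analog: a single membrane-confined species, no reactions
            return SpeciesModel(
                species=("MARKER",), D={"MARKER": 0.03},
                allowed={"MARKER": "membrane"}, reactions=(),
            )
        base = default_srp_model()
        if self.name == "ftsY_depletion":
            rx = tuple(
                Reaction(r.src, r.dst, 1.0 / 19.0, r.gate)
                if (r.src, r.dst) == ("RM", "SRP") else r
                for r in base.reactions
            )
            return SpeciesModel(reactions=rx)
        if self.name == "rna_overexpression":
            rx = tuple(
                Reaction("RNA", "SRP", 0.005) if (r.src, r.dst) == ("RNA", "SRP")
                else Reaction("SRP", "RNA", 0.08) if (r.src, r.dst) == ("SRP", "RNA")
                else r
                for r in base.reactions
            )
            return SpeciesModel(reactions=rx)
        if self.name == "lepB_overexpression":
            return default_srp_model(search_time=0.55)
        return base


SCENARIOS: dict[str, Scenario] = {
    "wildtype": Scenario(
        "wildtype", D=(0.05, 1.7, 4.3), occupancies=(0.28, 0.56, 0.16),
        dwell_bound=1.0, dwell_free=1.9,
        membrane_fraction_slow=0.44, membrane_fraction_binding=0.25,
        membrane_fraction_release=0.86,
    ),
    "ftsY_depletion": Scenario(
        "ftsY_depletion", D=(0.05, 1.7), occupancies=(19.0 / 20.9, 1.9 / 20.9),
        dwell_bound=19.0, dwell_free=None,
        membrane_fraction_slow=0.0, membrane_fraction_binding=0.0,
        membrane_fraction_release=0.0,
    ),
    "rna_overexpression": Scenario(
        "rna_overexpression", D=(0.05, 4.3), occupancies=(0.1, 0.9),
        dwell_bound=1.0, dwell_free=None,
        membrane_fraction_slow=0.44, membrane_fraction_binding=0.25,
        membrane_fraction_release=0.86,
    ),
    "lepB_overexpression": Scenario(
        "lepB_overexpression", D=(0.05, 1.7, 4.3), occupancies=(0.60, 0.28, 0.12),
        dwell_bound=1.0, dwell_free=1.16,
        membrane_fraction_slow=0.44, membrane_fraction_binding=0.25,
        membrane_fraction_release=0.86,
    ),
    # membrane-marker (LacY analog) movies allow two spots per cell in the
    # track-start rule and feed membrane_reference_from_tracks
    "membrane_marker": Scenario(
        "membrane_marker", D=(0.03,), occupancies=(1.0,),
        dwell_bound=np.inf, dwell_free=None,
        membrane_fraction_slow=1.0, membrane_fraction_binding=0.0,
        membrane_fraction_release=0.0,
    ),
}


@dataclass
class PipelineConfig:
    scenario: str = "wildtype"
    mode: str = "markov"  # markov | fast | full
    seed: int = 0
    # markov mode
    n_tracks: int = 2000
    mean_track_len: int = 30
    loc_error: float = 0.03
    frame_dt: float = 0.02
    # geometric modes
    n_cells: int = 10
    particles_per_cell: int = 10
    t_record: float = 20.0
    t_equilibrate: float = 5.0
    sim_dt: float = 0.002
    # analysis
    K: int | None = None
    thresholds: tuple[float, float] = COARSE_THRESHOLDS
    exposure: float = 0.0
    n_restarts: int = 5
    n_boot_profiles: int = 200
    outdir: str | None = None

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


# species index -> coarse ground-truth state for scoring: RNA=fast(2),
# SRP=intermediate(1), RC/RM=slow(0)
SPECIES_TO_COARSE = {0: 2, 1: 1, 2: 0, 3: 0}


@dataclass
class PipelineResult:
    config: PipelineConfig
    tracks: list
    model: HMMModel
    coarse: CoarseModel
    flux: dict
    spatial: dict
    kinetics: Optional[dict]
    scorecard: dict


def _markov_tracks(scn: Scenario, cfg: PipelineConfig, rng) -> list[Track]:
    return markov_switching_tracks(
        scn.D,
        rate_matrix=scn.rate_matrix(),
        frame_dt=cfg.frame_dt,
        n_tracks=cfg.n_tracks,
        mean_track_len=cfg.mean_track_len,
        loc_error=cfg.loc_error,
        seed=rng,
    )


def _geometric_tracks(scn: Scenario, cfg: PipelineConfig, rng, geom) -> list[Track]:
    model = scn.species_model()
    sim = SimulationConfig(
        dt=cfg.sim_dt, n_particles=cfg.particles_per_cell,
        n_replicates=cfg.n_cells, t_equilibrate=cfg.t_equilibrate,
        t_record=cfg.t_record, seed=int(rng.integers(2**31)),
        initial_species="stationary",
    )
    truths = simulate_cell(model, geom, sim)
    tracks = observe(
        truths, frame_dt=cfg.frame_dt, seed=int(rng.integers(2**31)),
        loc_error=cfg.loc_error if cfg.mode == "fast" else 0.0,
    )
    if cfg.mode == "fast":
        tracks = truncate_bleach(tracks, seed=int(rng.integers(2**31)))
        # map species labels to coarse ground truth
        for t in tracks:
            if t.true_states is not None:
                t.true_states = np.array([SPECIES_TO_COARSE[s] for s in t.true_states])
    return tracks


def _full_mode_tracks(tracks: list[Track], cfg: PipelineConfig, rng, geom,
                      start_rule_n: int = 1) -> list[Track]:
    """Render each cell's observed trajectories and re-detect them."""
    from .detect import detect_stack
    from .link import link_tracks
    from .render import IlluminationModel, OpticsModel, make_masks, render_movie

    optics = OpticsModel()
    illum = IlluminationModel(frame_interval=cfg.frame_dt)
    mask = make_masks(geom, optics=optics)
    out: list[Track] = []
    by_cell: dict[int, list[Track]] = {}
    for t in tracks:
        by_cell.setdefault(t.cell_id, []).append(t)
    for cell_id in sorted(by_cell):
        stack = render_movie(
            by_cell[cell_id], optics, illum, seed=int(rng.integers(2**31)), geom=geom,
        )
        stack.mask = (mask > 0).astype(int)
        dets = detect_stack(stack, mask=stack.mask)
        linked = link_tracks(
            dets, max_step=5 * np.sqrt(2 * 4.3 * cfg.frame_dt),
            frame_dt=cfg.frame_dt, start_rule_n=start_rule_n,
        )
        for t in linked:
            t.cell_id = cell_id
        out.extend(linked)
    # re-id tracks uniquely across cells
    for i, t in enumerate(out):
        t.track_id = i
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured virtual experiment; optionally write a run
    directory with all intermediate tables and reports."""
    scn = SCENARIOS[config.scenario]
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    geom = CellGeometry()

    if config.mode == "markov":
        tracks = _markov_tracks(scn, config, rngs[0])
    else:
        tracks = _geometric_tracks(scn, config, rngs[0], geom)
        if config.mode == "full":
            tracks = _full_mode_tracks(
                tracks, config, rngs[1], geom,
                start_rule_n=2 if config.scenario == "membrane_marker" else 1,
            )
    if not tracks:
        raise RuntimeError("stage simulate/track: no usable tracks produced")

    K = config.K if config.K is not None else len(scn.D)
    try:
        model = fit_hmm(
            tracks, K=K, exposure=config.exposure,
            n_restarts=config.n_restarts, seed=int(rngs[2].integers(2**31)),
        )
    except FloatingPointError as e:
        raise RuntimeError(f"stage hmm: {e}") from e
    coarse = coarse_grain(model, config.thresholds)
    flux = dwell_and_flux(coarse)

    spatial_report = _spatial_stage(scn, config, tracks, coarse, geom, rngs[3])
    kin = _kinetics_stage(scn, coarse, spatial_report)

    scorecard = _scorecard(scn, config, tracks, model, coarse, spatial_report)
    result = PipelineResult(
        config=config, tracks=tracks, model=model, coarse=coarse, flux=flux,
        spatial=spatial_report, kinetics=kin, scorecard=scorecard,
    )
    if config.outdir:
        _write_run_dir(result)
    return result


def _spatial_stage(scn, config, tracks, coarse, geom, rng) -> dict:
    """Radial profiles and membrane decomposition per coarse state.

    In geometry-free (markov) mode the positions are random walks without a
    cell frame, so state-resolved position sets are constructed from the
    scenario's ground-truth membrane fractions instead — the same
    construction used in the validation experiments.
    """
    cyt = extended_cytosol_profile(geom)
    # in fast mode no detection stage thins out-of-focus molecules, so the
    # reference must not apply the defocus-detectability weight either
    mem_ref = synthetic_membrane_reference(
        seed=int(rng.integers(2**31)), r_max=EXTENDED_R_MAX,
        detection_z_scale=None if config.mode == "fast" else 0.4,
    )
    report: dict = {"membrane_reference": mem_ref.provenance}
    fractions = {}
    if config.mode == "markov":
        specs = {0: scn.membrane_fraction_slow}
        for g in range(1, len(scn.D)):
            specs[g] = 0.0
        for g, frac in specs.items():
            pos = sample_two_component_positions(
                8000, frac, geom, rng=int(rng.integers(2**31))
            )
            prof = extended_histogram(pos)
            dec = decompose_profile(prof, cyt, mem_ref,
                                    n_boot=config.n_boot_profiles,
                                    seed=int(rng.integers(2**31)))
            fractions[g] = dec
        report["events"] = _construct_events_report(scn, config, cyt, mem_ref, rng)
    else:
        paths = decode(tracks, coarse)
        from .geometry import normalize_position

        for g in range(coarse.n_groups):
            if coarse.pi_coarse[g] <= 0:
                continue
            pts = []
            g_eff = _coarse_to_decoded(coarse, g)
            if g_eff is None:
                continue
            for t, p in zip(tracks, paths):
                sel = (p.states == g_eff) & ~p.ambiguous
                if sel.any():
                    pts.append(t.positions[sel])
            if not pts:
                continue
            pos = normalize_position(np.vstack(pts), geom=geom)
            prof = extended_histogram(pos)
            if prof.is_empty:
                continue
            fractions[g] = decompose_profile(
                prof, cyt, mem_ref, n_boot=config.n_boot_profiles,
                seed=int(rng.integers(2**31)),
            )
        events, ev_report = extract_events(paths, tracks, slow_state_id=0)
        stats = event_spatial_stats(
            events, cyt, mem_ref, geom=geom, n_boot=config.n_boot_profiles,
            seed=int(rng.integers(2**31)),
        )
        report["events"] = {"report": ev_report,
                            **{k: asdict(v) for k, v in stats.items()}}
    report["state_membrane_fractions"] = {
        g: {"fraction": d.membrane_fraction, "ci": d.ci} for g, d in fractions.items()
    }
    return report


def _coarse_to_decoded(coarse: CoarseModel, g: int) -> int | None:
    """Map a coarse group index to its index among non-empty groups (the
    decode HMM drops empty groups)."""
    keep = ~coarse.empty_groups
    if not keep[g]:
        return None
    return int(keep[:g].sum())


def _construct_events_report(scn, config, cyt, mem_ref, rng) -> dict:
    """Event-location decomposition from scenario-constructed events
    (markov mode has no cell frame; the construction mirrors the event
    counts and membrane fractions of the scenario)."""
    from .geometry import CellGeometry
    from .spatial import event_component_references, sample_event_positions

    geom = CellGeometry()
    cyt_ev, mem_ev = event_component_references(geom, seed=int(rng.integers(2**31)))
    out = {}
    for kind, frac, n in (
        ("binding", scn.membrane_fraction_binding, 200),
        ("release", scn.membrane_fraction_release, 200),
    ):
        pos = sample_event_positions(
            n, frac, geom, n_neighbors=2, rng=int(rng.integers(2**31))
        )
        prof = extended_histogram(pos)
        dec = decompose_profile(prof, cyt_ev, mem_ev, n_boot=config.n_boot_profiles,
                                seed=int(rng.integers(2**31)))
        out[kind] = {"membrane_fraction": dec.membrane_fraction, "ci": dec.ci,
                     "n_events": n}
    return out


def _kinetics_stage(scn, coarse, spatial_report) -> Optional[dict]:
    fr = spatial_report.get("state_membrane_fractions", {})
    ev = spatial_report.get("events", {})
    if 0 not in fr or "binding" not in ev:
        return None
    tau_bound = float(coarse.dwell[0])
    tau_free = float(coarse.dwell[1]) if coarse.n_groups > 1 and np.isfinite(coarse.dwell[1]) else np.nan
    phi_M = fr[0]["fraction"]
    b = ev["binding"]
    f_C = 1.0 - (b["membrane_fraction"] if isinstance(b, dict) else b.membrane_fraction)
    if not np.isfinite(tau_bound) or f_C <= 0:
        return None
    p = build_params(tau_free if np.isfinite(tau_free) else 0.0, tau_bound, phi_M, f_C)
    return {
        "tau_free_s": p.tau_free, "tau_bound_total_s": p.tau_bound_total,
        "phi_M": p.phi_M, "f_C": p.f_C, "tau_M_s": p.tau_M, "tau_C_s": p.tau_C,
        "cycle_time_s": p.cycle_time,
    }


def _scorecard(scn, config, tracks, model, coarse, spatial_report) -> dict:
    n_steps = total_steps(tracks)
    card = {
        "scenario": scn.name,
        "mode": config.mode,
        "n_tracks": len(tracks),
        "n_steps": n_steps,
        "converged_dataset": n_steps >= MIN_CONVERGED_STEPS,
        "truth": {
            "D": list(scn.D),
            "occupancies": list(scn.occupancies),
            "dwell_bound_s": scn.dwell_bound if np.isfinite(scn.dwell_bound) else None,
            "dwell_free_s": scn.dwell_free,
            "membrane_fraction_slow": scn.membrane_fraction_slow,
        },
        "estimate": {
            "D_coarse": [None if not np.isfinite(d) else float(d) for d in coarse.D_coarse],
            "pi_coarse": coarse.pi_coarse.tolist(),
            "dwell_s": [None if not np.isfinite(d) else float(d) for d in coarse.dwell],
            "log_likelihood": model.log_likelihood,
        },
    }
    fr = spatial_report.get("state_membrane_fractions", {})
    if 0 in fr:
        card["estimate"]["membrane_fraction_slow"] = fr[0]["fraction"]
    if not card["converged_dataset"]:
        card["warning"] = (
            f"dataset has {n_steps} steps; estimates may not be converged "
            f"(recommend >= {MIN_CONVERGED_STEPS})"
        )
    return card


def _write_run_dir(result: PipelineResult) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(result.config.to_json())
    write_tracks(result.tracks, out / "tracks.csv")
    with open(out / "model_report.txt", "w") as f:
        m, c = result.model, result.coarse
        f.write(f"K = {m.K}  steps = {m.n_steps}  logL = {m.log_likelihood:.6f}\n")
        f.write("state  D_um2_s  occupancy\n")
        for k in range(m.K):
            f.write(f"{k}  {m.D[k]:.6g}  {m.pi[k]:.6g}\n")
        f.write("A =\n")
        for row in m.A:
            f.write("  " + "  ".join(f"{v:.6g}" for v in row) + "\n")
        f.write(f"coarse thresholds = {c.thresholds}\n")
        f.write("group  D  occupancy  dwell_s\n")
        for g in range(c.n_groups):
            f.write(
                f"{g}  {c.D_coarse[g]:.6g}  {c.pi_coarse[g]:.6g}  {c.dwell[g]:.6g}\n"
            )
        fl = result.flux
        f.write("flux_in  " + "  ".join(f"{v:.6g}" for v in fl["flux_in"]) + "\n")
        f.write("flux_out  " + "  ".join(f"{v:.6g}" for v in fl["flux_out"]) + "\n")
    (out / "spatial.json").write_text(json.dumps(result.spatial, indent=2, default=str))
    if result.kinetics:
        (out / "kinetics.json").write_text(json.dumps(result.kinetics, indent=2))
    (out / "scorecard.json").write_text(json.dumps(result.scorecard, indent=2))
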