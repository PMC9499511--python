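"""Spatial analysis: radial histograms, membrane/interior decomposition, and
localization of binding/release events.

Positions are projected onto the short cell axis in normalized coordinates
(inner membrane edge at r = +/-1).  Profiles use only the cylindrical part:
positions within margin ``m`` of either pole, or of mid-cell (possible
septum), are excluded.  An observed profile is decomposed as a two-component
superposition

    observed ~ alpha * membrane_reference + (1 - alpha) * cytosol_reference

by least squares with alpha constrained to [0, 1].  Because membrane-shell
molecules can project beyond |r| = 1 and get clipped from the histogram,
each reference carries its in-range retention and the fitted in-range
weight is converted back to a molecule fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    N_BINS_DEFAULT,
    CellGeometry,
    NormalizedPosition,
    RadialProfile,
    sample_membrane_shell,
    theoretical_cytosol_profile,
)
from .hmm import StatePath, fit_hmm, decode
from .tracks import Track

POLE_MARGIN_DEFAULT = 0.15


@dataclass
class MembraneReference:
    """Empirical membrane radial profile (membrane-marker analog of LacY)."""

    profile: RadialProfile
    provenance: str = "synthetic-marker"

    @property
    def retention(self) -> float:
        return self.profile.retention


@dataclass
class TransitionEvent:
    """A Viterbi-detected arrival to (binding) or departure from (release)
    the slow, ribosome-bound state, with up to two neighbor positions
    (following the arrival / preceding the departure)."""

    kind: str  # "binding" | "release"
    cell_id: int
    track_id: int
    frame: int
    positions: np.ndarray  # (1..3, 2): event position + neighbors, lab µm
    norm_r: Optional[np.ndarray] = None
    norm_x: Optional[np.ndarray] = None


#: extended short-axis range used for decomposition fits: membrane-shell
#: positions project out to |r| ~ 1.12 (+ jitter), a region where the
#: cytosol reference has essentially no mass and which therefore carries
#: most of the membrane/interior discrimination
EXTENDED_R_MAX = 4.0 / 3.0


def extended_histogram(
    positions: NormalizedPosition,
    margin: float = POLE_MARGIN_DEFAULT,
) -> RadialProfile:
    """Radial histogram over |r| <= 4/3 with the standard 18-bin width
    (24 bins); used for decomposition fits rather than presentation."""
    return radial_histogram(positions, n_b=24, margin=margin,
                            r_max=EXTENDED_R_MAX)


def extended_cytosol_profile(geom: CellGeometry = CellGeometry()) -> RadialProfile:
    """Theoretical uniform-cytosol profile on the extended decomposition
    bins (zero density beyond |r| = 1)."""
    from .geometry import theoretical_cytosol_profile

    base = theoretical_cytosol_profile(geom, n_b=N_BINS_DEFAULT)
    edges = np.linspace(-EXTENDED_R_MAX, EXTENDED_R_MAX, 25)
    density = np.zeros(24)
    density[3:21] = base.density
    density /= np.sum(density * np.diff(edges))
    return RadialProfile(bin_edges=edges, density=density, n_total=0,
                         retention=1.0)


def radial_histogram(
    positions: NormalizedPosition,
    n_b: int = N_BINS_DEFAULT,
    margin: float = POLE_MARGIN_DEFAULT,
    weights: np.ndarray | None = None,
    r_max: float = 1.0,
) -> RadialProfile:
    """Short-axis histogram of normalized positions with pole and mid-cell
    exclusion windows.

    Positions with x_long in (0, m), (1-m, 1) complement... explicitly:
    only positions with m <= x_long <= 0.5-m or 0.5+m <= x_long <= 1-m
    contribute.  The histogram spans r in [-1, 1]; the retention field
    records the fraction of margin-surviving positions inside that range.
    """
    x = np.asarray(positions.x_long, dtype=float)
    r = np.asarray(positions.r_short, dtype=float)
    ok = np.isfinite(r) & np.isfinite(x)
    keep = ok & (
        ((x >= margin) & (x <= 0.5 - margin)) | ((x >= 0.5 + margin) & (x <= 1.0 - margin))
    )
    if margin == 0:
        keep = ok
    n_excluded = int(ok.sum() - keep.sum())
    r = r[keep]
    w = None if weights is None else np.asarray(weights, dtype=float)[keep]
    edges = np.linspace(-r_max, r_max, n_b + 1)
    in_range = (r >= -r_max) & (r <= r_max)
    n_in = int(in_range.sum())
    if n_in == 0:
        return RadialProfile(
            bin_edges=edges, density=np.zeros(n_b), n_total=0, retention=0.0,
            n_excluded_margin=n_excluded,
        )
    counts, _ = np.histogram(r[in_range], bins=edges,
                             weights=None if w is None else w[in_range])
    density = counts / counts.sum() / np.diff(edges)
    retention = n_in / len(r) if len(r) else 0.0
    return RadialProfile(
        bin_edges=edges, density=density, n_total=n_in, retention=retention,
        n_excluded_margin=n_excluded,
    )


def mirror_profile(profile: RadialProfile) -> RadialProfile:
    """Fold a signed profile about r = 0 (presentation convenience)."""
    n_b = len(profile.density)
    assert n_b % 2 == 0
    half = n_b // 2
    dens = profile.density[half:] + profile.density[:half][::-1]
    dens = dens / np.sum(dens * np.diff(profile.bin_edges[half:]))
    return RadialProfile(
        bin_edges=profile.bin_edges[half:], density=dens,
        n_total=profile.n_total, retention=profile.retention,
    )


@dataclass
class Decomposition:
    membrane_fraction: float  # molecule fraction after retention correction
    ci: tuple[float, float]
    alpha_in_range: float  # raw fitted weight among in-range positions
    residual_rms: float
    ill_conditioned: bool = False


def _fit_alpha(obs: np.ndarray, mem: np.ndarray, cyt: np.ndarray,
               widths: np.ndarray, n_total: int = 0,
               method: str = "ml") -> tuple[float, float]:
    """Constrained weight of the membrane component plus residual RMS.

    ``ml`` maximizes the multinomial bin likelihood (efficient when the
    discrimination lives in a few low-density bins); ``ls`` is plain least
    squares on densities.
    """
    diff = mem - cyt
    denom = float(np.sum(widths * diff * diff))
    if denom <= 0:
        return 0.0, float(np.sqrt(np.mean((obs - cyt) ** 2)))
    a = float(np.sum(widths * (obs - cyt) * diff) / denom)
    a = min(max(a, 0.0), 1.0)
    if method == "ml" and n_total > 0:
        from scipy.optimize import minimize_scalar

        counts = obs * widths * n_total

        def nll(x: float) -> float:
            mix = np.maximum(x * mem + (1 - x) * cyt, 1e-12)
            return -float(np.sum(counts * np.log(mix * widths)))

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        a = float(res.x)
    resid = obs - (a * mem + (1 - a) * cyt)
    return a, float(np.sqrt(np.mean(resid**2)))


def _alpha_to_molecule_fraction(a: float, ret_mem: float, ret_cyt: float) -> float:
    """Undo range clipping: convert the fitted in-range weight into the
    fraction of molecules that are membrane-bound."""
    if a <= 0:
        return 0.0
    num = a / max(ret_mem, 1e-9)
    den = num + (1.0 - a) / max(ret_cyt, 1e-9)
    return float(num / den)


def decompose_profile(
    observed: RadialProfile,
    cytosol_ref: RadialProfile,
    membrane_ref: MembraneReference,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> Decomposition:
    """Two-component decomposition of an observed radial profile.

    Fits observed ~ alpha * membrane + (1-alpha) * cytosol with
    alpha in [0, 1] by least squares on binned densities; the CI comes from
    a multinomial bootstrap over the contributing positions.  The returned
    membrane fraction is retention-corrected to the molecule scale.
    """
    mem_p = membrane_ref.profile
    if not np.allclose(observed.bin_edges, cytosol_ref.bin_edges) or not np.allclose(
        observed.bin_edges, mem_p.bin_edges
    ):
        raise ValueError("profiles must share identical bins")
    if observed.is_empty:
        raise ValueError("empty observed profile")
    widths = observed.bin_width
    a, resid = _fit_alpha(observed.density, mem_p.density, cytosol_ref.density,
                          widths, n_total=observed.n_total)
    # ill conditioning: membrane and cytosol references nearly identical
    sep = float(np.sum(widths * np.abs(mem_p.density - cytosol_ref.density)))
    ill = sep < 0.2
    frac = _alpha_to_molecule_fraction(a, mem_p.retention, cytosol_ref.retention)
    rng = np.random.default_rng(seed)
    boot = []
    n = observed.n_total
    probs = observed.density * widths
    probs = probs / probs.sum()
    for _ in range(max(n_boot, 1)):
        counts = rng.multinomial(n, probs)
        dens = counts / counts.sum() / widths
        ab, _ = _fit_alpha(dens, mem_p.density, cytosol_ref.density, widths,
                           n_total=n)
        boot.append(_alpha_to_molecule_fraction(ab, mem_p.retention, cytosol_ref.retention))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    if ill:
        lo, hi = 0.0, 1.0
    if n_boot <= 1:
        lo = hi = frac
    return Decomposition(
        membrane_fraction=frac, ci=(float(lo), float(hi)), alpha_in_range=a,
        residual_rms=resid, ill_conditioned=ill,
    )


# ---------------------------------------------------------------------------
# membrane-marker reference
# ---------------------------------------------------------------------------


def sample_marker_positions(
    n: int,
    geom: CellGeometry = CellGeometry(),
    z_jitter_std: float = 0.10,
    xy_shift_std: float = 0.08,
    detection_z_scale: float | None = 0.4,
    rng: np.random.Generator | int | None = 0,
    n_per_group: int = 20,
) -> NormalizedPosition:
    """Synthetic membrane-marker localizations in normalized coordinates.

    Emulates the apparent (2D-projected) distribution of a membrane protein:
    positions uniform in the shell volume of the cylindrical part, a shared
    z offset per group of positions (cell-to-cell focus jitter) and a shared
    in-plane shift per trajectory-sized group (segmentation imprecision).
    ``detection_z_scale`` (µm) applies a Gaussian defocus-detectability
    weight in total z — molecules far from the focal plane are less likely
    to be detected, which is how the z jitter changes the apparent profile;
    None disables the weighting (all positions kept).
    """
    rng = np.random.default_rng(rng)
    # oversample, then thin by detectability
    m = int(n * 3) if detection_z_scale else n
    pts = sample_membrane_shell(m, geom, rng, cylindrical_only=True)
    groups = np.arange(m) // max(n_per_group, 1)
    n_groups = groups.max() + 1
    z_off = rng.normal(0.0, z_jitter_std, size=n_groups)[groups] if z_jitter_std > 0 else 0.0
    y_shift = rng.normal(0.0, xy_shift_std, size=n_groups)[groups] if xy_shift_std > 0 else 0.0
    z_tot = pts[:, 2] + z_off
    if detection_z_scale:
        p = np.exp(-0.5 * (z_tot / detection_z_scale) ** 2)
        keep = rng.random(m) < p
        pts, z_tot, y_shift = pts[keep], z_tot[keep], np.asarray(y_shift)[keep] if np.ndim(y_shift) else y_shift
    pts = pts[:n]
    y_obs = pts[:, 1] + (y_shift[:n] if np.ndim(y_shift) else 0.0)
    x_long = (pts[:, 0] + geom.total_length / 2.0) / geom.total_length
    r_short = y_obs / geom.cylinder_radius
    return NormalizedPosition(
        x_long=x_long, r_short=r_short,
        z=z_tot[:n] if np.ndim(z_tot) else None,
    )


def sample_two_component_positions(
    n: int,
    membrane_fraction: float,
    geom: CellGeometry = CellGeometry(),
    z_jitter_std: float = 0.10,
    xy_shift_std: float = 0.08,
    rng: np.random.Generator | int | None = 0,
    n_per_group: int = 1,
) -> NormalizedPosition:
    """Synthetic position set with a known membrane-bound molecule fraction.

    ``membrane_fraction`` of the molecules sit in the membrane shell (with
    the marker's jitter and detectability model), the rest uniform in the
    cytosol.  Both components are sampled on the cylindrical part so the
    pole/mid-cell margins do not shift the composition.  Jitter offsets are
    drawn per position by default (independent draws); set ``n_per_group``
    to share them across trajectory-sized groups.
    """
    from .geometry import sample_cytosol_uniform

    rng = np.random.default_rng(rng)
    n_mem = int(rng.binomial(n, membrane_fraction)) if 0 < membrane_fraction < 1 else int(round(n * membrane_fraction))
    xs, rs = [], []
    if n_mem:
        mem = sample_marker_positions(
            n_mem, geom, z_jitter_std=z_jitter_std, xy_shift_std=xy_shift_std,
            rng=rng, n_per_group=n_per_group,
        )
        xs.append(mem.x_long)
        rs.append(mem.r_short)
    if n - n_mem:
        pts = sample_cytosol_uniform(n - n_mem, geom, rng, cylindrical_only=True)
        xs.append((pts[:, 0] + geom.total_length / 2.0) / geom.total_length)
        rs.append(pts[:, 1] / geom.cylinder_radius)
    return NormalizedPosition(x_long=np.concatenate(xs), r_short=np.concatenate(rs))


def sample_event_positions(
    n_events: int,
    membrane_fraction: float,
    geom: CellGeometry = CellGeometry(),
    n_neighbors: int = 2,
    D_slow: float = 0.05,
    frame_dt: float = 0.02,
    z_jitter_std: float = 0.10,
    xy_shift_std: float = 0.08,
    rng: np.random.Generator | int | None = 0,
    detection_z_scale: float | None = 0.4,
) -> NormalizedPosition:
    """Synthetic transition-event position pool with a known membrane split.

    Each event sits on the membrane shell (with the marker jitter and
    defocus-detectability model) with probability ``membrane_fraction``,
    otherwise uniform in the cytosol; its ``n_neighbors`` neighbor
    positions random-walk away at the slow-state diffusion coefficient
    (per-axis step std sqrt(2 D dt)), as the ±2-position rule pools them
    with the event itself.  Membrane-bound complexes diffuse along the
    shell surface (axial + angular), never radially off it.
    """
    rng = np.random.default_rng(rng)
    n_mem = int(rng.binomial(n_events, membrane_fraction)) if 0 < membrane_fraction < 1 else int(round(n_events * membrane_fraction))
    sigma_step = np.sqrt(2.0 * D_slow * frame_dt)
    xs, rs = [], []
    if n_mem:
        m = 4 * n_mem if detection_z_scale else n_mem
        pts = sample_membrane_shell(m, geom, rng, cylindrical_only=True)
        z_off = rng.normal(0.0, z_jitter_std, m) if z_jitter_std > 0 else np.zeros(m)
        if detection_z_scale:
            p = np.exp(-0.5 * ((pts[:, 2] + z_off) / detection_z_scale) ** 2)
            keep = np.flatnonzero(rng.random(m) < p)[:n_mem]
            pts = pts[keep]
        pts = pts[:n_mem]
        n_mem = len(pts)
        rho = np.sqrt(pts[:, 1] ** 2 + pts[:, 2] ** 2)
        phi = np.arctan2(pts[:, 1], pts[:, 2])
        x = pts[:, 0]
        y_shift = rng.normal(0.0, xy_shift_std, n_mem) if xy_shift_std > 0 else 0.0
        for j in range(n_neighbors + 1):
            if j > 0:
                x = x + rng.normal(0.0, sigma_step, n_mem)
                phi = phi + rng.normal(0.0, sigma_step, n_mem) / rho
            y_obs = rho * np.sin(phi) + y_shift
            xs.append((x + geom.total_length / 2.0) / geom.total_length)
            rs.append(y_obs / geom.cylinder_radius)
    n_cyt = n_events - n_mem
    if n_cyt:
        from .geometry import sample_cytosol_uniform

        pts = sample_cytosol_uniform(n_cyt, geom, rng, cylindrical_only=True)
        x, y = pts[:, 0], pts[:, 1]
        for j in range(n_neighbors + 1):
            if j > 0:
                x = x + rng.normal(0.0, sigma_step, n_cyt)
                y = y + rng.normal(0.0, sigma_step, n_cyt)
            xs.append((x + geom.total_length / 2.0) / geom.total_length)
            rs.append(y / geom.cylinder_radius)
    return NormalizedPosition(x_long=np.concatenate(xs), r_short=np.concatenate(rs))


def event_component_references(
    geom: CellGeometry = CellGeometry(),
    n: int = 150_000,
    n_neighbors: int = 2,
    D_slow: float = 0.05,
    frame_dt: float = 0.02,
    margin: float = POLE_MARGIN_DEFAULT,
    seed: int | np.random.Generator = 0,
    **obs_kwargs,
) -> tuple[RadialProfile, "MembraneReference"]:
    """Large-sample references for event-profile decomposition.

    Pure-membrane and pure-cytosol event pools (event + neighbors, with the
    same observation model as the data) are sampled at large n and binned
    on the extended decomposition range, so the decomposition compares the
    observed event pool against exactly matched component shapes.
    """
    rng = np.random.default_rng(seed)
    mem_pos = sample_event_positions(
        n, 1.0, geom, n_neighbors=n_neighbors, D_slow=D_slow,
        frame_dt=frame_dt, rng=rng, **obs_kwargs,
    )
    cyt_pos = sample_event_positions(
        n, 0.0, geom, n_neighbors=n_neighbors, D_slow=D_slow,
        frame_dt=frame_dt, rng=rng, **obs_kwargs,
    )
    mem_prof = extended_histogram(mem_pos, margin=margin)
    cyt_prof = extended_histogram(cyt_pos, margin=margin)
    return cyt_prof, MembraneReference(profile=mem_prof,
                                       provenance="matched-event-components")


def synthetic_membrane_reference(
    n: int = 200_000,
    geom: CellGeometry = CellGeometry(),
    z_jitter_std: float = 0.10,
    xy_shift_std: float = 0.08,
    n_b: int = N_BINS_DEFAULT,
    margin: float = POLE_MARGIN_DEFAULT,
    seed: int | np.random.Generator = 0,
    detection_z_scale: float | None = 0.4,
    r_max: float = 1.0,
) -> MembraneReference:
    """Membrane reference profile from the synthetic shell sampler."""
    pos = sample_marker_positions(
        n, geom, z_jitter_std=z_jitter_std, xy_shift_std=xy_shift_std, rng=seed,
        detection_z_scale=detection_z_scale,
    )
    if r_max != 1.0:
        prof = radial_histogram(pos, n_b=24, margin=margin, r_max=r_max)
    else:
        prof = radial_histogram(pos, n_b=n_b, margin=margin)
    return MembraneReference(profile=prof, provenance="synthetic-shell-sampler")


def membrane_reference_from_tracks(
    marker_tracks: Sequence[Track],
    geom: CellGeometry = CellGeometry(),
    n_b: int = N_BINS_DEFAULT,
    margin: float = POLE_MARGIN_DEFAULT,
    min_positions: int = 500,
    seed: int = 0,
    exposure: float = 0.0,
) -> MembraneReference:
    """Build the membrane reference from membrane-marker tracks.

    A two-state HMM separates genuine marker diffusion (slower, dominant)
    from tracking artifacts; only positions confidently assigned to the
    marker state enter the profile.  With insufficient data the analytic
    shell-projection reference convolved with the configured jitter is used
    instead (flagged in provenance).
    """
    try:
        model = fit_hmm(marker_tracks, K=2, exposure=exposure, n_restarts=3, seed=seed)
        paths = decode(marker_tracks, model)
        marker_state = int(np.argmax(model.pi))
        xs, rs = [], []
        for t, p in zip(sorted(marker_tracks, key=lambda t: (t.cell_id, t.track_id)),
                        sorted(paths, key=lambda p: (p.cell_id, p.track_id))):
            sel = (p.states == marker_state) & ~p.ambiguous
            from .geometry import normalize_position

            norm = normalize_position(t.positions[sel], geom=geom)
            xs.append(norm.x_long)
            rs.append(norm.r_short)
        pos = NormalizedPosition(x_long=np.concatenate(xs), r_short=np.concatenate(rs))
        if len(pos) < min_positions:
            raise ValueError("insufficient marker positions")
        prof = radial_histogram(pos, n_b=n_b, margin=margin)
        return MembraneReference(profile=prof, provenance="marker-tracks")
    except (ValueError, FloatingPointError):
        ref = synthetic_membrane_reference(n_b=n_b, margin=margin, geom=geom, seed=seed)
        ref.provenance = "fallback-analytic-shell"
        return ref


# ---------------------------------------------------------------------------
# transition events
# ---------------------------------------------------------------------------


def extract_events(
    state_paths: Sequence[StatePath],
    tracks: Sequence[Track],
    slow_state_id: int = 0,
    min_segments: int = 3,
    n_neighbors: int = 2,
) -> tuple[list[TransitionEvent], dict]:
    """Binding (arrival to the slow state) and release (departure from it)
    events from Viterbi paths.

    An event is kept only if the track has at least ``min_segments``
    displacement steps before AND after the transition position.  Arrivals
    attach up to ``n_neighbors`` following positions, departures the
    preceding ones (the slow state moves little between frames, so the
    neighbors share the event's location).
    """
    by_key = {(t.cell_id, t.track_id): t for t in tracks}
    events: list[TransitionEvent] = []
    n_cand = 0
    n_filtered = 0
    for p in state_paths:
        t = by_key[(p.cell_id, p.track_id)]
        s = p.states
        n_pos = len(s)
        for i in range(1, n_pos):
            if s[i] == slow_state_id and s[i - 1] != slow_state_id:
                kind, pos_idx = "binding", i
                neigh = list(range(i + 1, min(i + 1 + n_neighbors, n_pos)))
            elif s[i] != slow_state_id and s[i - 1] == slow_state_id:
                kind, pos_idx = "release", i - 1
                neigh = list(range(max(i - 1 - n_neighbors, 0), i - 1))
            else:
                continue
            n_cand += 1
            steps_before = pos_idx
            steps_after = (n_pos - 1) - pos_idx
            if steps_before < min_segments or steps_after < min_segments:
                n_filtered += 1
                continue
            idx = [pos_idx] + neigh
            events.append(
                TransitionEvent(
                    kind=kind,
                    cell_id=t.cell_id,
                    track_id=t.track_id,
                    frame=int(t.frames[pos_idx]),
                    positions=t.positions[idx].copy(),
                )
            )
    report = {"n_candidates": n_cand, "n_filtered_out": n_filtered,
              "n_binding": sum(e.kind == "binding" for e in events),
              "n_release": sum(e.kind == "release" for e in events)}
    return events, report


def event_positions_normalized(
    events: Sequence[TransitionEvent],
    geom: CellGeometry = CellGeometry(),
    poses: dict | None = None,
) -> NormalizedPosition:
    """Pool event + neighbor positions (equal weight) in normalized
    coordinates; per-cell poses map lab to cell frames (identity default)."""
    from .geometry import CellPose, normalize_position

    xs, rs = [], []
    for e in events:
        pose = (poses or {}).get(e.cell_id, CellPose())
        norm = normalize_position(e.positions, pose=pose, geom=geom)
        xs.append(norm.x_long)
        rs.append(norm.r_short)
    if not xs:
        return NormalizedPosition(x_long=np.empty(0), r_short=np.empty(0))
    return NormalizedPosition(x_long=np.concatenate(xs), r_short=np.concatenate(rs))


def event_spatial_stats(
    events: Sequence[TransitionEvent],
    cytosol_ref: RadialProfile,
    membrane_ref: MembraneReference,
    geom: CellGeometry = CellGeometry(),
    poses: dict | None = None,
    n_b: int | None = None,
    margin: float = POLE_MARGIN_DEFAULT,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, Decomposition]:
    """Membrane fraction of binding and of release events.

    Event and neighbor positions are pooled into radial histograms per kind
    and each decomposed against the references.
    """
    import warnings

    out: dict[str, Decomposition] = {}
    n_b = n_b if n_b is not None else len(cytosol_ref.density)
    r_max = float(cytosol_ref.bin_edges[-1])  # match the references' bins
    for kind in ("binding", "release"):
        ev = [e for e in events if e.kind == kind]
        if len(ev) == 0:
            continue
        if len(ev) < 50:
            warnings.warn(f"only {len(ev)} {kind} events; fractions will be noisy")
        pos = event_positions_normalized(ev, geom=geom, poses=poses)
        prof = radial_histogram(pos, n_b=n_b, margin=margin, r_max=r_max)
        out[kind] = decompose_profile(
            prof, cytosol_ref, membrane_ref, n_boot=n_boot, seed=seed
        )
    return out
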