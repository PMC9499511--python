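"""Multi-state diffusion hidden Markov model over trajectory displacements.

Hidden states are diffusion coefficients; the emission for state k at step i
is an isotropic 2D Gaussian displacement with per-axis variance

    v_{k,i} = 2 D_k dt_i (1 - t_E / (3 dt_i)) + sigma_i^2 + sigma_{i+1}^2

where dt_i is the frame interval (or twice it across a recorded gap), t_E
the stroboscopic exposure (motion-blur correction), and sigma the
per-localization uncertainties.  Gap steps use the squared transition matrix.
Fitting is EM (Baum-Welch) with multiple restarts; the likelihood is
asserted to ascend monotonically.

Fitted models are coarse-grained into slow / intermediate / fast groups by
diffusion-coefficient thresholds (defaults 0.8 and 3 µm²/s), aggregating
occupancies and transition probabilities as occupancy-weighted averages;
mean dwell times follow from the coarse transition-matrix diagonal as
dwell = frame_dt / (1 - A_kk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .tracks import Track, total_steps

COARSE_THRESHOLDS = (0.8, 3.0)


@dataclass
class HMMModel:
    K: int
    D: np.ndarray  # per-state diffusion coefficient, µm²/s
    pi: np.ndarray  # stationary occupancy (mean posterior over all steps)
    A: np.ndarray  # per-frame transition probability matrix
    frame_dt: float
    exposure: float
    log_likelihood: float
    startprob: np.ndarray | None = None
    n_steps: int = 0
    ll_history: list | None = None  # EM log-likelihood per iteration

    def __post_init__(self) -> None:
        assert np.allclose(self.A.sum(axis=1), 1.0, atol=1e-9)
        assert abs(self.pi.sum() - 1.0) < 1e-9
        assert np.all(self.D >= 0)

    def stationary_of_A(self) -> np.ndarray:
        """Stationary vector of A (for the post-fit stationarity check)."""
        w, v = np.linalg.eig(self.A.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        return p / p.sum()


@dataclass
class CoarseModel:
    group_map: np.ndarray  # fine state -> coarse group index
    D_coarse: np.ndarray
    pi_coarse: np.ndarray
    A_coarse: np.ndarray
    dwell: np.ndarray
    frame_dt: float
    exposure: float = 0.0
    thresholds: tuple = COARSE_THRESHOLDS

    @property
    def n_groups(self) -> int:
        return len(self.pi_coarse)

    @property
    def empty_groups(self) -> np.ndarray:
        return self.pi_coarse <= 0.0

    def as_hmm(self) -> HMMModel:
        """View the coarse model as an HMM (for decoding on coarse states)."""
        keep = ~self.empty_groups
        D = np.where(np.isnan(self.D_coarse), 0.0, self.D_coarse)[keep]
        pi = self.pi_coarse[keep] / self.pi_coarse[keep].sum()
        A = self.A_coarse[np.ix_(keep, keep)]
        A = A / A.sum(axis=1, keepdims=True)
        return HMMModel(
            K=int(keep.sum()), D=D, pi=pi, A=A, frame_dt=self.frame_dt,
            exposure=self.exposure, log_likelihood=np.nan, startprob=pi.copy(),
        )


@dataclass
class StatePath:
    """Decoded per-position states for one track."""

    track_id: int
    cell_id: int
    states: np.ndarray  # per-position Viterbi state (coarse index)
    posteriors: np.ndarray  # (n_positions, K) per-position state posteriors
    ambiguous: np.ndarray  # True where max posterior <= threshold

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------


class _Packed:
    """Track steps padded into (n_tracks, T) arrays for batch EM.

    Tracks are sorted by descending step count so that at time index t only
    a prefix of rows is active; recursions slice that prefix, keeping the
    work proportional to the true number of steps rather than n * max_len.
    """

    def __init__(self, tracks: Sequence[Track], exposure: float):
        order = np.argsort([-t.n_steps for t in tracks], kind="stable")
        tracks = [tracks[i] for i in order]
        self.order = order
        lengths = np.array([t.n_steps for t in tracks])
        n, T = len(tracks), int(lengths.max())
        self.lengths = lengths
        #: n_active[t] = number of tracks with a step at time index t
        self.n_active = np.searchsorted(-lengths, -(np.arange(T) + 1), side="right")
        self.disp2 = np.zeros((n, T))
        self.locvar = np.zeros((n, T))
        self.dtfac = np.ones((n, T), dtype=int)
        self.mask = np.zeros((n, T), dtype=bool)
        self.frame_dt = tracks[0].frame_dt
        self.exposure = exposure
        for i, t in enumerate(tracks):
            m = t.n_steps
            d = t.displacements
            self.disp2[i, :m] = d[:, 0] ** 2 + d[:, 1] ** 2
            self.locvar[i, :m] = t.step_loc_var
            self.dtfac[i, :m] = t.dt_factors
            self.mask[i, :m] = True
        self.has_gaps = bool((self.dtfac[self.mask] == 2).any())
        # per-step diffusive variance coefficient: v = coefD * D + locvar
        dt_i = self.dtfac * self.frame_dt
        self.coefD = 2.0 * dt_i * (1.0 - exposure / (3.0 * dt_i))
        self.n_total = int(lengths.sum())
        # flat views of the valid steps (row-major over the mask)
        self.rows, self.cols = np.nonzero(self.mask)
        self.coefD_flat = self.coefD[self.mask]
        self.locvar_flat = self.locvar[self.mask]
        self.disp2_flat = self.disp2[self.mask]

    def log_emission(self, D: np.ndarray) -> np.ndarray:
        """(n, T, K) log emission densities (2D isotropic Gaussian)."""
        v = self.coefD[..., None] * D[None, None, :] + self.locvar[..., None]
        v = np.maximum(v, 1e-12)
        return -np.log(2.0 * np.pi * v) - self.disp2[..., None] / (2.0 * v)

    def emission_scaled(self, D: np.ndarray):
        """Padded per-step emissions normalized to max 1 per step, plus the
        total log of the per-step scale factors (for the log-likelihood).

        Emissions are evaluated only on the valid (flat) steps and scattered
        into the padded array; padding stays at 1 so it never perturbs the
        recursions.
        """
        v = np.maximum(
            self.coefD_flat[:, None] * D[None, :] + self.locvar_flat[:, None], 1e-12
        )
        logB = -np.log(2.0 * np.pi * v) - self.disp2_flat[:, None] / (2.0 * v)
        shift = logB.max(axis=1)
        Bf = np.exp(logB - shift[:, None])
        n, T = self.mask.shape
        B = np.ones((n, T, len(D)))
        B[self.rows, self.cols] = Bf
        return B, float(shift.sum())


def _forward_backward(pack: _Packed, D, A, startprob):
    """Scaled forward-backward over all tracks at once.

    Returns log-likelihood, per-step posteriors gamma (n,T,K), expected
    per-frame transition counts accumulated over all single and decomposed
    gap steps, and the initial-state posteriors.
    """
    n, T = pack.mask.shape
    K = len(D)
    B, log_shift_sum = pack.emission_scaled(D)
    A2 = A @ A
    alpha = np.zeros((n, T, K))
    c = np.ones((n, T))
    a = startprob[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0][:, None]
    for t in range(1, T):
        na = pack.n_active[t]
        prev = alpha[:na, t - 1]
        if pack.has_gaps:
            gap = pack.dtfac[:na, t - 1] == 2
            a = np.where(gap[:, None], prev @ A2, prev @ A) * B[:na, t, :]
        else:
            a = (prev @ A) * B[:na, t, :]
        s = a.sum(axis=1)
        c[:na, t] = s
        alpha[:na, t] = a / s[:, None]
    loglik = float(np.sum(np.log(c[pack.mask]))) + log_shift_sum

    beta = np.zeros((n, T, K))
    last = pack.lengths - 1
    beta[np.arange(n), last] = 1.0
    # transition counts: xi1 over single-frame steps, xi2 over gap (A^2) steps
    xi1 = np.zeros((K, K))
    xi2 = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        na = pack.n_active[t + 1]
        if na == 0:
            continue
        nb = B[:na, t + 1, :] * beta[:na, t + 1, :] / c[:na, t + 1][:, None]
        al = alpha[:na, t]
        if pack.has_gaps:
            gap = pack.dtfac[:na, t] == 2
            if gap.any():
                xi2 += (al[gap].T @ nb[gap]) * A2
                xi1 += (al[~gap].T @ nb[~gap]) * A
                beta[:na, t] = np.where(gap[:, None], nb @ A2.T, nb @ A.T)
            else:
                xi1 += (al.T @ nb) * A
                beta[:na, t] = nb @ A.T
        else:
            xi1 += (al.T @ nb) * A
            beta[:na, t] = nb @ A.T
        ended = pack.mask[:, t] & ~pack.mask[:, t + 1]
        if ended.any():
            beta[ended, t] = 1.0

    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
    gamma *= pack.mask[..., None]

    counts = xi1.copy()
    if xi2.any():
        # split two-frame counts: path k->m->l has weight A[k,m]A[m,l]/A2[k,l]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(A2 > 0, xi2 / np.maximum(A2, 1e-300), 0.0)
        path = A[:, :, None] * A[None, :, :]  # path[k,m,l] = A[k,m] A[m,l]
        counts += np.einsum("kl,kml->km", ratio, path)  # first hop k->m
        counts += np.einsum("kl,kml->ml", ratio, path)  # second hop m->l
    gamma0 = gamma[:, 0, :]
    return loglik, gamma, counts, gamma0


def _optimize_D(pack: _Packed, gamma_k: np.ndarray, d_max: float = 100.0) -> float:
    """M-step for one state's diffusion coefficient (no closed form when
    localization variances differ per step): bounded scalar optimization in
    log-space of the expected negative log-likelihood."""
    w = gamma_k[pack.rows, pack.cols]
    tot = w.sum()
    if tot <= 0:
        return 0.0
    a = pack.coefD_flat
    s = pack.locvar_flat
    q = pack.disp2_flat

    def nll(logD: float) -> float:
        v = np.maximum(a * np.exp(logD) + s, 1e-12)
        return float(np.sum(w * (np.log(v) + q / (2.0 * v))))

    res = minimize_scalar(
        nll, bounds=(np.log(1e-7), np.log(d_max)), method="bounded",
        options={"xatol": 1e-7},
    )
    return float(np.exp(res.x))


def fit_hmm(
    tracks: Sequence[Track],
    K: int,
    frame_dt: float | None = None,
    exposure: float = 0.0,
    n_restarts: int = 5,
    seed: int | np.random.Generator = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
    init_D: Sequence[float] | None = None,
    init_A: np.ndarray | None = None,
    warn: bool = True,
) -> HMMModel:
    """Fit a K-state diffusion HMM by EM with random restarts.

    States are relabelled by ascending D in the returned model.  The EM
    log-likelihood is checked to be non-decreasing on every iteration.
    """
    if len(tracks) == 0:
        raise ValueError("no tracks")
    pack = _Packed(tracks, exposure)
    if frame_dt is not None and abs(frame_dt - pack.frame_dt) > 1e-12:
        pack = _Packed([_with_dt(t, frame_dt) for t in tracks], exposure)
    n_steps = pack.n_total
    if warn and n_steps < 10 * K * K:
        import warnings

        warnings.warn(
            f"only {n_steps} steps for a {K}-state model; estimates may be "
            "poorly constrained (~10 K^2 steps recommended)"
        )
    rng = np.random.default_rng(seed)
    base_D = (
        np.asarray(init_D, dtype=float)
        if init_D is not None
        else np.logspace(-3, 1, K)
    )
    # data-driven alternative start: quantiles of the per-step apparent D
    d_proxy = np.maximum(
        (pack.disp2_flat / 2.0 - pack.locvar_flat) / pack.coefD_flat, 1e-4
    )
    quant_D = np.quantile(d_proxy, np.linspace(0.15, 0.9, K))
    best: Optional[HMMModel] = None
    for r in range(max(n_restarts, 1)):
        if init_D is not None:
            D0 = base_D * (np.exp(rng.uniform(np.log(0.7), np.log(1.3), size=K))
                           if r > 0 else 1.0)
        elif r == 0:
            D0 = base_D.copy()
        elif r == 1:
            D0 = quant_D.copy()
        else:
            # diverse restarts: sorted log-uniform draws over the same range
            D0 = np.sort(np.exp(rng.uniform(np.log(1e-3), np.log(10.0), size=K)))
        if init_A is not None:
            A0 = np.asarray(init_A, dtype=float).copy()
        else:
            A0 = np.full((K, K), 0.05 / max(K - 1, 1))
            np.fill_diagonal(A0, 0.95)
        model = _em(pack, D0, A0, np.full(K, 1.0 / K), max_iter, tol)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    order = np.argsort(best.D)
    return HMMModel(
        K=best.K,
        D=best.D[order],
        pi=best.pi[order],
        A=best.A[np.ix_(order, order)],
        frame_dt=pack.frame_dt,
        exposure=exposure,
        log_likelihood=best.log_likelihood,
        startprob=best.startprob[order],
        n_steps=n_steps,
        ll_history=best.ll_history,
    )


def _with_dt(t: Track, frame_dt: float) -> Track:
    from dataclasses import replace as _replace

    return _replace(t, frame_dt=frame_dt)


def _em(pack: _Packed, D, A, startprob, max_iter, tol) -> HMMModel:
    D = np.asarray(D, dtype=float).copy()
    A = np.asarray(A, dtype=float).copy()
    startprob = np.asarray(startprob, dtype=float).copy()
    prev_ll = -np.inf
    gamma = None
    history: list[float] = []
    for it in range(max_iter):
        ll, gamma, counts, gamma0 = _forward_backward(pack, D, A, startprob)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood during EM")
        history.append(ll)
        # monotone ascent up to round-off
        assert ll >= prev_ll - 1e-6 * max(abs(prev_ll), 1.0), "EM likelihood decreased"
        converged = np.isfinite(prev_ll) and (ll - prev_ll) <= tol * abs(ll)
        prev_ll = ll
        if converged:
            break
        row = counts.sum(axis=1, keepdims=True)
        A = np.where(row > 0, counts / np.maximum(row, 1e-300), A)
        A = np.maximum(A, 1e-12)
        A /= A.sum(axis=1, keepdims=True)
        startprob = gamma0.mean(axis=0)
        startprob = np.maximum(startprob, 1e-12)
        startprob /= startprob.sum()
        for k in range(len(D)):
            D[k] = _optimize_D(pack, gamma[:, :, k])
    occ = gamma.sum(axis=(0, 1)) if gamma is not None else startprob
    occ = occ / occ.sum()
    return HMMModel(
        K=len(D), D=D, pi=occ, A=A, frame_dt=pack.frame_dt,
        exposure=pack.exposure, log_likelihood=prev_ll, startprob=startprob,
        ll_history=history,
    )


def sweep_models(
    tracks: Sequence[Track],
    K_range: Sequence[int] = range(3, 9),
    exposure: float = 0.0,
    n_restarts: int = 5,
    seed: int = 0,
    **kwargs,
) -> list[HMMModel]:
    """Fit one model per state count (default 3-8) for the coarse-graining
    report: across model sizes the fitted D values cluster into the slow /
    intermediate / fast groups."""
    rng = np.random.default_rng(seed)
    return [
        fit_hmm(
            tracks, K=k, exposure=exposure, n_restarts=n_restarts,
            seed=int(rng.integers(2**31)), **kwargs,
        )
        for k in K_range
    ]


def coarse_grain(
    model: HMMModel, thresholds: tuple[float, float] = COARSE_THRESHOLDS
) -> CoarseModel:
    """Merge fine states into groups by D thresholds (ties join the lower
    group); occupancies add, D and transition rows average with occupancy
    weights, and dwell times come off the coarse diagonal."""
    if not thresholds[0] < thresholds[1]:
        raise ValueError("thresholds must be strictly increasing")
    edges = np.array([-np.inf, *thresholds, np.inf])
    group = np.searchsorted(edges, model.D, side="left") - 1
    G = len(thresholds) + 1
    pi_c = np.zeros(G)
    D_c = np.full(G, np.nan)
    A_c = np.zeros((G, G))
    for g in range(G):
        sel = group == g
        pg = model.pi[sel].sum()
        pi_c[g] = pg
        if pg > 0:
            D_c[g] = float(model.pi[sel] @ model.D[sel] / pg)
            for h in range(G):
                A_c[g, h] = float(
                    model.pi[sel] @ model.A[np.ix_(sel, group == h)].sum(axis=1) / pg
                )
        else:
            A_c[g, g] = 1.0  # explicit empty-group marker (undefined D, nan)
    with np.errstate(divide="ignore"):
        dwell = np.where(
            A_c.diagonal() < 1.0,
            model.frame_dt / (1.0 - A_c.diagonal()),
            np.inf,
        )
    dwell = np.where(pi_c > 0, dwell, np.nan)
    return CoarseModel(
        group_map=group, D_coarse=D_c, pi_coarse=pi_c, A_coarse=A_c,
        dwell=dwell, frame_dt=model.frame_dt, exposure=model.exposure,
        thresholds=tuple(thresholds),
    )


def dwell_and_flux(coarse: CoarseModel) -> dict:
    """Mean dwell times and per-frame probability fluxes per coarse state.

    flux_in_k = sum_j pi_j A_jk (j != k); flux_out_k = pi_k (1 - A_kk).
    At stationarity the two agree — the self-consistency check on fitted
    models.
    """
    A, pi = coarse.A_coarse, coarse.pi_coarse
    out = pi * (1.0 - A.diagonal())
    inn = pi @ A - pi * A.diagonal()
    with np.errstate(divide="ignore", invalid="ignore"):
        balance = np.where(out > 0, inn / out, np.nan)
    return {
        "dwell_s": coarse.dwell,
        "flux_in": inn,
        "flux_out": out,
        "balance_ratio": balance,
    }


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def decode(
    tracks: Sequence[Track],
    model: CoarseModel | HMMModel,
    posterior_threshold: float = 0.95,
) -> list[StatePath]:
    """Viterbi paths and per-position posteriors on the (coarse) model.

    Step states/posteriors are mapped to positions by assigning each
    position the state of the step that starts there (the last position
    inherits the final step).  Positions whose maximum posterior does not
    exceed the threshold are flagged ambiguous and excluded from spatial
    occupancy analysis downstream.
    """
    hmm = model.as_hmm() if isinstance(model, CoarseModel) else model
    out = []
    for t in tracks:
        pack = _Packed([t], hmm.exposure)
        ll, gamma, _, _ = _forward_backward(pack, hmm.D, hmm.A, hmm.startprob)
        g = gamma[0, : t.n_steps]
        path = _viterbi_single(pack, hmm)
        pos_states = np.concatenate([path, path[-1:]])
        pos_post = np.vstack([g, g[-1:]])
        out.append(
            StatePath(
                track_id=t.track_id,
                cell_id=t.cell_id,
                states=pos_states,
                posteriors=pos_post,
                ambiguous=pos_post.max(axis=1) <= posterior_threshold,
            )
        )
    return out


def _viterbi_single(pack: _Packed, hmm: HMMModel) -> np.ndarray:
    logB = pack.log_emission(hmm.D)[0]
    m = int(pack.lengths[0])
    logA1 = np.log(np.maximum(hmm.A, 1e-300))
    logA2 = np.log(np.maximum(hmm.A @ hmm.A, 1e-300))
    delta = np.log(np.maximum(hmm.startprob, 1e-300)) + logB[0]
    back = np.zeros((m, hmm.K), dtype=int)
    for t in range(1, m):
        logA = logA2 if pack.dtfac[0, t - 1] == 2 else logA1
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(m, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(m - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# uncertainty
# ---------------------------------------------------------------------------


def bootstrap_uncertainty(
    tracks: Sequence[Track],
    K: int,
    n_boot: int = 500,
    seed: int = 0,
    exposure: float = 0.0,
    thresholds: tuple[float, float] = COARSE_THRESHOLDS,
    ci_level: float = 0.95,
    max_iter: int = 100,
    point_model: HMMModel | None = None,
) -> dict:
    """Cell-level bootstrap CIs for coarse occupancies, D and dwell times.

    Cells (the natural independence unit) are resampled with replacement
    and the model refitted warm-started from the point estimate.
    """
    cells: dict[int, list[Track]] = {}
    for t in tracks:
        cells.setdefault(t.cell_id, []).append(t)
    cell_ids = sorted(cells)
    if len(cell_ids) < 20 and len(tracks) < 100:
        import warnings

        warnings.warn("few cells/tracks for a meaningful bootstrap")
    rng = np.random.default_rng(seed)
    if point_model is None:
        point_model = fit_hmm(tracks, K=K, exposure=exposure, seed=int(rng.integers(2**31)))
    point_coarse = coarse_grain(point_model, thresholds)
    stats = {"pi_coarse": [], "D_coarse": [], "dwell": []}
    n_skipped = 0
    for b in range(n_boot):
        chosen = rng.choice(cell_ids, size=len(cell_ids), replace=True)
        sample = [t for c in chosen for t in cells[c]]
        if total_steps(sample) < 2 * K:
            n_skipped += 1
            continue
        try:
            m = fit_hmm(
                sample, K=K, exposure=exposure, n_restarts=1,
                seed=int(rng.integers(2**31)), max_iter=max_iter,
                init_D=point_model.D, init_A=point_model.A, warn=False,
            )
        except (FloatingPointError, AssertionError):
            n_skipped += 1
            continue
        c = coarse_grain(m, thresholds)
        stats["pi_coarse"].append(c.pi_coarse)
        stats["D_coarse"].append(c.D_coarse)
        stats["dwell"].append(c.dwell)
    q = np.array([(1 - ci_level) / 2, 1 - (1 - ci_level) / 2]) * 100
    result = {"n_skipped": n_skipped, "n_boot_effective": n_boot - n_skipped,
              "point": point_coarse}
    point_vals = {"pi_coarse": point_coarse.pi_coarse,
                  "D_coarse": point_coarse.D_coarse,
                  "dwell": point_coarse.dwell}
    for key, vals in stats.items():
        arr = np.array(vals, dtype=float)
        if len(arr) == 0:
            result[key + "_ci"] = None
            continue
        if n_boot <= 1:
            # a single resample carries no spread information: the interval
            # degenerates to the point estimate
            result[key + "_ci"] = np.vstack([point_vals[key], point_vals[key]])
        else:
            result[key + "_ci"] = np.nanpercentile(arr, q, axis=0)
        result[key + "_samples"] = arr
    return result
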