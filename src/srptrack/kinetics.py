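"""Closed-form dual-pathway kinetics of SRP-mediated ribosome targeting.

The model distinguishes two binding modes: SRP binds a translating ribosome
anywhere in the cytosol (fraction f_C of bindings) and delivers it to the
membrane by 3D diffusion, or binds a ribosome already at the membrane
(1 - f_C); release happens only at the membrane.  Given the total mean
ribosome-bound dwell tau_bound_total, the membrane fraction phi_M of the
bound-state occupancy, and f_C, steady-state occupancy apportionment gives

    tau_M = phi_M * tau_bound_total                 (membrane-bound time)
    tau_C = (1 - phi_M) * tau_bound_total / f_C     (3D membrane-search time)

since every bound molecule passes through the membrane sub-state but only
the cytosol-binding fraction passes through the search sub-state, so
f_C * tau_C + tau_M = tau_bound_total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DualPathwayParams:
    """Kinetic quantities of the dual-pathway targeting cycle (times in s)."""

    tau_free: float  # free-SRP dwell (search for a target ribosome)
    tau_bound_total: float  # mean ribosome-bound dwell (both pathways)
    phi_M: float  # membrane fraction of bound-state occupancy
    f_C: float  # fraction of bindings occurring in the cytosol
    tau_M: float  # membrane-bound time
    tau_C: float  # 3D membrane-search time of the cytosol-bound complex
    cycle_time: float  # tau_free + tau_bound per pathway-average

    def __post_init__(self) -> None:
        for name in ("tau_free", "tau_bound_total", "tau_M", "tau_C", "cycle_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("phi_M", "f_C"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(self.f_C * self.tau_C + self.tau_M - self.tau_bound_total) > 1e-9:
            raise ValueError("inconsistent dual-pathway times")


def dual_pathway(tau_bound_total: float, phi_M: float, f_C: float) -> tuple[float, float]:
    """Membrane-bound time and 3D search time from the bound dwell, its
    membrane occupancy fraction, and the cytosolic binding fraction."""
    if not 0.0 <= phi_M <= 1.0:
        raise ValueError("phi_M must be in [0, 1]")
    if f_C <= 0.0:
        if phi_M < 1.0:
            raise ValueError(
                "f_C = 0 with phi_M < 1 is inconsistent: cytosolic bound "
                "occupancy requires cytosolic bindings"
            )
        return phi_M * tau_bound_total, 0.0
    tau_M = phi_M * tau_bound_total
    tau_C = (1.0 - phi_M) * tau_bound_total / f_C
    return tau_M, tau_C


def build_params(
    tau_free: float, tau_bound_total: float, phi_M: float, f_C: float
) -> DualPathwayParams:
    tau_M, tau_C = dual_pathway(tau_bound_total, phi_M, f_C)
    return DualPathwayParams(
        tau_free=tau_free,
        tau_bound_total=tau_bound_total,
        phi_M=phi_M,
        f_C=f_C,
        tau_M=tau_M,
        tau_C=tau_C,
        cycle_time=cycle_time(tau_free, tau_bound_total),
    )


def cycle_time(tau_search: float, tau_bound: float) -> float:
    """Mean SRP cycling time: search plus bound dwell."""
    if tau_search < 0 or tau_bound < 0:
        raise ValueError("times must be >= 0")
    return tau_search + tau_bound


def sampling_time_bound(tau_search: float, n_nontarget: int) -> float:
    """Upper bound on the dwell per unproductively sampled ribosome if
    n_nontarget ribosomes must be probed within the search time."""
    if n_nontarget < 1:
        raise ValueError("n_nontarget must be >= 1")
    return tau_search / n_nontarget


def target_fraction(f_imp: float, f_window: float) -> float:
    """Fraction of elongating ribosomes that are current SRP targets:
    (fraction translating SRP-dependent membrane proteins) x (fraction of
    translation time inside the SRP-binding window)."""
    for v in (f_imp, f_window):
        if not 0.0 <= v <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    return f_imp * f_window


def elongation_during_binding(
    tau_bound: float, rate_lo: float, rate_hi: float
) -> tuple[float, float]:
    """Amino acids elongated during one targeting event, as a (lo, hi)
    range for the given elongation-rate range (aa/s)."""
    if rate_lo > rate_hi:
        raise ValueError("rate_lo must be <= rate_hi")
    return tau_bound * rate_lo, tau_bound * rate_hi


def required_cycle_time(
    imp_molecules_per_generation: float, srp_copies: float, generation_time: float
) -> float:
    """Cycle time each SRP must sustain if all inner-membrane proteins made
    per generation are SRP-targeted: each copy completes imp/srp cycles per
    generation time."""
    if srp_copies <= 0:
        raise ValueError("srp_copies must be positive")
    if imp_molecules_per_generation <= 0 or generation_time <= 0:
        raise ValueError("inputs must be positive")
    return generation_time * srp_copies / imp_molecules_per_generation


def simulate_dual_pathway(
    tau_C: float,
    tau_M: float,
    f_C: float,
    n_cycles: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Forward Monte-Carlo of the two-pathway renewal process.

    Each binding is cytosolic with probability f_C (exponential 3D search of
    mean tau_C, then exponential membrane dwell tau_M) or membrane-proximal
    (membrane dwell only).  Returns the mean bound dwell and the fraction of
    bound time spent at the membrane — the forward check that inverts
    :func:`dual_pathway`.
    """
    rng = np.random.default_rng(seed)
    cytosolic = rng.random(n_cycles) < f_C
    t_search = np.where(cytosolic, rng.exponential(tau_C, n_cycles), 0.0)
    t_mem = rng.exponential(tau_M, n_cycles) if tau_M > 0 else np.zeros(n_cycles)
    total = t_search + t_mem
    return {
        "mean_bound_dwell": float(total.mean()),
        "membrane_occupancy_fraction": float(t_mem.sum() / total.sum()),
        "cytosolic_binding_fraction": float(cytosolic.mean()),
    }
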