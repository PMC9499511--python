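"""Closed-form dual-pathway kinetics of the SRP targeting cycle.

From the measured total ribosome-bound dwell (~1 s), the membrane fraction
of the bound state (44%) and the fraction of bindings that occur in the
cytosol (75%), computes how the bound time splits into a 3D membrane
search and a membrane-bound phase, plus the derived cycle quantities, and
cross-checks the split with a forward Monte-Carlo of the two-pathway
renewal process.
"""

from srptrack.kinetics import (
    build_params,
    elongation_during_binding,
    sampling_time_bound,
    simulate_dual_pathway,
    target_fraction,
)

from srptrack.kinetics import cycle_time

p = build_params(tau_free=1.5, tau_bound_total=1.0, phi_M=0.44, f_C=0.75)
print(f"membrane-bound time tau_M : {p.tau_M*1e3:.0f} ms")
print(f"3D search time tau_C      : {p.tau_C*1e3:.0f} ms")
print(f"cycle time (1.5 s search + 1.0 s bound dwell)     : {p.cycle_time:.2f} s")
print(f"cycle time with the simulation-refined 0.75 s bound: "
      f"{cycle_time(1.5, 0.75):.2f} s")

sim = simulate_dual_pathway(p.tau_C, p.tau_M, p.f_C, n_cycles=200_000, seed=0)
print(f"forward-simulated bound dwell        : {sim['mean_bound_dwell']:.3f} s")
print(f"forward-simulated membrane occupancy : "
      f"{sim['membrane_occupancy_fraction']:.3f}")

print(f"\nsampling-time bound (99 non-targets in 1.5 s): "
      f"{sampling_time_bound(1.5, 99)*1e3:.1f} ms")
print(f"target-ribosome fraction (10% IMP x 10% window): "
      f"{target_fraction(0.10, 0.10)*100:.1f}%")
lo, hi = elongation_during_binding(0.75, 16, 17)
print(f"nascent-chain growth during one targeting event: "
      f"{round(lo)}-{round(hi)} aa")
# tau_M = 440 ms and tau_C ~ 747 ms; the simulation returning ~1.0 s mean
# bound dwell and ~0.44 membrane occupancy confirms the closed form.
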