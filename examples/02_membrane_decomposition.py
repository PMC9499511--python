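"""Decompose a radial position profile into membrane + cytosol components.

Builds a synthetic position set in which 44% of the molecules sit in the
membrane shell (with the measured z and x-y localization jitters) and the
rest are uniform in the cytosol, projects it onto the short cell axis, and
recovers the membrane-bound fraction against the theoretical cytosol
profile and a synthetic membrane-marker reference.
"""

from srptrack.geometry import CellGeometry
from srptrack.spatial import (
    EXTENDED_R_MAX,
    decompose_profile,
    extended_cytosol_profile,
    extended_histogram,
    sample_two_component_positions,
    synthetic_membrane_reference,
)

TRUE_MEMBRANE_FRACTION = 0.44

geom = CellGeometry()
positions = sample_two_component_positions(10_000, TRUE_MEMBRANE_FRACTION,
                                           geom, rng=1)
profile = extended_histogram(positions)
cytosol = extended_cytosol_profile(geom)
membrane = synthetic_membrane_reference(seed=2, r_max=EXTENDED_R_MAX)

dec = decompose_profile(profile, cytosol, membrane, n_boot=300, seed=3)
print(f"true membrane fraction : {TRUE_MEMBRANE_FRACTION:.2f}")
print(f"recovered              : {dec.membrane_fraction:.3f}")
print(f"95% bootstrap CI       : ({dec.ci[0]:.3f}, {dec.ci[1]:.3f})")
print(f"residual rms           : {dec.residual_rms:.4f}")
# The recovered fraction should sit within a couple of percentage points of
# 0.44 with a CI width of ~0.03-0.05 at 10,000 positions.
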