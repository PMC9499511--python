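"""Fit the diffusion-state HMM to synthetic wild-type switching tracks.

Generates ~40,000 displacement steps from the three-state chain
(ribosome-bound SRP at 0.05 µm²/s, free SRP at 1.7 µm²/s, free 4.5S RNA at
4.3 µm²/s; occupancies ~28/56/16%), fits a 3-state model, coarse-grains it
and prints the recovered occupancies, diffusion coefficients and dwell
times next to the generator's ground truth.
"""

import numpy as np

from srptrack import coarse_grain, dwell_and_flux, fit_hmm
from srptrack.simulate import markov_switching_tracks, wildtype_rate_matrix

TRUTH_D = (0.05, 1.7, 4.3)
TRUTH_OCC = (0.28, 0.56, 0.16)

tracks = markov_switching_tracks(
    TRUTH_D, rate_matrix=wildtype_rate_matrix(TRUTH_OCC, 1.0, 1.9),
    n_tracks=1500, mean_track_len=30, loc_error=0.03, seed=7,
)
print(f"{len(tracks)} tracks, {sum(t.n_steps for t in tracks)} steps")

model = fit_hmm(tracks, K=3, n_restarts=5, seed=0)
coarse = coarse_grain(model)
flux = dwell_and_flux(coarse)

print("\nstate  D_true  D_fit   occ_true  occ_fit  dwell_fit(s)")
for k in range(3):
    print(f"{k}      {TRUTH_D[k]:<7} {model.D[k]:<7.3f} {TRUTH_OCC[k]:<9}"
          f" {model.pi[k]:<8.3f} {coarse.dwell[k]:.2f}")
print("\nflux balance (in/out per state):", np.round(flux["balance_ratio"], 3))
# Occupancies within a few percent, D within ~10%, and the free-SRP dwell
# (state 1, ~1.9 s) within ~15% indicate the fit resolved all three states.
# Balance ratios near 1 show the fitted kinetics are self-consistent; the
# free-RNA state exchanges very rarely, so its tiny fluxes carry a noisy
# ratio even on a good fit.
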