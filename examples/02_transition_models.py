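"""Ladder vs attractor transition models.

The hidden migration rate at each locus follows a continuous-time chain
on a discrete rate grid; this script prints the two infinitesimal
generators and their stationary laws.
"""

import numpy as np

from locusmix import rate_matrix, transition_matrix
from locusmix.hmm import stationary_distribution

J = 5
ladder = rate_matrix(J, "ladder")
attractor = rate_matrix(J, "attractor", phi=0.2, zeta=0.6, a=1)

print("ladder generator (nearest-neighbour moves at unit rate):")
print(ladder)
print("stationary law:", np.round(stationary_distribution(ladder), 3))
print()
print("attractor generator (a=1: background rate; drift toward it at "
      "1+zeta, away at 1-zeta, leave it at phi):")
print(attractor)
print("stationary law:", np.round(stationary_distribution(attractor), 3))
print()
P = transition_matrix(ladder, kappa=1.0, delta=0.5)
print("ladder transition over distance delta=0.5 (kappa=1):")
print(np.round(P, 4))
print()
print("The attractor's stationary mass peaks at the background state — "
      "loci revert there between introgression peaks, which is what "
      "makes excess/dearth calls relative to the background meaningful.")
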