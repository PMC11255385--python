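"""Drift covariance of an admixture graph.

Builds a two-population graph with one migration edge and shows how the
expected covariance of arcsine-transformed allele frequencies responds
to the migration rate.
"""

import numpy as np

from locusmix import drift_covariance, parse_graph

graph = parse_graph("""
ROOT R
BRANCH R s 0.02
BRANCH s P1 0.01
BRANCH R t 0.015
BRANCH t P2 0.005
MIG m1 s t            # migration from the pop1 lineage into the pop2 lineage
LEAF P1 pop1
LEAF P2 pop2
""")

print(f"graph: {graph.M} populations, {graph.K} branches, "
      f"{graph.I} migration edge(s)\n")
for w in (0.0, 0.3, 1.0):
    W = drift_covariance(graph, graph.branch_lengths(), [w])
    print(f"w = {w:.1f}:  W =")
    print(np.round(W, 5))
    print()

print("At w=0 the covariance is the plain tree (diagonal here: the two "
      "populations share no drift).  Opening the edge moves pop2's "
      "lineage through the pop1 side: the off-diagonal term w*c(R->s) "
      "appears and pop2's own variance re-weights by (1-w)^2 / w^2.")
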