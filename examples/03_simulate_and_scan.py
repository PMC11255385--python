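"""Simulate a genome scan and recover locus-specific migration rates.

Four populations, one migration edge, a peak-block migration track;
fits the HMM and compares the posterior mean rates with the truth.
Takes about half a minute.
"""

import warnings

import numpy as np

from locusmix import FitConfig, fit
from locusmix.simulate import (
    evaluate_detection,
    four_population_graph,
    simulate_dataset,
    simulate_track,
)

warnings.filterwarnings("ignore")

graph = four_population_graph("tip")
track = simulate_track(1500, "peaks", peak_width=50, background=0.1, peak=0.4)
dataset, truth = simulate_dataset(graph, graph.branch_lengths(), track,
                                  mu=-0.5, sigma2=0.3, N=100, seed=42)
print(f"simulated {dataset.L} loci x {dataset.M} populations "
      f"(N=100 alleles each; background rate 0.1, peaks at 0.4)")

config = FitConfig(restarts=50, grid_size=11, sigma_clusters=5,
                   max_iter=120, max_components=2, seed=42)
model, summary = fit(dataset, graph, config)

keep = ~(np.all(dataset.n == 0, 1) | np.all(dataset.n == dataset.N, 1))
w_true = track.rates[keep]
labels = track.labels[keep]
mae = np.abs(summary.mean_rate[:, 0] - w_true).mean()
sel = labels != 1
auc = evaluate_detection(summary.mean_rate[sel, 0], labels[sel] == 2)

print(f"fitted transition model: {model.variant}"
      + (f" (attractor at grid index {model.attractor[0]})"
         if model.attractor is not None else ""))
print(f"log-likelihood: {model.loglik:.1f}")
print(f"posterior-mean rate MAE vs truth: {mae:.3f}")
print(f"AUC, peak vs background loci:     {auc:.3f}")
print()
print("MAE ~< 0.1 means the per-locus posterior mean tracks the simulated "
      "track closely; AUC near 1 means elevated-migration regions rank "
      "above background, i.e. the scan finds the introgression peaks.")
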