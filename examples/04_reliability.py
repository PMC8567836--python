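"""Reproducibility of similarity networks.

Three checks: (1) split-half consistency of the mean network, (2)
robustness to rebuilding networks from 20 of the 25 marker features, and
(3) edge-wise test-retest ICC on a multi-session cohort with a known
planted variance ratio.
"""

import numpy as np

from r2sn import (CohortSpec, build_r2sn, edge_icc, feature_subset_robustness,
                  make_cohort, minmax_normalize, splithalf_consistency)
from r2sn.synthetic import make_phantom_cohort_tables

tables = make_phantom_cohort_tables(12, seed=5)
nets = [build_r2sn(minmax_normalize(t)) for t in tables]

r_split = splithalf_consistency(nets, n_iter=200, seed=1)
print(f"split-half r over 200 iterations: mean {r_split.mean():.4f}, "
      f"min {r_split.min():.4f}")

r_sub = feature_subset_robustness(tables, k=20, n_iter=200, seed=2)
print(f"20-of-25 feature subset r: mean {r_sub.mean():.4f}, "
      f"min {r_sub.min():.4f}")

spec = CohortSpec(n_subjects=50, n_sessions=4, n_regions=20, n_modules=4,
                  sigma_b=0.08, sigma_w=0.08, seed=3)
stack, truth = make_cohort(spec)
icc = edge_icc(stack, variant="single")
print(f"planted variance ratio {truth['implied_icc']:.2f}; "
      f"mean recovered single-measures ICC {np.nanmean(icc):.3f}")
print("High split-half and subset r values mean the mean network is stable "
      "to cohort composition and to the exact marker set; ICC recovery "
      "validates the one-way ANOVA estimator.")
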