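"""Extract per-region radiomics features from a textured phantom.

Builds a 90-region labeled phantom volume, runs the 47-feature engine and
prints a few entries. Each row of the resulting table is one region's
radiomics profile: intensity statistics plus co-occurrence and run-length
texture descriptors averaged over the 13 spatial directions.
"""

from r2sn import (ExtractionParams, PhantomSpec, extract_region_features,
                  full_catalog, make_phantom)

vol, truth = make_phantom(PhantomSpec(seed=7))
table = extract_region_features(vol, full_catalog(),
                                ExtractionParams(n_levels=32))

print(f"feature matrix: {table.n_regions} regions x {table.n_features} features")
for fid in ("firstorder_mean", "firstorder_entropy", "glcm_contrast",
            "glrlm_sre"):
    col = table.feature_ids.index(fid)
    print(f"  {fid:25s} region 1: {table.matrix[0, col]:8.3f}   "
          f"region 45: {table.matrix[44, col]:8.3f}")
print("Regions in different texture classes separate on entropy and "
      "contrast; same-class regions have similar profiles.")
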