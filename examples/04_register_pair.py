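"""Coarse-to-fine registration of one held-out pair, with ground truth.

Pipeline: density equalization, curvature on both clouds, 25 FPS regions of
the pre-operative cloud, learned matching + RANSAC per region, oracle region
selection (minimum rotation error against the supplied ground truth), then
fine refinement. Errors are the geodesic rotation error e_r (degrees) and
translation error e_t (mm) of the estimated transform against ground truth.

Run 03_train_matcher.py first to produce matcher.npz.
"""

import spinereg as sr

model = sr.load_model("matcher.npz")
pair = sr.make_pair(sr.PairSpec(seed=520))
print(f"registering: {len(pair.intraop)}-point intra-op patch onto "
      f"{len(pair.preop)}-point pre-op cloud "
      f"(overlap {pair.achieved_overlap:.2%})")

cfg = sr.PipelineConfig(mode="oracle")
result = sr.register(pair.preop, pair.intraop, model, cfg,
                     t_gt=pair.ground_truth)
if result.failed:
    print("registration failed (no region produced a usable pose)")
else:
    c, f = result.coarse_error, result.fine_error
    print(f"selected region {result.selected_region_index}")
    print(f"coarse: e_r {c.rotation_error_deg:6.2f} deg   "
          f"e_t {c.translation_error_mm:6.2f} mm")
    print(f"fine  : e_r {f.rotation_error_deg:6.2f} deg   "
          f"e_t {f.translation_error_mm:6.2f} mm")
    print({k: round(v, 2) for k, v in result.timings.items()})
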