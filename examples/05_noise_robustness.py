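"""Noise-robustness sweep: re-noise the intra-operative clouds at several
Gaussian levels and compare mean coarse errors.

Registration failures (e_r > 60 degrees or e_t > 60 mm) are excluded from
the means, mirroring the reporting convention of comparison tables in this
problem domain. Run 03_train_matcher.py first.
"""

import spinereg as sr

model = sr.load_model("matcher.npz")
pairs = [sr.make_pair(sr.PairSpec(seed=700 + i)) for i in range(3)]
sigmas = [0.0, 0.5, 1.0]

reports = sr.noise_sweep(pairs, sigmas, model,
                         sr.PipelineConfig(mode="oracle"), seed=5)
print("sigma (mm)   mean coarse e_r (deg)   mean coarse e_t (mm)   failed")
for s in sigmas:
    c = reports[s].summary["coarse"]
    print(f"  {s:4.2f}        {c['mean_e_r']:8.2f}              "
          f"{c['mean_e_t']:8.2f}          {c['n_failed']}/{c['n']}")
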