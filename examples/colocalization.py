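"""Compare two spot-detection runs with directional colocalization.

Simulates a paired 3-D spot field at the scale of a dual-method experiment
(380 vs 345 spots per sample, 260 true shared positions, 100 nm
localization jitter), then computes the fraction of each method's spots
lying within 750 nm of a spot from the other method.
"""

import tempfile
from pathlib import Path

from hcrkit import FixtureSpec, colocalize, load_spots, make_spot_fields, summarize_samples

workdir = Path(tempfile.mkdtemp(prefix="hcrkit_example_"))

spec = FixtureSpec(seed=1)  # 260 shared + 120 HCR-only + 85 smFISH-only
csv_a, csv_b, truth = make_spot_fields(spec, workdir)

hcr = load_spots(csv_a, label="hcr")
smfish = load_spots(csv_b, label="smfish")
res = colocalize(hcr, smfish, radius_nm=750.0)  # strict '<' at the boundary

print(f"spots: {res.n_a} (hcr), {res.n_b} (smfish)")
print(f"planted shared positions: {truth['n_shared']}")
print(f"% hcr spots with a smfish spot within 750 nm:  "
      f"{100 * res.frac_a_near_b:.1f}  (planted: "
      f"{100 * truth['expected_frac_a_near_b']:.1f})")
print(f"% smfish spots with an hcr spot within 750 nm: "
      f"{100 * res.frac_b_near_a:.1f}  (planted: "
      f"{100 * truth['expected_frac_b_near_a']:.1f})")
print()
print(summarize_samples([res]).to_string())
print("\nThe two directions differ because each method also detects spots")
print("the other misses; matching is neighbor-existence, not one-to-one.")
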