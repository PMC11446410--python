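"""The two exon-junction FASTA conventions give identical designs.

A probe spanning a splice junction would fail to detect the mature mRNA, so
junctions must be masked. Either write the gene as one record with 'N'
between exons, or one record per exon; both normalize to the same
junction-masked target, and every window touching a junction is rejected
with reason CONTAINS_N.
"""

import tempfile
from pathlib import Path

from hcrkit import DesignConfig, FixtureSpec, enumerate_candidates, make_target, read_target
from hcrkit.design import CONTAINS_N

workdir = Path(tempfile.mkdtemp(prefix="hcrkit_example_"))
single_fa, multi_fa, _ = make_target(FixtureSpec(seed=2), workdir)

t_single = read_target(single_fa, "single_entry_N")
t_multi = read_target(multi_fa, "multi_entry_exons")
print(f"single-entry file : {single_fa.name}")
print(f"multi-entry file  : {multi_fa.name}")
print(f"equivalent targets: {t_single.equivalent_to(t_multi)}")
print(f"junctions (1-based): {[j + 1 for j in t_single.junction_positions]}")

cands = enumerate_candidates(t_single, DesignConfig())
masked = [c for c in cands if CONTAINS_N in c.fail_reasons]
print(f"candidate windows: {len(cands)}, junction-spanning (rejected): "
      f"{len(masked)}")
print("Every window overlapping a masked junction carries CONTAINS_N and")
print("can never be selected, so no probe spans an exon-exon boundary.")
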