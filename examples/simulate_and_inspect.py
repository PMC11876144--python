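"""Simulate KASP plates for several rubric classes and inspect their geometry.

Generates one plate per score class, prints the geometric descriptors that
realize the rubric's verbal clauses, and shows that cluster separation decays
and NTC specificity appears exactly where the rubric says they should.
"""

import numpy as np

from talsrx import default_spec, morphology_descriptors, sample_plate

rng = np.random.default_rng(0)

print(f"{'score':>5} {'separation':>10} {'ntc_index':>9} {'|het dev|':>9}  notes")
for score in range(100, -10, -10):
    plate = sample_plate(default_spec(score), rng)
    rep = morphology_descriptors(plate)
    dev = rep.het_midpoint_deviation
    dev_mag = float(np.hypot(*dev)) if dev else float("nan")
    note = "NTC amplified!" if rep.ntc_specific else ""
    print(
        f"{score:>5} {rep.separation_index:>10.2f} "
        f"{rep.ntc_specificity_index:>9.2f} {dev_mag:>9.3f}  {note}"
    )

print(
    "\nseparation_index = min centroid distance / mean cluster spread: high for"
    "\nclean plates, near 1 when clusters merge.  ntc_index > 0.5 flags control"
    "\nwells that amplified (the score-10 failure mode).  |het dev| is how far"
    "\nthe heterozygote cloud sits from the homozygote midpoint."
)
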