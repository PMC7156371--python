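"""Segment chewing cycles and detect the four gape-cycle phases.

The FC/SC and SO/FO boundaries are located from jaw acceleration (the
second derivative of gape); detected frames are compared with the
generator's true junctions.
"""

import numpy as np

import chewgear as cg
from chewgear import cycles as cyc
from chewgear import kinematics as kin

rec = cg.build_recording(cg.SyntheticScenario(n_cycles=5, noise_sigma_mm=0.15, seed=1))
ds = kin.filter_dataset(kin.fill_gaps(rec.dataset), 30, 4)
ds = kin.fix_cranial_frame(ds, rec.config.cranial, 0)
gape = kin.gape_distance(ds, "mand_ant", frame=rec.config.frame)

prom = 0.2 * (gape.values.max() - gape.values.min())
cycles = cyc.extract_cycles(gape, min_prominence=prom)
truth = {t["start"]: t for t in rec.truth.transitions}

print(f"detected {len(cycles)} cycles "
      f"({cycles[0].duration_s * 1000:.0f} ms each at {gape.frame_rate:.0f} fps)")
print(f"{'cycle':>5} {'FC/SC':>7} {'min gape':>9} {'SO/FO':>7}   (frame error vs truth)")
for i, c in enumerate(cycles):
    t = min(truth.values(), key=lambda tt: abs(tt["start"] - c.start))
    print(f"{i:>5} {c.fc_sc:>7} {c.min_gape:>9} {c.so_fo:>7}   "
          f"({c.fc_sc - t['fc_sc']:+d}, {c.min_gape - t['min_gape']:+d}, {c.so_fo - t['so_fo']:+d})")
print()
print("Boundary errors of a frame or two (7-13 ms) are the noise floor of")
print("acceleration-based phase detection at 0.15 mm marker precision.")
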