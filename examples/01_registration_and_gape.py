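"""Register a jaw scene and measure gape distance.

Builds a short synthetic recording with whole-scene drift, fixes the cranial
reference frame by SVD registration, recovers the per-frame mandibular
transforms, and compares the measured gape distance with the generator's
prescribed trajectory.
"""

import numpy as np

import chewgear as cg
from chewgear import kinematics as kin

rec = cg.build_recording(
    cg.SyntheticScenario(n_cycles=3, noise_sigma_mm=0.15,
                         drift_translation_mm=0.5, drift_rotation_deg=0.5, seed=0)
)

ds = kin.filter_dataset(kin.fill_gaps(rec.dataset), cutoff_hz=30, order=4)
ds = kin.fix_cranial_frame(ds, rec.config.cranial, reference_frame_index=0)
transforms = kin.mandible_transforms(ds, rec.config.mandibular, 0)
gape = kin.gape_distance(ds, "mand_ant", frame=rec.config.frame)

resid = np.sqrt(np.mean((gape.values - rec.truth.gape) ** 2))
phi = np.degrees(max(T.rotation_angle() for T in transforms))

print(f"frames processed:        {ds.n_frames}")
print(f"occlusion frame:         {gape.occlusion_frame}")
print(f"max gape measured:       {gape.values.max():.2f} mm (prescribed {rec.truth.gape.max():.2f} mm)")
print(f"max jaw rotation:        {phi:.2f} deg")
print(f"gape RMS error vs truth: {resid:.3f} mm")
print()
print("The RMS error is at the scale of the 0.15 mm marker noise: the")
print("registration removed the scene drift without distorting jaw motion.")
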