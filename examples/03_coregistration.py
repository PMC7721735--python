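"""Co-register distorted reference sections back to the cuff frame.

MicroCT-like and histology-like cross-sections are rendered with tissue
shrinkage (anisotropic rescaling) and an arbitrary rotation, then brought
back into the circular, fiducial-at-12-o'clock frame; the recovered
fascicle centers are compared with the phantom ground truth.
"""

import numpy as np

from neureit.coregister import compare_coms, coregister, segmentation_from_reference
from neureit.phantom import make_phantom, render_reference_images
from neureit.recon import FascicleCoM

phantom = make_phantom(seed=7)
all_coms = []
for modality in ("microct", "histology"):
    ref = render_reference_images(phantom, modality=modality, seed=11)
    d = ref.distortion
    seg = segmentation_from_reference(ref, nerve_id="demo")
    spec, coms = coregister(seg)
    print(f"{modality}: applied scales ({d.scale_x:.2f}, {d.scale_y:.2f}), "
          f"rotation {d.rotation_deg:.1f}°; recovered rotation "
          f"{spec.rotation_deg:.1f}°, boundary residual {spec.residual_rms_um:.1f} µm")
    for c in coms:
        cx, cy = phantom.fascicle(c.label).center_xy_um()
        err = np.hypot(c.x_um - cx, c.y_um - cy)
        print(f"  {c.label:9s} CoM (R {c.r_um:5.0f} µm, θ {c.theta_deg:5.1f}°), "
              f"error vs truth {err:.1f} µm")
    all_coms.extend(coms)

# add the ground truth as a pseudo-technique and compare pairwise
for lab, (cx, cy) in phantom.com_table_um().items():
    r, th = np.hypot(cx, cy), np.degrees(np.arctan2(cx, cy)) % 360
    all_coms.append(FascicleCoM(x_um=cx, y_um=cy, r_um=r, theta_deg=th,
                                label=lab, technique="truth", nerve_id="demo"))
print(compare_coms(all_coms).to_string(index=False))
# Distances of a few µm (sub-pixel) show the rescaling + fiducial rotation
# recovers the cuff frame; in real tissue the residuals are dominated by
# fixation artifacts rather than the transform itself.
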