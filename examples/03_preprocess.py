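"""Condition the two modalities the way real whole-slide inputs are.

Stain side: illuminant normalization and Reinhard color transfer.
SC side: background masking, zero-defect inpainting and vessel-halo
correction.
"""

import numpy as np

from scstain import phantom as ph
from scstain.preprocess import clean_sc, normalize_ps, reinhard_transfer

# a slice rendered under a tinted illuminant, as a slide scanner might
tinted = ph.make_cortex_phantom(
    256, 256, seed=2,
    params=ph.PhantomParams(speckle_var=0.0, illuminant=(0.92, 0.85, 0.75)))
clean = normalize_ps(tinted.ps)
print("illuminant normalization:")
print(f"  channel means before {tinted.ps.mean(axis=(0, 1)).round(3)}")
print(f"  channel means after  {clean.mean(axis=(0, 1)).round(3)}")

# color transfer standardizes staining variation across sections
ref = ph.make_cortex_phantom(256, 256, seed=3,
                             params=ph.PhantomParams(speckle_var=0.0)).ps
dark = ph.make_cortex_phantom(
    256, 256, seed=2, params=ph.PhantomParams(speckle_var=0.0, ps_gamma=0.7)).ps
moved = reinhard_transfer(dark, ref)
print("\nReinhard transfer toward a reference section:")
print(f"  mean |channel difference to ref| before "
      f"{np.abs(dark.mean((0, 1)) - ref.mean((0, 1))).mean():.3f}, "
      f"after {np.abs(moved.mean((0, 1)) - ref.mean((0, 1))).mean():.3f}")

# SC cleanup: inject zero-valued fitting defects, then repair them
slc = ph.make_cortex_phantom(256, 256, seed=4)
x = slc.sc.copy()
rng = np.random.default_rng(0)
rows, cols = np.nonzero(slc.labels != 0)
pick = rng.choice(len(rows), 200, replace=False)
x[rows[pick], cols[pick]] = 0.0
repaired, masks = clean_sc(x, return_masks=True)
fixed = ((x == 0) & masks["foreground"] & (repaired > 0)).sum()
print(f"\nSC cleanup: {fixed} zero-valued defects inpainted by the local "
      f"median;")
print(f"{masks['combined'].sum()} vessel-edge/outlier pixels raised to the "
      f"local maximum.")
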