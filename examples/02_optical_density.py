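"""Optical density as the biophysical bridge between the modalities.

OD(Y) = -(1/3) sum_c log10(Y_c) of a stain image has the same contrast
as the SC map (high where myelin is dense), which is why pixel-aligned
OD/stain pairs can pseudo-supervise the SC-to-stain translator.
"""

import numpy as np

from scstain import phantom as ph
from scstain.biophys import hist_equalize, optical_density

slc = ph.make_cortex_phantom(256, 256, seed=1,
                             params=ph.PhantomParams(speckle_var=0.0))
od = optical_density(slc.ps).od
tissue = slc.labels != ph.BACKGROUND

print(f"OD range on tissue: [{od[tissue].min():.3f}, {od[tissue].max():.3f}]")
print(f"OD vs myelin correlation:  r = "
      f"{np.corrcoef(od[tissue], slc.myelin[tissue])[0, 1]:.2f}")
print(f"OD vs SC correlation:      r = "
      f"{np.corrcoef(od[tissue], slc.sc[tissue])[0, 1]:.2f}")

odq = hist_equalize(od)
xq = hist_equalize(slc.sc)
print(f"\nafter foreground histogram equalization both network inputs live "
      f"in [0,1]:")
print(f"  equalized OD mean {odq[tissue].mean():.2f}, "
      f"equalized SC mean {xq[tissue].mean():.2f}")
print("the shared contrast (both bright on white matter) is the premise of")
print("the pseudo-supervised auxiliary task.")
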