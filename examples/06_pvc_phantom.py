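"""Two-compartment partial-volume correction on a phantom.

A tissue box (value 3.0) in zero-valued CSF is blurred with a 6-mm PSF;
the correction divides by the blurred tissue fraction and restores the
interior value.
"""

import numpy as np

from synpet import PsfModel, pvc_two_compartment
from synpet.simulate import pvc_acceptance_phantom

img, mask, truth = pvc_acceptance_phantom(tissue_value=3.0, fwhm_mm=6.0)
print(f"observed tissue mean after blurring: {img[mask].mean():.3f} (truth {truth})")
out = pvc_two_compartment(img, mask, PsfModel.isotropic(6.0),
                          voxel_sizes=(2.0, 2.0, 2.0))
print(f"corrected tissue mean: {np.nanmean(out[mask]):.3f}")
c = 20
interior = out[c - 6:c + 6, c - 6:c + 6, c - 6:c + 6]
print(f"max interior error: {np.nanmax(np.abs(interior - truth)) / truth:.2%}")
print("-> blurring dilutes the boundary signal into CSF; dividing by the "
      "PSF-blurred tissue fraction undoes the dilution")
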