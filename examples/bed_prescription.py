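"""Biologically effective dose of an SBRT prostate re-irradiation schedule.

Converts a uniform 35 Gy / 7-fraction dose grid to BED with the
linear-quadratic model at the prostate alpha/beta of 1.5 Gy.
"""

import numpy as np

from dosiomics import DoseGrid, ImageVolume, Unit
from dosiomics.preprocess import to_bed

grid = ImageVolume(np.full((3, 3, 3), 35.0), spacing_mm=(1, 1, 1), unit=Unit.GY)
dose = DoseGrid(grid, n_fractions=7)
bed = to_bed(dose, alpha_beta_gy=1.5)

print(f"physical dose : {grid.values[0, 0, 0]:.1f} Gy in {dose.n_fractions} fractions")
print(f"BED (a/b=1.5) : {bed.values[0, 0, 0]:.1f} Gy")
# The BED rescales the fractionated schedule onto a common radiobiological
# scale: 35 Gy in 5 Gy fractions is equivalent to 151.7 Gy delivered in
# infinitesimal fractions for a tissue with alpha/beta = 1.5 Gy.
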