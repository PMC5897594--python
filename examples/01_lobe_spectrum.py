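"""Count the lobes of a star-shaped outline from its lobe spectrum.

Builds a six-armed superformula star, decomposes it, and prints the lobe
amplitude spectrum L_l. Classic elliptic Fourier analysis smears a
six-lobed shape over harmonics 5 and 7; the lobe-mode spectrum puts the
peak at 6, directly matching the visible protrusion count.
"""

import numpy as np

from locoefa import (
    STAR_PARAMS,
    efa_decompose,
    efa_power,
    loco_spectrum,
    resample_contour,
    superformula_shape,
)

star = superformula_shape(STAR_PARAMS[(6, "mid")])  # area-normalised
contour = resample_contour(star, 1000)
coef = efa_decompose(contour, 51)
spectrum = loco_spectrum(coef)
power = efa_power(coef)

print("l    L_l (lobe modes)   P_n (raw EFA harmonics)")
for l in range(1, 9):
    print(f"{l}    {spectrum.L[l - 1]:8.4f}          {power[l - 1]:8.4f}")
peak = spectrum.argmax_lobe()
print(f"\ndominant lobe mode (l >= 2): {peak}")
print("-> the lobe spectrum peaks at 6 (the true arm count), while raw")
print("   EFA splits the same signal between harmonics 5 and 7.")
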