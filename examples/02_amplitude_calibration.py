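"""Lobe amplitude is reported in units of the equivalent-circle radius.

A circle with radial modulation r = 1 + eps*cos(6 theta), area-normalised,
must return L_6 = eps: an L-value of 0.15 means the lobes protrude and
retract by 15% of the cell radius (peak-to-trough 15% of the diameter).
"""

from locoefa import canonicalise, cosine_lobed_circle, efa_decompose, loco_spectrum

for eps in (0.05, 0.10, 0.15, 0.20):
    shape = cosine_lobed_circle(eps, l=6)
    canon, scale = canonicalise(shape)
    coef = efa_decompose(canon, 51, scale=scale, spacing="uniform")
    L6 = loco_spectrum(coef).L[5]
    print(f"imposed eps = {eps:.2f}   recovered L_6 = {L6:.4f}")
print("\n-> the recovered amplitude tracks the imposed one; the small")
print("   deficit is the second-order correction from scaling area to pi.")
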