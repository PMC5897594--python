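# locoefa

Lobe-contribution elliptic Fourier analysis of two-dimensional cell
outlines, with an extended cellular Potts simulator for generating
confluent tissues of cells with specified lobed shapes.

## The problem

Complex cell shapes — the jigsaw-piece pavement cells of plant epidermis,
amnioserosa cells in insect embryos — defeat traditional descriptors
(aspect ratio, form factor) and landmark-based morphometrics. Classic
elliptic Fourier analysis (EFA) describes any closed outline as a sum of
harmonic ellipses, but its harmonics do not map onto visible features: a
six-lobed cell appears as a mixed contribution of harmonics five and
seven, the coefficient set is not unique, and amplitudes cannot be read
as lobe sizes.

This package implements the lobe-contribution reassignment that fixes
this. Each EFA harmonic ellipse is split into two counter-rotating
circles (rotors),

```
lambda+ e^{i phi+} = ((a_n + d_n) + i(c_n - b_n)) / 2
lambda- e^{i phi-} = ((a_n - d_n) + i(c_n + b_n)) / 2 ,
```

and rotors are regrouped by the radial frequency they actually draw on
the counter-clockwise base circle: the CCW rotor of harmonic *n* draws
*n − 1* bumps, the CW rotor draws *n + 1*. Lobe mode *l* therefore owns
the CCW rotor of harmonic *l + 1* and the CW rotor of harmonic *l − 1*,
with scalar amplitude

```
L_l = sqrt( r_ccw^2 + r_cw^2 + 2 r_ccw r_cw cos(phi_ccw + phi_cw - 2 zeta) ),
```

where *zeta* is the mode-1 reference phase after the starting point of
the traversal has been canonicalised. After scaling every cell to area
pi, `L_l` reads directly as the amplitude of *l*-fold lobes in units of
the equivalent-circle radius.

Derived per-cell metrics: the **XOR difference** (area mismatch between
the cell and its first-*N*-mode reconstruction on the source pixel
grid), the **marginal difference** (XOR drop per added mode — its peaks
count features), the **cumulative difference** `cd` (lobe richness), the
spectrum **entropy** (shape irregularity), and the natural **cut-off**
(first mode at which XOR reaches zero on the grid).

The `cpm` module implements a cellular Potts model whose Hamiltonian is
extended with lobe (−s·ν·cos nθ), elongation (−s·χ·cos 2α) and roundness
(+s·μ·sign(r−R)(r−R)²) forces per copy event, with target directions
re-anchored every 100 Monte Carlo steps — enough to grow cells with a
specified lobe count and watch what tissue packing does to them.

## Worked example

```python
from locoefa import (STAR_PARAMS, superformula_shape, resample_contour,
                     efa_decompose, loco_spectrum)

star = superformula_shape(STAR_PARAMS[(6, "mid")])   # six arms, area pi
coef = efa_decompose(resample_contour(star, 1000), 51)
spectrum = loco_spectrum(coef)
print(spectrum.argmax_lobe())        # -> 6
print(round(spectrum.L[5], 4))       # -> 0.2306
```

Running `python examples/01_lobe_spectrum.py` prints both spectra:

```
l    L_l (lobe modes)   P_n (raw EFA harmonics)
1      1.0323            1.4599
5      0.0000            0.2140
6      0.2306            0.0000
7      0.0000            0.1122
dominant lobe mode (l >= 2): 6
```

The lobe spectrum peaks at 6 — the true arm count — with amplitude 0.23
(arms protrude/retract by 23% of the cell radius), while raw EFA smears
the same signal over harmonics 5 and 7. The other scripts in `examples/`
demonstrate amplitude calibration (`L_6` tracks an imposed cosine
modulation: 0.05 → 0.0500, 0.15 → 0.1491), the complexity metrics, whole
label-image analysis, and the in-silico tissue-confinement experiment
(cells specified to be six-lobed reach `L_6 = 0.34` alone but a median
`L_6` ratio of 0.94 inside a packed 16-cell tissue).

From the shell:

```
loco shapes make --kind star --m 6 --out star6.csv
loco analyze star6.csv --out-prefix star6
loco shapes tissue --cells 20 --field 256 --out tissue.tif
loco analyze tissue.tif --out-prefix tissue
loco map tissue.tif tissue_cells.csv --metric L:6 --out l6_map.png
loco cpm run sim.cfg --out-prefix sim
```

`analyze` writes a wide per-cell table (`*_cells.csv`: `L1..L50`,
`argmax_md_mode`, `cd`, `entropy`, `cutoff`, border flag), a long-format
spectrum table, and a population summary that excludes border-clipped
cells by default.

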