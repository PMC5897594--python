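# Methods

## Contour handling

Cell regions are traced from integer label rasters by marching squares
at iso-level 0.5 on the zero-padded region mask, giving sub-pixel
vertices at pixel-edge midpoints (pixel centre (r, c) sits at x = c,
y = r). Each connected component of an ID yields one contour; regions
touching the image border are traced and flagged rather than dropped —
the pipeline keeps their records but the CLI's population summary
excludes them by default, since clipped outlines are artefacts of the
field of view, not of the cell.

Contours are resampled to 1000 vertices uniformly in arc length (enough
to resolve 50 modes with >10 samples per shortest wavelength), oriented
counter-clockwise, and scaled so the enclosed area is pi. With that
normalisation all amplitudes are fractions of the equivalent-circle
radius; the centroid is not moved, because translation is absorbed
entirely by the offset term of the Fourier decomposition. Canonicalising
twice is the identity (second scale = 1 to machine precision).
Self-intersecting input polygons are rejected.

## Elliptic Fourier decomposition

Coefficients are computed by the closed-form piecewise-linear integrals
for the polygon (not an FFT of the samples), so they are exact for the
polygonal contour and independent of how vertices align with the
harmonic phase. The default order is 51 harmonics, which feeds 50 lobe
modes.

**Traversal parameterisation.** Two conventions are supported.
`spacing="chord"` (the default, and the classic convention) traverses
the polygon at constant speed; it is the only general choice for
outlines traced from images, whose vertices carry no preferred
parameter. `spacing="uniform"` assigns one parameter unit per vertex;
for shapes sampled at equal polar angle — everything the synthetic
generators produce — this is the polar parameterisation. The two agree
in the small-amplitude limit but differ at second order in relative
lobe depth: for r(θ) = 1 + ε cos(lθ) the polar parameterisation returns
L_l = ε exactly (up to the O(ε²) area-normalisation correction, e.g.
0.1491 for ε = 0.15), whereas constant-speed traversal transfers part of
the modulation into overtones and returns ≈ 0.143 at ε = 0.15 (the
deficit grows like (lε)²). Amplitude semantics — "L = 0.15 means lobes
of 15% of the cell radius" — are therefore exact statements about the
polar parameterisation and first-order statements about the chord one.
The package analyses natively polar fixtures with `spacing="uniform"`
and raster-derived outlines with `spacing="chord"`; comparisons within
one pipeline are always made under a single convention.

## Rotor split and lobe-mode reassignment

Writing harmonic n as a complex signal, the 2×2 coefficient block is
equivalent to two counter-rotating circles: λ⁺e^{i(nωt+φ⁺)} (CCW) and
λ⁻e^{i(φ⁻−nωt)} (CW); both phases are starting angular positions
measured counter-clockwise from +x, which makes the split an exact,
invertible reparameterisation (round-trip at 1e−12).

Starting-point redundancy is removed by shifting the traversal parameter
so the dominant rotor of harmonic 1 (the base circle — always the CCW
one after orientation canonicalisation) starts at angle zero; φ⁺_n
advances by nωτ, φ⁻_n retards by the same, and the residual mode-1
reference phase ζ (zero by construction) enters the amplitude formula.
The shift τ is stored so a full-mode reconstruction can be compared
pointwise against the plain harmonic reconstruction.

On a CCW base circle a CCW rotor of harmonic n modulates the radius at
frequency n−1 and a CW rotor at frequency n+1, so lobe mode l collects
the CCW rotor of harmonic l+1 and the CW rotor of harmonic l−1. Mode 1
is the consistent limit of that rule: its vacant CW slot holds the base
circle itself (so L₁ ≈ 1 for an area-normalised cell, representing the
overall circular shape) and its CCW slot the CCW rotor of harmonic 2.
Harmonic offsets (the DC term) belong to no mode. With N harmonics,
modes 1..N+1 exist internally — the last two carry only the boundary CW
rotors, so rotor content is conserved exactly and a full-mode
reconstruction equals the full harmonic reconstruction to 1e−9 —
while reported spectra use modes 1..N−1 (50 for the default 51).

The two rotors of mode l draw l-fold radial cosines whose phase offsets,
seen from the mode-1 starting point, are φ⁺_{l+1} − ζ and ζ − φ⁻_{l−1};
the law-of-cosines combination

    L_l = sqrt(r_ccw² + r_cw² + 2 r_ccw r_cw cos(φ_ccw + φ_cw − 2ζ))

is invariant to rigid rotation and to the starting vertex, reduces to a
single rotor's radius when the other vanishes, and was validated against
a numeric radial-modulation oracle (counting and measuring radial maxima
of composite rotor curves). Exact ties in argmax reporting go to the
lowest mode.

## Complexity metrics

XOR(n) is the symmetric difference between the cell's pixel set and the
rasterised n-mode reconstruction, divided by cell area, computed on the
source grid for image-derived cells and on a 512×512 grid (shape
spanning ~60% of the field) for free-standing contours. Rasterisation is
an even-odd scanline fill sampled at pixel centres — robust to the
self-intersecting outlines low-order truncations can produce — with the
reconstruction polygon sampled at 4 points per grid-diagonal pixel to
avoid aliasing. XOR(0) := 1 (the empty reconstruction), which makes the
marginal differences md(n) = XOR(n−1) − XOR(n) a complete decomposition:
Σ md = 1 − XOR(N) exactly. The reported argmax of md is taken over
n ≥ 2, since mode 1 always explains the bulk circle. Cumulative
difference sums XOR(n) from n = 2 to 50 even when the cut-off comes
earlier (later terms are zero).

The natural cut-off — the first n with XOR(n) = 0 on the grid — is
finite whenever 50 modes suffice at the working resolution: Voronoi
tissue cells cut off around modes 24–38 and a gentle six-lobed star at
42 (512² grid), but sharp-tipped stars genuinely need more modes than 50
at that resolution (≈98 for the pronounced test star), in which case the
profile reports no cut-off rather than a fabricated one.

Entropy is Shannon entropy (log base 2, so uniform-over-k gives log₂ k)
of the amplitude proportions f_l = L_l / Σ L. The pipeline computes it
over lobe modes l ≥ 2: mode 1 is the overall circle and carries no
complexity, and including it reduces the measure to a lobe-to-circle
ratio under which a plain elongated cell outscores a genuinely irregular
multi-lobed one — the opposite of what an irregularity measure should
do. With mode 1 excluded the intended behaviour holds robustly (4:1
ellipse ≈ 1.13 vs ≈ 2.7 for a cd-matched irregular outline). The
function itself defaults to summing from mode 1 and exposes `l_min`, a
squared-amplitude switch, and the log base. In the pipeline, amplitudes
below 1e−6 equivalent-radius units (far below any rasterisation-scale
feature, far above double-precision noise) are treated as absent, and an
entirely featureless spectrum scores 0 — the entropy of rounding noise
is not shape irregularity.

## Synthetic generators

Superformula shapes r(θ) = [|cos(mθ/4)/a|^{n2} + |sin(mθ/4)/b|^{n3}]^{−1/n1}
are sampled at 1000 equal polar angles and area-normalised. The shipped
star table uses n2 = n3 (required for m-fold symmetry) at three
pointedness levels — (n1, n2) = (9, 7), (5, 9), (3, 12) — chosen to give
dominant-mode amplitudes of roughly 0.09, 0.23 and 0.50; exact m-fold
symmetry makes every non-multiple-of-m mode vanish to machine precision,
which the tests use as a selection-rule check. Cosine-lobed circles
r = 1 + ε cos(lθ) (ε < 1 to stay simple) are the amplitude-calibration
fixtures. Synthetic tissues are seeded-Voronoi label rasters on a
jittered grid of centres; discrete Voronoi regions of Euclidean metric
are row-convex, hence 4-connected. These stand-ins have straight walls
and convex cells — they exercise the pipeline's plumbing and the
metrics' identities, not the deep-lobed morphologies of real epidermis,
so passing tests demonstrate correctness of the measurements, not
biological realism.

## Cellular Potts simulator

Standard Metropolis CPM on a square lattice with Moore (second-order)
neighbourhood: H = J·(unlike pairs) + Σ_c λ_a(a_c−A)² + λ_p(p_c−P)²,
with perimeter counted as unlike Moore pairs per cell (consistent with
the coupling neighbourhood). Copy events that lower H by at least the
yield Y are always accepted; otherwise acceptance is exp(−(ΔH+Y)/T) —
taken literally, so ΔH ∈ (−Y, 0] is accepted with probability < 1 when
Y > 0. One time step (MCS) is one sweep of as many elementary
evaluations as interior lattice sites.

Three per-cell forces are added to ΔH for both cells involved in an
event (six extra terms), with s = +1 for the gaining and −1 for the
losing cell, evaluated on the copy vector (site minus cell centre of
mass, length r, angle θ): a lobe term −s·ν·cos(n(θ−φ_c)) favouring
extension along n equally spaced target directions; an elongation term
−s·χ·cos(2(θ−ψ_c)), bipolar because an axis favours extension at both
ends; and a roundness term +s·μ·sign(r−R)(r−R)², R = √(A/π), penalising
extension beyond the preferred radius and retraction inside it (this
signed-quadratic form implements the stated purpose — resisting
deviation from a circle — the printed sources give only that purpose).
Every 100 MCS the lobe phase φ_c is re-anchored to the offset maximising
the circular cross-correlation between the cell's radial boundary
profile and cos(nθ) (closed form via the n-th circular moment; a
featureless profile keeps the current phase), and ψ_c to the principal
axis of the second area moments.

Bookkeeping (areas, perimeters, centre-of-mass sums) is incremental and
audited against full recounts (exact) and against brute-force
Hamiltonian recomputation (|error| < 1e−9 over random 32² fixtures). A
single seeded generator drives site choice, neighbour choice and
acceptance; trajectories are bit-reproducible for a given seed. Cell
fragmentation is detected by a 4-connectivity audit every 100 MCS and
logged as a warning while the simulation continues (the μ term exists
precisely because cells in confluent tissue can lose coherence).

Default parameters (J = 4, A = 450, P = 400, λ_a = 0.3, λ_p = 0.05,
T = 6, Y = 0) give a coherent, moderately fluctuating cell of radius
≈ 12 px; the lobed study condition adds ν = 25, n = 6, μ = 0.5, under
which an isolated cell relaxes to a clear six-lobed shape
(argmax L = 6, L₆ ≈ 0.34 after 2000 MCS). The tissue experiment packs
16 such cells (initialised as a 4×4 block grid) in a 112² field for
2000 MCS and compares each cell's L₆ with the isolated reference —
problem sizes chosen so the whole experiment runs in a few minutes on
one core while leaving the confinement effect (median ratio < 1)
clearly resolved. Fields are bounded (frozen background ring), not
periodic.

## Known limitations

- EFA-level quantities are parameterisation-dependent beyond first
  order in lobe depth (see above); spectra obtained under different
  spacing conventions should not be mixed.
- The XOR cut-off depends on the working grid: higher resolution can
  push it past the 50-mode default, in which case cd/entropy are still
  well-defined but the profile reports no cut-off.
- Free-standing contours rasterised for XOR purposes retain a small
  mismatch floor (the analysed polygon is not re-traced from the grid);
  exact XOR zeros are guaranteed only for raster-derived cells.
- The Potts simulator shares one process-wide random stream per run;
  interleaving `step` calls from two simulations breaks per-run
  reproducibility (run them sequentially).
- Mode-1 bookkeeping (base circle + CCW rotor of harmonic 2) is the
  consistent limit of the epicycle rule; alternative low-mode
  conventions exist and would change L₁ only.
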