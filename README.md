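# topocontour

Contour detection and completion for 2D grayscale images — e.g. finding
cell boundaries in microscopy fields, or reconstructing an object's edges
through an occluded region — by combining a *topological sensitivity* edge
detector with *fast-marching minimal paths*.

## The method

**Edge detection.** The image `v` is restored by one implicit diffusion
step, `u − div(c∇u) = v` with natural Neumann borders, and edges are
defined as the places where inserting an infinitesimally thin insulating
crack would most decrease the gradient energy `j = ∫‖∇u‖²`. For a crack at
`x` with unit normal `n` the first-order change is the quadratic form

    G(x, n) = −π c (∇u₀·n)(∇p₀·n) − π |∇u₀·n|² = nᵀ M(x) n,

where `u₀` is the diffused image and `p₀` the adjoint state of the energy.
Minimising over `n` gives the smallest eigenvalue `λ_min(x)` of the
symmetric 2×2 matrix `M(x)`; deeply negative `λ_min` marks edge pixels,
with a much tighter support than the plain gradient magnitude because the
sensitivity measures a *global* energy change.

**Contour completion.** `λ_min` is shifted to a positive potential
`P = λ_min − min λ_min + α`. Fronts are propagated from keypoints (deep
minima of `λ_min`) by solving the Eikonal equation `‖∇D‖ = P + α` with a
first-order upwind fast-marching solver that also records the
weighted-Voronoi label of every pixel. Adjacent fronts meet at saddle
points; processing saddles cheapest-first while capping every keypoint at
two connections, and back-propagating from each saddle down the arrival
field, yields connected minimal-path contours along the valleys of the
sensitivity.

**Inpainting.** For a hidden region ω with boundary ring γ, two harmonic
extensions of the known image are compared: `u_D` matching the values on
γ and `u_N` matching the normal derivative. Their mismatch
`J(σ) = ½‖u_D − u_N‖²` has its own crack sensitivity
`G = −[(∇u_D·n)(∇p_D·n) + (∇u_N·n)(∇p_N·n)]`; minimal paths along its
valleys, rasterised into insulating link cuts, let a final harmonic fill
reconstruct the hidden region with sharp edges exactly on the completed
contours.

## Worked example

`examples/04_inpaint_rectangle.py` hides a 20-pixel-wide strip (800
pixels) across a dark bar and reconstructs it:

```
hidden pixels: 800
keypoints found: [(70, 70), (70, 89), (89, 70), (89, 89)]
crack links laid: 40
mismatch cost before/after cracks: 39.157 / 1.59e-28
plain fill mismatch:  24 px
hybrid fill mismatch: 0 px
```

The four keypoints are where the bar's two long edges enter the hidden
strip. Two 20-link crack curtains complete the edges across the gap, the
Dirichlet/Neumann mismatch cost collapses to zero, and the crack-aware
fill restores the bar exactly, while the plain harmonic fill mislabels 24
pixels. The other examples demonstrate edge detection on a smooth ramp
(`01`), fast marching and back-propagation on a dark valley (`02`), and
closed-contour segmentation of a drawn ring (`03`).

A thin CLI wraps the same drivers:

```
topocontour simulate rect --gap 20 -o fx
topocontour inpaint fx_rect.png fx_rect_mask.png
topocontour edges image.png --delta-fraction 0.5
topocontour segment image.png --n-keypoints 3
```

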