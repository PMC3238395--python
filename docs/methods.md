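# Methods

This note records the model, the discretisation, the tunable parameters
and the design choices made where the underlying method leaves the
discrete realisation open. Everything quantitative stated here is
computed by the test-suite or by `scripts/acceptance.py`.

## Model

Let `Ω` be the pixel grid and `v` the observed image. The edge detector
solves the restoration problem

    u − div(c ∇u) = v  in Ω,    ∂ₙu = 0 on ∂Ω,

and asks where the gradient energy `j = ∫ ‖∇u‖²` would drop most if an
infinitesimally thin insulating crack (homogeneous Neumann condition on
both faces) were inserted. The first-order sensitivity for a crack at
`x` with unit normal `n` is the quadratic form `nᵀM(x)n` with

    M = −π c (∇u₀ ∇p₀ᵀ + ∇p₀ ∇u₀ᵀ)/2 − π ∇u₀ ∇u₀ᵀ,

`u₀` the restored image and `p₀` the adjoint state (same operator,
right-hand side `2 div ∇u₀`). Its smallest eigenvalue `λ_min(x)`, with
the minimising eigenvector as crack normal, is the edge indicator. The π
factors are kept literally; they only rescale thresholds.

For inpainting, a hidden region `ω` with exterior boundary ring `γ`
admits two harmonic extensions of the known data — `u_D` matching the
image values on γ, `u_N` matching the estimated normal derivative — and
the cost is their mismatch `J(σ) = ½‖u_D − u_N‖²_ω`. Its sensitivity is
`G = −[(∇u_D·n)(∇p_D·n) + (∇u_N·n)(∇p_N·n)]`, where `p_D` solves the
zero-boundary Dirichlet problem with source `−(u_D − u_N)` and `p_N` the
zero-flux Neumann problem with source `+(u_D − u_N)`. These adjoint
forms (and their signs) are not taken on faith: the suite certifies them
by exhaustively cutting individual links, re-solving, and checking that
the true cost changes rank-correlate with the predicted sensitivities
(Spearman ≈ 0.85–0.95 for both costs).

Contours are completed by fast marching on the shifted sensitivity
`P = λ_min − min λ_min`, front speed `1/(P + α)`: keypoints seed
multi-source propagation, adjacent fronts meet at saddle points, and
back-propagation from the saddles down the arrival field produces
minimal paths, paired cheapest-first with every keypoint capped at two
connections so the union forms simple open or closed contours.

## Discretisation

* Pixel-centred grid, 0-based `(row, col)`, spacing `h = 1` by default.
* Diffusivity and cracks live on pixel-pair interfaces (`LinkField`); a
  cut link is simply omitted from the 5-point stencil, which realises
  the crack's Neumann condition exactly and makes "crack insulation"
  literal: a closed curtain of cut links decouples the two sides to the
  last bit (checked exactly).
* All elliptic solves use a sparse direct factorisation (desk-scale
  grids, bit-stable reruns). Sum of the diffusion solution equals the
  sum of the input to ~1e−15 relative (Neumann structure).
* The pure-Neumann solve is singular per connected component: the
  right-hand side is mean-projected per component (the projection
  magnitude is logged) and the additive constant anchored — by default
  to the mean of the boundary data over the component's contact pixels,
  or to a caller-supplied value.
* Dirichlet-unreachable components (possible once cracks enclose a
  region) are filled with the mean of the data over γ and logged.
* Gradients are central differences, one-sided at borders and across
  cut links (the field is discontinuous there).
* Boundary fluxes `∂ₙv` on γ are estimated from the two nearest pixels
  outside ω along the normal (a one-sided two-point stencil); missing
  second pixels fall back to zero flux.
* Fast marching uses the first-order Godunov upwind update with a
  min-heap; ties are broken by insertion order, so runs are
  deterministic. Arrival labels are inherited from the smallest-arrival
  accepted 4-neighbour. Saddle value = the larger of the two meeting
  arrivals; per label pair the cheapest interface is kept. The scheme's
  uniform-speed error against the Euclidean distance is ~7% (max
  relative, beyond ten pixels from the seed) and halves with the grid
  step (ratio ≈ 0.65).
* Back-propagation is discrete 8-neighbour steepest descent restricted
  to the target front's Voronoi region; ties prefer axis steps, then
  the lowest row and column. Arrival strictly decreases along every
  path, so termination at the keypoint is guaranteed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `c` | 1.0 | diffusion conductivity of the restoration step; smaller values blur less and localise edges of thin structures more tightly (0.25 is used for the thin-ring experiments) |
| `delta` / `admissible_fraction` | 0.5 | edge/admissible threshold as a fraction of the deepest sensitivity |
| `alpha` (segmentation) | 1e−3 × potential range | path-length regularisation; tiny, because segmentation valleys are deep and must be followed whatever their length |
| `alpha_fraction` (inpainting) | 0.1 | inside a hidden zone the sensitivity is essentially flat away from γ (exhaustive single-link re-solves show *positive* energy changes mid-gap), so a larger length penalty keeps completions straight where the field carries no information while the deep near-boundary valleys still dominate |
| `potential_smoothing` | 0 | Gaussian smoothing of the sensitivity before path extraction; line-like features produce twin valleys flanking the line, and a smoothing of about the line width merges them onto the centreline (1.5 px for the ring experiments) |
| `n_keypoints` | 3 | seeds per segmentation run; the first is the global sensitivity minimum, the rest farthest points in the weighted metric |
| `max_ring_fraction` | 0.6 | inpainting contours with more of their pixels on the inner boundary ring of ω are discarded: the mismatch sensitivity is always deep along that ring, but such contours carry no hidden-edge information and, as link cuts, would insulate ω from its own boundary data |
| `exclusion_radius` | 3 px | dilation of found contours before a segmentation restart |
| `fill_mode` | `dirichlet` | the final fill extends boundary values; `neumann` (flux matching, with per-component anchoring) is available but can leave small seams at its anchoring boundaries |

## Design choices in the inpainting driver

* **Keypoints.** Hidden edges reach γ, where the sensitivity is
  deepest; keypoints are one per 8-connected cluster of admissible
  ring pixels. Within a cluster the keypoint is placed beside the
  largest tangential jump of the *known* boundary data — the visible
  edge crossing — because the bare sensitivity argmin lands one or two
  pixels off when the edge crosses γ obliquely. The admissible fraction
  relaxes (0.5 → 0.3 → 0.2 → 0.1) until at least two clusters appear,
  since crossings of a curved edge can have very unequal depths.
* **Crack rasterisation.** A pixel path discretises a crack that
  really lives on the interface grid. Each path becomes a "curtain" of
  cut links: axis steps cut the links on the crack side of both
  endpoints, vertical jogs cut the sideways links of their crack-side
  corner, diagonal steps seal the whole 2×2 quad, and one virtual step
  extends each end so the curtain closes against γ. Insulation of the
  resulting curtains is verified exactly in the tests, including
  diagonal staircases.
* **Lateralisation.** The same curve can be laid on either side of the
  path (half-a-pixel ambiguity). Both candidate curtains are scored by
  the mismatch cost they leave behind, jointly over all paths; when one
  candidate clearly reconciles the extensions (cost below half the
  other's) it wins. When neither does — typically when the hidden edge
  crosses the grid obliquely and both lateralisation are half a pixel
  off — the crack is laid on the majority-tone side, correcting the
  known bias of the boundary-mean Neumann anchor, which makes the
  sensitivity valley systematically deeper on the minority-tone flank.

## Synthetic data

The generators produce the study geometries: a Gaussian-CDF ramp (edge
localisation), a 120×20 dark bar crossed by hidden strips of 20/40/80
pixels (the 20-pixel strip hides ≈800 pixels), a dark disc with a
20×20 bite over its boundary arc (curved-edge completion), a drawn ring
and straight valley (thin-line tracking), and seeded blurred discs
("cells", for multi-object restarts). All are noiseless by default —
the reference reconstructions are exact binary patterns — with Gaussian
noise and impulse clutter available per generator. The potential
comparison uses 8% impulse clutter: localized jumps corrupt a local
gradient map linearly but enter the global sensitivity only
quadratically, which is the mechanism that makes the sensitivity-based
potential track the centreline better (mean distance ≈ 0.8 px vs
≈ 1.1–1.3 px, averaged over three clutter realisations).

What passing these tests does *not* show: behaviour under texture,
shading comparable to edge contrast, colour, or real point-spread
functions; the binary fixtures make "perfect reconstruction"
well-defined but are easier than natural images, where the sensitivity
valleys are shallower and thresholds need adjustment.

## Known limitations

* Inside a wide hidden zone the first-order sensitivity carries no
  usable valley along the edge continuation (measured: every single
  link cut mid-gap *increases* the mismatch cost), so completions there
  are straightness-regularised interpolations between boundary
  crossings; curvature is recovered only near γ. At four times the
  object size the pairing of boundary crossings itself becomes
  unreliable and reconstruction of connectivity is not guaranteed.
* Keypoint count and the degree-two cap assume simple open/closed
  contours; T-junctions and bifurcations are out of scope.
* Anchoring of the Neumann extension is a genuine gauge freedom of the
  cost; the boundary-mean convention is used throughout, and its tonal
  bias is compensated only at the crack-lateralisation stage.
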