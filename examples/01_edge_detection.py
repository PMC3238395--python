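"""Edge detection on a smooth ramp: sensitivity vs plain gradient.

Builds the Gaussian-CDF ramp image, computes the crack-insertion
sensitivity (direct diffusion solve + adjoint solve + per-pixel 2x2
matrix), and compares how tightly the deep-sensitivity set and the
strong-gradient set concentrate around the true transition column.
"""

import numpy as np

from topocontour import fixtures, topograd

image = fixtures.gen_sigmoid(shape=(32, 64), center_col=32, width=3.0)
result, u0, p0 = topograd.topological_gradient(image)
lam = result.lambda_min
grad = topograd.standard_gradient_magnitude(u0)

print(f"sensitivity range: [{lam.min():.4f}, {lam.max():.4f}]")
deep = lam <= 0.5 * lam.min()
strong = grad >= 0.5 * grad.max()
deep_cols = np.nonzero(deep.any(axis=0))[0]
strong_cols = np.nonzero(strong.any(axis=0))[0]
print(f"deep-sensitivity columns:  {deep_cols.min()}..{deep_cols.max()} "
      f"(span {deep_cols.max() - deep_cols.min() + 1})")
print(f"strong-gradient columns:   {strong_cols.min()}..{strong_cols.max()} "
      f"(span {strong_cols.max() - strong_cols.min() + 1})")

mask = topograd.edge_mask(lam, 0.5 * lam.min())
cols = np.nonzero(mask.any(axis=0))[0]
print(f"edge mask: {int(mask.sum())} pixels, all within "
      f"{np.abs(cols - 32).max()} columns of the true transition (col 32)")

# The spans show the point of the method: at matched depth fractions the
# sensitivity support is strictly narrower than the gradient support, so
# thresholding it yields thin, well-localised edges.
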