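"""Fit the folding scaling law to a synthetic cohort.

Samples log points exactly on the theoretical plane, perturbs them with a
little measurement noise, and fits logAt + 0.25 logT2 = alpha logAe + log k.
The fitted exponent should sit near the theoretical 5/4, with a 95% CI
covering it; the implied fractal dimension is twice the exponent.
"""

import numpy as np

from foldmorph import fit_scaling_law, generate_on_plane, implied_fractal_dimension

points = generate_on_plane(n=120, log_k=0.0, spread=0.1, seed=0)
rng = np.random.default_rng(1)  # independent measurement-noise stream
points[:, 0] += rng.normal(0, 0.01, len(points))  # noise in log At

fit = fit_scaling_law(points)
print(f"alpha      = {fit.alpha:.4f}  (theory: 1.25)")
print(f"95% CI     = ({fit.alpha_ci[0]:.4f}, {fit.alpha_ci[1]:.4f})")
print(f"log k      = {fit.log_k:.4f}")
print(f"R^2        = {fit.r_squared:.4f}   n = {fit.n}")
print(f"implied fractal dimension = {implied_fractal_dimension(fit.alpha):.3f}  (theory: 2.5)")
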