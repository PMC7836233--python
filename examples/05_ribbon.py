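"""Build intuition with the folded-ribbon toy model.

A sinusoid with 8 folds wrapped around a circle stands in for a folded
cortex: the base radius drives the exposed-perimeter analog, the fold
amplitude drives the folded-length analog, and the ribbon thickness is
used directly.  Scanning a 3D parameter grid and differencing shows how
each component responds — tension K rises with thickness and amplitude
but falls with radius; size I rises with thickness and radius; shape S
falls with thickness.
"""

import json

from foldmorph import RibbonSpec, gradient_signs, ribbon_components, ribbon_grid

spec = RibbonSpec(R0=12.0, a=1.0, T=0.5, n_folds=8)
c = ribbon_components(spec)
print(f"ribbon R0={spec.R0}, a={spec.a}, T={spec.T}, {spec.n_folds} folds:")
print(f"  K = {float(c.K):+.4f}   S = {float(c.S):+.4f}   I = {float(c.I):+.4f}")

grid = ribbon_grid()  # R0 in [8,16], a in [0,2], T in [0.2,1], 10^3 points
print(f"\nscanned {len(grid)} parameter combinations; finite-difference signs:")
print(json.dumps(gradient_signs(grid), indent=2))
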