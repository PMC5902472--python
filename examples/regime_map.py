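"""Map the (D, N) regime where directed growth can emerge, and classify.

The 1-D cell-nutrient reaction-diffusion model depends on the diffusivity
ratio D = D_m/D_n and the dimensionless nutrient concentration
N = p L^2 N0 / D_n.  For each (D, N) we solve to t = 1 (about 119 days of
growth for the standard petri-dish scales) and record the maximum bias
index I_b; values above ~0.52 mark parameter regimes where a colony grows
toward a nutrient source.
"""

import numpy as np

from dlgrowth import PhysicalParams, nondimensionalize, regime_sweep
from dlgrowth.workflows import classify_dlg

phys = PhysicalParams(D_m=3e-2, N0=3.8e-3)
dim = nondimensionalize(phys)
print(
    f"standard parameters: c_hat = {dim.c_hat:.3g}, time scale = "
    f"{dim.time_scale_min / (60 * 24):.0f} days per dimensionless time unit"
)
print(f"D_m = 3e-2 mm^2/min, N0 = 3.8e-3 g/mm^2  ->  D = {dim.D:.3g}, N = {dim.N:.3g}")

print("\ncomputing the regime map (integer decades, ~15 s) ...")
rm = regime_sweep(np.arange(-6.0, 4.0), np.arange(0.0, 6.0))
ld, ln, v = rm.argmax()
print(f"max I_b peaks at log10 D = {ld:g}, log10 N = {ln:g} (I_b = {v:.3f})")
print("N = 1 row (no bias possible at low nutrient):",
      np.round(rm.max_ib[0], 3))

for name, delta, N in [
    ("B. subtilis   (Delta = 0.2,  N = 1e2)", 0.2, 1e2),
    ("S. cerevisiae (Delta = 3e-3, N = 1e2)", 3e-3, 1e2),
]:
    verdict = classify_dlg(delta, N, regime_map=rm)
    print(f"{name}: {verdict}")
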