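"""Binding stoichiometry from a titration curve.

Simulates the A505 isotherm of an 80 uM solution of a bidentate ligand
titrated with Cu(I) forming a tight 2:1 (ligand:metal) complex, adds 2%
noise, and locates the saturation breakpoint by continuous two-segment
least squares.  The breakpoint in metal:ligand equivalents is the
reciprocal of the binding stoichiometry: a 2:1 complex saturates at 0.5
equivalents.
"""

import numpy as np

import regulonprint as rp

l_total = 80.0  # uM ligand
additions = np.arange(0.0, 88.0, 8.0)  # 0 .. 1 equivalent in 0.1 steps
plateau = 0.01 * l_total / 2  # absorbance at saturation (epsilon = 0.01/uM)

curve = rp.gen_titration(l_total, additions, epsilon=0.01,
                         noise_sd=0.02 * plateau, seed=1)
fit = rp.fit_breakpoint(curve)

print(f"breakpoint: {fit.x_break:.3f} equivalents of Cu(I)")
print(f"inferred stoichiometry: {fit.stoichiometry:.2f} "
      f"(~{fit.stoichiometry_rounded:g}:1 ligand:metal)")
print(f"rising slope {fit.slope_rise:.4f} A/equiv, "
      f"plateau slope {fit.slope_plateau:.4f} A/equiv")

# a finite formation constant rounds the corner but keeps the breakpoint
soft = rp.gen_titration(l_total, additions, beta2=1e12, epsilon=0.01)
print(f"finite beta2 = 1e12 M^-2: breakpoint "
      f"{rp.fit_breakpoint(soft).x_break:.3f} equivalents")
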