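"""Dale-compliant E/I decompositions along the lambda_EI continuum.

Decomposes a trained network at several lambda_EI values, verifies that the
excitatory population reproduces the original rates exactly, and prints the
inhibitory-population angle statistics that distinguish private inhibition
(lambda=0) from inhibitory prediction units (lambda=1).
"""

import numpy as np

from predinet import condition, decompose, inhibitory_geometry, make_network, steady_state

net = make_network(N=400, P=2, mu=0.97, b=20.0, seed=0)

for lam in (0.0, 0.3, 0.6, 1.0):
    ei = decompose(net, lam, seed=0)
    res_j, _ = ei.constraint_residuals()
    r0 = steady_state(net, condition(2, "x_only")).r
    r1 = steady_state(ei.effective_network(), condition(2, "x_only")).r
    geo = inhibitory_geometry(ei)
    print(
        f"lambda={lam:3}: constraint residual = {res_j:.1e}   "
        f"max E-rate diff = {np.max(np.abs(r0 - r1)):.1e}   "
        f"cos(r^I_xy, r^I_x) = {geo.cos_psi:+.3f}   I R-fraction = {geo.frac_R:.3f}"
    )

print(
    "\nEvery member of the family reproduces the excitatory rates exactly;\n"
    "as lambda grows the inhibitory population shifts from private copies of\n"
    "excitatory neurons toward units signalling internal predictions, which\n"
    "aligns their match and mismatch responses."
)
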