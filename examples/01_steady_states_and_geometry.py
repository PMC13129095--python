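"""Steady states across learning: match suppression and response geometry.

Builds single-pair networks at three learning stages, solves the match and
mismatch steady states, and prints the mean rates, their ratio, and the
angle statistics of the population responses.
"""

import numpy as np

from predinet import make_network, pair_geometry

for mu in (0.0, 0.5, 0.9):
    net = make_network(N=3000, P=1, mu=mu, b=20.0, seed=0)
    geo = pair_geometry(net)
    print(
        f"mu={mu:4}: mismatch/match rate ratio = {geo.rate_ratio:5.2f}   "
        f"cos(r_x, r_y) = {geo.cos_xy:+.3f}   cos(r_xy, r_x) = {geo.cos_match_x:+.3f}"
    )

print(
    "\nThe ratio grows with learning (match responses are suppressed, mismatch\n"
    "responses amplified), the two mismatch responses become anti-correlated,\n"
    "and match and mismatch responses decorrelate."
)
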