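"""Functional cell-types and the desegregation of predictive representations.

Classifies neurons as representation (R) or prediction-error (PE) cells
across learning, then measures the fraction of mixed-representation neurons
(different types for two learned pairs) at the data-constrained gain.
"""

import numpy as np

from predinet import calibrate_gain_to_balance, make_network, mixed_fraction, pe_r_fractions
from predinet.celltypes import pair_voltages

b_star = calibrate_gain_to_balance(target=162.0, mu=0.97, N=2000, seed=0)

print("R/PE fractions across learning (P=1):")
print(pe_r_fractions(N=2000, b=b_star, mus=[0.0, 0.5, 0.97], n_instances=3, seed=0).round(3))

pcts = []
for seed in range(5):
    net = make_network(N=4000, P=2, mu=0.97, b=b_star, seed=seed)
    h_x, _ = pair_voltages(net, 0)
    res = mixed_fraction(net, sigma=float(np.std(h_x)), center=False)
    pcts.append(100 * res.fraction)
print(
    f"\nmixed-representation neurons (P=2, alpha~0): {np.mean(pcts):.1f}% +- {np.std(pcts):.1f}%\n"
    "About a quarter of dually-responsive neurons are R for one association\n"
    "and PE for the other: stimulus and error coding are desegregated."
)
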