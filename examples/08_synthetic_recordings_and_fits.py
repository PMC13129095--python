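"""Synthetic recordings and parameter recovery.

Generates voltage-clamp-style and extracellular-style recordings from a
ground-truth network, recovers the gain b by inverting the closed-form
variance ratio, and recovers the E/I structure parameter lambda_EI from
RS/FS population correlations.
"""

from predinet import (
    decompose,
    estimate_lambda,
    fit_gain_am,
    fit_gain_vm,
    generate_am_recording,
    generate_rsfs_recording,
    generate_vm_recording,
    make_network,
)

net = make_network(N=4000, P=1, mu=0.97, b=20.0, seed=7)

rec = generate_vm_recording(net, seed=5)
fit = fit_gain_vm(rec, seed=5)
print(f"V-M style fit: true b = 20, recovered b = {fit.b_hat:.1f}, "
      f"CI = [{fit.ci[0]:.1f}, {fit.ci[1]:.1f}]")

rec = generate_am_recording(net, seed=6)
fit = fit_gain_am(rec, seed=6)
print(f"A-M style fit: true b = 20, recovered b = {fit.b_hat:.1f}, "
      f"CI = [{fit.ci[0]:.1f}, {fit.ci[1]:.1f}]")

truth = make_network(N=400, P=2, mu=[0.97, 0.0], b=20.0, seed=3)
ei = decompose(truth, 0.6, seed=3)
rsfs = generate_rsfs_recording(ei, noise_sd=0.05, seed=4)
est = estimate_lambda(rsfs, b=20.0, N_ref=300, seed=11)
print(f"RS/FS fit: true lambda_EI = 0.6, recovered = {est['lambda_hat']:.2f}")

print(
    "\nEvery generator serializes its ground truth, and every downstream fit\n"
    "is validated by recovering that truth within its uncertainty."
)
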