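"""Match/mismatch decoding from inputs vs network responses.

Shows that (i) with cross-pair controls the raw stimulus vectors are not
linearly separable, (ii) the network's learned responses are, and (iii) after
learning even a one-dimensional population-mean-rate readout matches the
max-margin decoder.
"""

import warnings

from predinet import build_decode_dataset, linear_decoder_error, make_network

warnings.filterwarnings("ignore")

KINDS = ("x_only", "y_only", "cross_pair")

net = make_network(N=400, P=4, mu=0.97, b=170.0, seed=8)
ds_in = build_decode_dataset(net, noise_sd=0.1, n_samples=120, seed=9,
                             feature_space="inputs", mismatch_kinds=("cross_pair",))
err_in, _ = linear_decoder_error(ds_in, "max_margin", n_repeats=5)
print(f"decoding from raw inputs (cross-pair controls): error = {err_in:.2f}  (chance = 0.5)")

for mu in (0.0, 0.97):
    net = make_network(N=400, P=4, mu=mu, b=170.0, seed=8)
    ds = build_decode_dataset(net, noise_sd=0.1, n_samples=120, seed=9, mismatch_kinds=KINDS)
    svm, _ = linear_decoder_error(ds, "max_margin", n_repeats=5)
    mr, _ = linear_decoder_error(ds, "mean_rate_threshold", n_repeats=5)
    print(f"mu={mu:4}: max-margin error = {svm:.3f}   mean-rate error = {mr:.3f}")

print(
    "\nThe nonlinear network transform makes the prediction error linearly\n"
    "readable; after learning a stimulus-independent mean-rate readout\n"
    "performs as well as the optimal decoder."
)
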