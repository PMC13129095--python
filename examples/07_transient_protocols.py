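"""Pulse and step protocols: transient predictions and time-resolved balance.

Pulses of associated stimuli separated by an interval delta_t probe the
network's ability to bridge the gap with an internally maintained
prediction; steps expose a transient episode of tight balance at the onset
of the predicted second stimulus.
"""

import numpy as np

from predinet import PulseProtocol, StepProtocol, make_network, run_pulse_protocol, run_step_protocol

for mu in (0.0, 0.9):
    net = make_network(N=600, P=2, mu=mu, b=5.0, seed=0)
    _, m = run_pulse_protocol(net, PulseProtocol(pair=0, delta_t=0.01, condition="match"))
    print(f"mu={mu}: post-removal mismatch/match ratio = {m.ratio_post:5.2f}   "
          f"decay timescale tau = {m.tau_decay:.2f}")

net = make_network(N=600, P=2, mu=0.9, b=5.0, seed=0)
_, cross = run_pulse_protocol(
    net, PulseProtocol(pair=0, delta_t=0.01, condition="cross_pair", cross_partner=1)
)
print(f"cross-pair control at mu=0.9: ratio = {cross.ratio_post:.2f} (no suppression)")

_, times, med = run_step_protocol(net, StepProtocol(pair=0, delta_t=1.0, step_width=4.0))
pre = np.nanmedian(med[(times > 1.0) & (times < 1.5)])
peak = np.nanmax(med[(times >= 1.5) & (times <= 2.5)])
print(
    f"\nstep protocol: median balance before y-onset = {pre:.2f}, "
    f"transient peak after onset = {peak:.2f}\n"
    "Learning slows the decay of transient responses, makes match suppression\n"
    "specific to associated pairs, and produces a transient tightening of the\n"
    "balance when the predicted stimulus arrives."
)
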