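"""Simulate a single leaky integrate-and-fire neuron step by step.

Builds a constant-current drive, runs the discrete hard-reset dynamics
h[k+1] = h[k]*lam*(1-o[k]) + I, and prints the membrane trajectory with the
spike train.  With lam=0.5 and drive 0.3 the potential converges to
0.3/(1-0.5) = 0.6 and never crosses a threshold of 1.0; raising the drive
to 0.6 makes the neuron fire periodically (potential resets to zero after
each spike).
"""

import numpy as np

from htda import LIFParams, run_spiking_layer


def show(drive, v_th):
    params = LIFParams(lam=0.5, v_th=v_th, learnable=False)
    drives = [np.array([drive])] * 12
    spikes, state = run_spiking_layer(drives, params)
    train = "".join("|" if s[0] else "." for s in spikes)
    print(f"drive={drive:.2f}  V_th={v_th:.1f}  spikes: {train}  final h={state.h.data[0]:.4f}")


print("subthreshold: converges to drive/(1-lam), stays silent")
show(0.3, 1.0)
print("suprathreshold: integrate, fire, hard-reset, repeat")
show(0.6, 1.0)
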