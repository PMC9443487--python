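"""Measure firing rates and event-driven MACs of a traced inference.

Runs an untrained model on a batch of scenes, prints the per-layer firing
proportions, the mean firing rate (spikes / neurons / steps), the sparse
MAC estimate (only neurons that fired drive post-synaptic work) and the
parameter count.  The density-1 upper bound shows how much computation the
spike sparsity saves relative to a dense network of the same shape.
"""

import numpy as np

from htda import HTDANetwork, NetworkConfig
from htda.data import make_scene_dataset
from htda.profiler import count_params, dense_conv_macs, estimate_macs, firing_rates

model = HTDANetwork(
    NetworkConfig(height=16, width=16, in_channels=1, base_channels=8, n_classes=2, k_steps=4),
    rng=0,
)
images, _, _ = make_scene_dataset(50, seed=1, label_mode="texture")
trace = model.infer(images, collect=True)

rates = firing_rates(trace)
print("firing proportion per layer and step:")
for name, row in zip(rates.layers, rates.per_layer_step):
    print(f"  {name:6s} " + " ".join(f"{v:.3f}" for v in row))
print(f"mean firing rate: {rates.mean_rate:.4f}")

rep = estimate_macs(trace, model)
k, batch = model.config.k_steps, images.shape[0]
widths = model.stage_widths
sizes = [(16, 16), (16, 16), (8, 8), (8, 8), (4, 4), (4, 4)]
dense_bound = sum(dense_conv_macs(*sizes[i], widths[i - 1], widths[i]) for i in range(1, 6))
dense_bound = (dense_bound + widths[-1] * 4 * model.config.hidden
               + model.config.hidden * model.config.n_classes) * k * batch
print(f"\nspiking-path MACs: {rep.spiking_macs}  (density-1 bound {dense_bound})")
print(f"dense parts (encoder+generator+decoder): {rep.dense_macs}")
print(f"total MACs for the batch: {rep.total}  parameters: {count_params(model)}")
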