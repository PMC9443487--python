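"""Attack a trained model with L-infinity PGD through the full closed loop.

Trains briefly, then perturbs held-out scenes within an eps-ball using 10
sign-gradient steps (the gradient flows through the attention feedback, not
around it) and reports clean vs robust accuracy.  Robust accuracy drops as
eps grows; the perturbation never exceeds the printed budget.
"""

import numpy as np

from htda import HTDANetwork, LossWeights, NetworkConfig, PGDConfig, TrainConfig, train
from htda.adversarial import pgd_attack, robust_accuracy
from htda.data import make_scene_dataset

images, labels, _ = make_scene_dataset(1100, seed=3, label_mode="texture")
model = HTDANetwork(
    NetworkConfig(height=16, width=16, in_channels=1, base_channels=8, n_classes=2, k_steps=4),
    rng=0,
)
tcfg = TrainConfig(epochs=12, batch_size=100, lr=0.01, warmup_epochs=3, seed=0,
                   loss_weights=LossWeights(alpha=0.5))
train(model, images[:1000], labels[:1000], tcfg)

xte, yte = images[1000:], labels[1000:]
clean = np.mean(model.infer(xte, collect=False).prediction == yte)
print(f"clean accuracy: {clean:.3f}")
for eps in (8 / 255, 16 / 255, 32 / 255):
    cfg = PGDConfig(epsilon=eps, iterations=10, seed=0)
    adv = pgd_attack(model, xte, yte, cfg)
    print(f"eps={eps:.4f}: max|X_adv - X| = {np.abs(adv - xte).max():.4f} (<= eps), "
          f"robust accuracy = {robust_accuracy(model, xte, yte, cfg):.3f}")
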