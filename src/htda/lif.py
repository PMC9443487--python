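"""Discrete-time leaky integrate-and-fire (LIF) layers with hard reset.

The membrane potential of a layer of neurons follows, per time step of
length Td,

    h[k+1] = h[k] * lam * (1 - o[k]) + I[k+1]
    o[k]   = H(h[k] - V_th),          lam = exp(-Td / tau)

where ``I`` is the synaptic drive (weights times pre-synaptic spikes plus
bias), ``lam`` the membrane decay factor, ``V_th`` the firing threshold and
``H`` the Heaviside step (H(0) = 1 here, a fixed tie-break).  A spike hard-
resets the potential to zero before the next step's leak; the continuous-
time reset potential is therefore fixed at 0 and the membrane resistance is
absorbed into the synaptic weights.

Training uses a rectangular surrogate-gradient window of half-width ``a``
around threshold in place of H's almost-everywhere-zero derivative.  The
decay factor and threshold can be learnable: ``lam`` is stored as an
unconstrained scalar squashed through a logistic to stay in (0,1), and
``V_th`` is stored directly with a positivity floor of 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def decay_factor(td: float, tau: float) -> float:
    """Membrane decay per step, exp(-Td/tau); strictly in (0,1) for positive args."""
    if td <= 0 or tau <= 0:
        raise ValueError(f"Td and tau must be positive, got Td={td}, tau={tau}")
    return float(np.exp(-td / tau))


@dataclass
class LIFParams:
    """Layer-level LIF parameters.

    lam and v_th are the *initial* values; when ``learnable`` the layer owns
    trainable scalars seeded from them.
    """

    lam: float = 0.5
    v_th: float = 0.5
    td: float = 1.0  # ms
    tau: float | None = None  # ms; when given, lam is derived as exp(-td/tau)
    window: float = 0.5  # surrogate half-width a, membrane-potential units
    learnable: bool = True
    spike_fn: str = "step"  # "step" (hard spikes) or "ramp" (integrated
    # surrogate; continuous, used to validate gradients by finite differences)
    u_reset: float = field(default=0.0, init=False)  # hard reset target, fixed

    def __post_init__(self):
        if self.tau is not None:
            self.lam = decay_factor(self.td, self.tau)
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"decay factor must be in (0,1), got {self.lam}")
        if self.v_th <= 0:
            raise ValueError(f"threshold must be positive, got {self.v_th}")
        if self.window <= 0:
            raise ValueError(f"surrogate window must be positive, got {self.window}")
        if self.spike_fn not in ("step", "ramp"):
            raise ValueError(f"spike_fn must be 'step' or 'ramp', got {self.spike_fn!r}")


@dataclass
class LIFLayerState:
    """Membrane potentials and previous spikes of one layer (zeros at rest)."""

    h: Tensor
    o: Tensor

    @classmethod
    def zeros(cls, shape: tuple[int, ...]) -> "LIFLayerState":
        return cls(h=Tensor(np.zeros(shape)), o=Tensor(np.zeros(shape)))


_VTH_FLOOR = 1e-3


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


class LIFCell:
    """Trainable state-update rule shared by conv and dense spiking layers.

    Owns the (possibly learnable) decay and threshold scalars; the synaptic
    drive is computed by the caller.
    """

    def __init__(self, params: LIFParams):
        self.params = params
        self.lam_raw = Tensor(_logit(params.lam), requires_grad=params.learnable)
        self.v_th_raw = Tensor(params.v_th, requires_grad=params.learnable)

    @property
    def lam(self) -> Tensor:
        return ad.sigmoid(self.lam_raw)

    @property
    def v_th(self) -> Tensor:
        # positivity floor keeps the threshold away from zero while learnable
        return ad.relu(self.v_th_raw - _VTH_FLOOR) + _VTH_FLOOR

    def trainable(self) -> dict[str, Tensor]:
        return {"lam_raw": self.lam_raw, "v_th_raw": self.v_th_raw} if self.params.learnable else {}

    def step(self, state: LIFLayerState, current: Tensor) -> tuple[LIFLayerState, Tensor]:
        if current.shape != state.h.shape:
            raise ValueError(f"drive shape {current.shape} != state shape {state.h.shape}")
        h_new = state.h * self.lam * (1.0 - state.o) + current
        fn = ad.heaviside_surrogate if self.params.spike_fn == "step" else ad.spike_ramp
        spikes = fn(h_new - self.v_th, self.params.window)
        return LIFLayerState(h=h_new, o=spikes), spikes


def lif_step(state: LIFLayerState, current: Tensor | np.ndarray, params: LIFParams) -> tuple[LIFLayerState, Tensor]:
    """One hard-reset LIF update with fixed (non-learnable) scalars from `params`.

    Returns the new state and the binary spike tensor (spike where the new
    potential reaches threshold).
    """
    current = ad.as_tensor(current)
    if current.shape != state.h.shape:
        raise ValueError(f"drive shape {current.shape} != state shape {state.h.shape}")
    h_new = state.h * params.lam * (1.0 - state.o) + current
    spikes = ad.heaviside_surrogate(h_new - params.v_th, params.window)
    return LIFLayerState(h=h_new, o=spikes), spikes


def surrogate_spike(h: Tensor | np.ndarray, v_th: float, window: float = 0.5) -> Tensor:
    """Forward H(h - v_th) with H(0)=1; backward (1/(2a))·1[|h - v_th| < a]."""
    return ad.heaviside_surrogate(ad.as_tensor(h) - v_th, window)


def run_spiking_layer(
    inputs, params: LIFParams
) -> tuple[list[np.ndarray], LIFLayerState]:
    """Run K composed lif_step updates from the zero state.

    `inputs` is a sequence of K per-step synaptic drives with a common shape.
    Returns the K binary spike arrays and the final state.
    """
    inputs = list(inputs)
    if not inputs:
        raise ValueError("run_spiking_layer needs at least one drive step")
    shape = np.asarray(inputs[0]).shape
    state = LIFLayerState.zeros(shape)
    spikes = []
    for drive in inputs:
        state, s = lif_step(state, np.asarray(drive, dtype=np.float64), params)
        spikes.append(s.data)
    return spikes, state
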