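"""Plasma input functions for Patlak analysis.

The population input function is modeled as a linear rise from zero to a
peak at ``peak_time_min``, followed by a sum of decaying exponentials
(tri-exponential by default).  Both the value Cp(t) and the running integral
are available in closed form, which makes noiseless Patlak recovery exact to
machine precision.  A single multiplicative ``scale`` adapts the population
shape to a patient's image-derived blood-pool activity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class InputFunction:
    """Cp(t) = scale * [rise to peak, then sum_i A_i exp(-lambda_i (t - tp))].

    Amplitudes are on the tissue (SUV-comparable) scale at the peak time;
    decay rates are per minute.  ``peak_time_min = 0`` gives a pure
    multi-exponential from t = 0 (no rise).
    """

    amplitudes: tuple[float, ...]
    decay_rates: tuple[float, ...]
    peak_time_min: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "decay_rates", tuple(float(r) for r in self.decay_rates))
        if len(self.amplitudes) != len(self.decay_rates) or not self.amplitudes:
            raise ValueError("amplitudes and decay_rates must be equal-length, non-empty")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if any(r <= 0 for r in self.decay_rates):
            raise ValueError(f"decay rates must be positive, got {self.decay_rates}")
        if self.peak_time_min < 0:
            raise ValueError("peak time must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def is_degenerate(self) -> bool:
        """True when all amplitudes vanish (Cp identically zero)."""
        return all(a == 0 for a in self.amplitudes)

    @property
    def peak_value(self) -> float:
        return self.scale * sum(self.amplitudes)

    def value(self, t):
        """Cp(t), t in minutes (scalar or array)."""
        t = np.asarray(t, dtype=float)
        tp = self.peak_time_min
        amps = np.asarray(self.amplitudes)
        lams = np.asarray(self.decay_rates)
        peak = amps.sum()
        decay = (amps[:, None] * np.exp(-lams[:, None] * np.maximum(t.ravel() - tp, 0.0))).sum(axis=0)
        out = np.where(
            t.ravel() < tp,
            peak * np.divide(t.ravel(), tp, out=np.zeros_like(t.ravel()), where=tp > 0),
            decay,
        ).reshape(t.shape)
        out = np.where(t < 0, 0.0, out.reshape(t.shape))
        res = self.scale * out
        return float(res) if res.ndim == 0 else res

    def integral(self, t):
        """Closed-form integral of Cp from 0 to t (minutes * concentration)."""
        t = np.asarray(t, dtype=float)
        tp = self.peak_time_min
        amps = np.asarray(self.amplitudes)
        lams = np.asarray(self.decay_rates)
        peak = amps.sum()
        tr = np.clip(t, 0.0, None)
        if tp > 0:
            rise = peak * np.minimum(tr, tp) ** 2 / (2.0 * tp)
        else:
            rise = np.zeros_like(tr)
        tail_t = np.maximum(tr - tp, 0.0)
        # -expm1 avoids cancellation for small decay rates
        tail = ((amps[:, None] / lams[:, None]) * (-np.expm1(-lams[:, None] * tail_t.ravel()))).sum(axis=0)
        res = self.scale * (rise + tail.reshape(tr.shape))
        return float(res) if res.ndim == 0 else res

    def with_scale(self, scale: float) -> "InputFunction":
        """Return a copy with the absolute scale replaced."""
        return replace(self, scale=float(scale))


# a plausible FDG-like shape: fast vascular clearance, intermediate exchange,
# slow washout; arbitrary but configurable (the true population parameters are
# not public), which is immaterial for the Patlak algebra exercised here
DEFAULT_POPULATION_IF = InputFunction(
    amplitudes=(8.0, 3.0, 1.2),
    decay_rates=(2.0, 0.15, 0.01),
    peak_time_min=1.0,
)
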