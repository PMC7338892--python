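"""Learning-rate schedules shared by all online trainers.

Every synaptic/dendritic parameter has its own base rate; a single decay
profile multiplies all of them.  The default profile is the linearly
decaying, floored schedule used in the multichannel experiments:

    eta(t) = base * max(1 - slope * t, floor)

with base 0.02, slope 5e-6 and floor 0.1, which anneals from 0.02 down to
0.002 over the first 180,000 steps and stays there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LearningSchedule"]

_DECAYS = ("none", "linear-floor", "inverse-t", "inverse-sqrt-t")


@dataclass(frozen=True)
class LearningSchedule:
    """Per-parameter base learning rates and a common decay profile.

    Parameters
    ----------
    base:
        Shared base rate; any of ``eta_a .. eta_m`` left at ``None``
        defaults to it.
    eta_a, eta_b, eta_alpha, eta_beta, eta_m:
        Base rates for distal weights, proximal weights, distal and
        proximal dendritic variables, and lateral weights.
    decay:
        One of ``"none"``, ``"linear-floor"``, ``"inverse-t"``,
        ``"inverse-sqrt-t"``.
    slope, floor:
        Decay parameters.  ``linear-floor`` evaluates
        ``max(1 - slope*t, floor)``; the inverse profiles evaluate
        ``1/(1 + slope*t)`` and ``1/sqrt(1 + slope*t)``.
    """

    base: float = 0.02
    eta_a: float | None = None
    eta_b: float | None = None
    eta_alpha: float | None = None
    eta_beta: float | None = None
    eta_m: float | None = None
    decay: str = "linear-floor"
    slope: float = 5e-6
    floor: float = 0.1

    def __post_init__(self) -> None:
        if self.decay not in _DECAYS:
            raise ValueError(f"unknown decay {self.decay!r}; choose from {_DECAYS}")
        for name in ("base", "eta_a", "eta_b", "eta_alpha", "eta_beta", "eta_m"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    # -- resolved base rates -------------------------------------------------
    @property
    def rate_a(self) -> float:
        return self.base if self.eta_a is None else self.eta_a

    @property
    def rate_b(self) -> float:
        return self.base if self.eta_b is None else self.eta_b

    @property
    def rate_alpha(self) -> float:
        return self.base if self.eta_alpha is None else self.eta_alpha

    @property
    def rate_beta(self) -> float:
        return self.base if self.eta_beta is None else self.eta_beta

    @property
    def rate_m(self) -> float:
        return self.base if self.eta_m is None else self.eta_m

    # -- decay profile -------------------------------------------------------
    def factor(self, t: int) -> float:
        """Decay multiplier at step ``t`` (t = 0 is the first update)."""
        if self.decay == "none":
            return 1.0
        if self.decay == "linear-floor":
            return max(1.0 - self.slope * t, self.floor)
        if self.decay == "inverse-t":
            return 1.0 / (1.0 + self.slope * t)
        return 1.0 / np.sqrt(1.0 + self.slope * t)

    def factors(self, start: int, n: int) -> np.ndarray:
        """Vector of decay multipliers for steps ``start .. start+n-1``."""
        t = np.arange(start, start + n, dtype=np.float64)
        if self.decay == "none":
            return np.ones(n)
        if self.decay == "linear-floor":
            return np.maximum(1.0 - self.slope * t, self.floor)
        if self.decay == "inverse-t":
            return 1.0 / (1.0 + self.slope * t)
        return 1.0 / np.sqrt(1.0 + self.slope * t)

    # -- convenience constructors -------------------------------------------
    @classmethod
    def constant(cls, base: float) -> "LearningSchedule":
        """A flat schedule (no decay)."""
        return cls(base=base, decay="none")

    @classmethod
    def paper_multichannel(cls) -> "LearningSchedule":
        """The linearly floored default used by the multichannel network."""
        return cls()

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "eta_a": self.eta_a,
            "eta_b": self.eta_b,
            "eta_alpha": self.eta_alpha,
            "eta_beta": self.eta_beta,
            "eta_m": self.eta_m,
            "decay": self.decay,
            "slope": self.slope,
            "floor": self.floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LearningSchedule":
        return cls(**{k: v for k, v in d.items() if v is not None or k in ("decay",)})
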