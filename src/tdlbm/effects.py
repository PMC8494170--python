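"""Random-effect switch configurations.

A cell curve in block (k, l) is modelled as

    x(t) = alpha_1 + exp(alpha_2) * m(t - alpha_3; beta_kl) + eps(t),

with (alpha_1, alpha_2, alpha_3) ~ N3(mu, Sigma) cell-specific random
effects: an amplitude (vertical) shift, a log-scale factor, and a time
(phase) shift.  Any of the three may be switched off, which constrains it to
a point mass at zero and changes the notion of cluster: e.g. with the time
shift off, curves that differ only by a phase shift land in different
clusters.  Configurations are named by a 3-letter code, T = on, F = off, in
the order (amplitude, scale, time shift): "TFT", "FFF", ...
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RandomEffectConfig:
    on_amplitude: bool = True
    on_scale: bool = True
    on_timeshift: bool = True

    @classmethod
    def from_name(cls, name: str) -> "RandomEffectConfig":
        name = name.upper()
        if len(name) != 3 or set(name) - {"T", "F"}:
            raise ValueError(f"config name must be 3 letters of T/F, got {name!r}")
        return cls(*(c == "T" for c in name))

    @property
    def name(self) -> str:
        return "".join("T" if f else "F" for f in self.flags)

    @property
    def flags(self) -> tuple:
        return (self.on_amplitude, self.on_scale, self.on_timeshift)

    @property
    def mask(self) -> np.ndarray:
        """Boolean length-3 mask of switched-on effects."""
        return np.array(self.flags, dtype=bool)

    @property
    def n_on(self) -> int:
        return int(sum(self.flags))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: All 8 possible switch patterns, FFF first, TTT last.
ALL_CONFIGS = tuple(
    RandomEffectConfig(a, s, t)
    for a in (False, True) for s in (False, True) for t in (False, True)
)
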