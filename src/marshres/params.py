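"""Parameters and foraging modes for the hog–mussel–cordgrass model.

Mussel cover ``M`` is measured as a fraction of maximum standing crop
(``K = 1``, corresponding to roughly 10% absolute marsh surface cover).
Cordgrass cover is proportional to mussel cover (``V = q * M``). Hog
density ``H`` is a fixed forcing in relative units; time is in years.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace


class ForagingMode(str, enum.Enum):
    """How hog predation pressure on mussels depends on mussel cover.

    ``NONE``
        Haphazard trampling/consumption: per-mussel pressure constant in
        cover (Holling type I).
    ``INCOMPLETE``
        Ordinary prey depletion: per-mussel pressure falls as mussels
        become scarce (Holling type III numerator behaviour).
    ``COMPLETE``
        Depensatory focusing: hogs concentrate on remaining mussels, so
        per-mussel pressure *rises* as cover falls (saturating, type II).
    """

    NONE = "none"
    INCOMPLETE = "incomplete"
    COMPLETE = "complete"

    @classmethod
    def coerce(cls, value: "ForagingMode | str") -> "ForagingMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown foraging mode {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class ModelParams:
    """Rates and functional-response constants.

    Parameters
    ----------
    g : float
        Mussel intrinsic logistic regrowth rate (per year). Must be > 0.
    K : float
        Maximum standing crop of mussel cover. Fixed at 1 by convention.
    a : float
        Per-hog attack coefficient (cover fraction per hog per year).
    H : float
        Hog density (relative units, >= 0).
    h : float
        Half-saturation / switching constant for the saturating
        responses, as a cover fraction in (0, 1).
    q : float
        Cordgrass-to-mussel cover proportionality constant.
    """

    g: float = 1.0
    K: float = field(default=1.0)
    a: float = 1.0
    H: float = 0.0
    h: float = 0.2
    q: float = 1.0

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError(f"g must be > 0, got {self.g}")
        if self.K != 1.0:
            raise ValueError("K is fixed at 1 (cover is scaled to standing crop)")
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if self.H < 0:
            raise ValueError(f"H must be >= 0, got {self.H}")
        if not 0 < self.h < 1:
            raise ValueError(f"h must lie in (0, 1), got {self.h}")
        if not self.q > 0:
            raise ValueError(f"q must be > 0, got {self.q}")

    def with_hogs(self, H: float) -> "ModelParams":
        """Return a copy at a different hog density."""
        return replace(self, H=H)
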