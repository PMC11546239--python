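"""Daily fluid-balance intervention strategies.

A strategy is a *truncation* (clamp) of the natural daily net fluid balance:
whenever the day's natural balance falls inside ``[lower, upper]`` it is left
alone, otherwise it is set to the nearest bound.  ``(-inf, +inf)`` is the
natural course (no intervention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schema import ValidationError


@dataclass(frozen=True)
class InterventionSpec:
    """A daily net-fluid-balance range strategy, in mL.

    ``lower`` / ``upper`` may be ``-inf`` / ``+inf``; equal bounds denote a
    fixed daily balance.
    """

    lower: float = -math.inf
    upper: float = math.inf
    label: str | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError(f"intervention lower ({self.lower}) > upper ({self.upper})")
        if self.label is None:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.is_natural_course:
            return "natural course"
        lo = "-inf" if math.isinf(self.lower) else f"{self.lower:g}"
        hi = "+inf" if math.isinf(self.upper) else f"{self.upper:g}"
        return f"[{lo}, {hi}] mL"

    @property
    def is_natural_course(self) -> bool:
        return math.isinf(self.lower) and math.isinf(self.upper)

    def apply(self, fluid_ml: np.ndarray) -> np.ndarray:
        """Clamp an array of natural daily balances (mL) into the range."""
        return np.clip(fluid_ml, self.lower, self.upper)


NATURAL_COURSE = InterventionSpec()
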