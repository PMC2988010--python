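"""Right-continuous step functions used for survival curves and cumulative hazards."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous piecewise-constant function of time.

    ``f(t) = initial_value`` for ``t < times[0]`` and ``f(t) = values[i]``
    for ``times[i] <= t < times[i+1]``.  Jump times must be strictly
    increasing.  Left limits are queryable via :meth:`left_limit`, which is
    what survival estimators need at event times.

    Parameters
    ----------
    times
        Strictly increasing jump locations.
    values
        Value taken on ``[times[i], times[i+1])``.
    initial_value
        Value on ``[0, times[0])``; defaults to 1.0 (survival convention).
    se
        Optional pointwise standard errors aligned with ``values``.
    """

    times: np.ndarray
    values: np.ndarray
    initial_value: float = 1.0
    se: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.se is not None:
            s = np.asarray(self.se, dtype=float)
            if s.shape != v.shape:
                raise ValueError("se must align with values")
            object.__setattr__(self, "se", s)

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.initial_value)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side=side) - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.initial_value)
        return out if out.ndim else float(out)

    def __call__(self, t):
        """Evaluate the function at ``t`` (scalar or array), right-continuously."""
        return self._eval(t, "right")

    def left_limit(self, t):
        """Evaluate ``f(t-)``: the value immediately before ``t``."""
        return self._eval(t, "left")

    @property
    def n_jumps(self) -> int:
        return int(self.times.size)

    def to_frame(self):
        import pandas as pd

        d = {"time": self.times, "value": self.values}
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)
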