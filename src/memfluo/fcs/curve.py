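"""Container for measured or simulated autocorrelation curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CorrelationCurve"]


@dataclass
class CorrelationCurve:
    """An autocorrelation curve G(τ) with optional per-lag standard errors.

    lags are seconds (strictly increasing, > 0); values are the
    dimensionless correlation with the G(τ)→1 baseline convention;
    ``duration`` is the length of the underlying intensity trace and
    ``mean_intensity`` its mean count rate in counts/s.
    """

    lags: np.ndarray
    values: np.ndarray
    se: np.ndarray | None = None
    duration: float = 0.0
    mean_intensity: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.values.shape:
            raise ValueError("lags and values must be 1D arrays of equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing and > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.lags.shape:
                raise ValueError("se must match lags in length")
            if np.any(self.se < 0):
                raise ValueError("se must be >= 0")

    def __len__(self) -> int:
        return self.lags.size

    def restrict(self, tau_min: float = 0.0, tau_max: float = np.inf) -> "CorrelationCurve":
        """Return the sub-curve with tau_min <= τ <= tau_max."""
        m = (self.lags >= tau_min) & (self.lags <= tau_max)
        return CorrelationCurve(
            self.lags[m],
            self.values[m],
            None if self.se is None else self.se[m],
            self.duration,
            self.mean_intensity,
            dict(self.meta),
        )
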