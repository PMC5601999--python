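"""Software multiple-tau autocorrelator for photon-count traces.

Mirrors hardware-correlator conventions: a linear block of ``m`` lags
per level, factor-2 coarsening of the trace between levels, and
symmetric normalization (the product sum at lag k is divided by the
means of the leading and trailing sub-traces), which makes G(τ)→1 for
an uncorrelated signal.  The first reported lag defaults to two bin
widths to keep shot-noise/afterpulsing artifacts out of the curve.
"""

from __future__ import annotations

import numpy as np

from .curve import CorrelationCurve

__all__ = ["correlate_trace", "DegenerateTraceError", "MIN_TRACE_BINS"]

MIN_TRACE_BINS = 2**14


class DegenerateTraceError(ValueError):
    """Raised for traces that carry no signal (e.g. all zeros)."""


def _level_correlation(z: np.ndarray, ks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation values at integer lags ``ks`` for one coarsening level."""
    out = np.empty(ks.size)
    ok = np.ones(ks.size, dtype=bool)
    n = z.size
    for i, k in enumerate(ks):
        if k >= n - 1:
            ok[i] = False
            continue
        head = z[: n - k]
        tail = z[k:]
        m_head = head.mean()
        m_tail = tail.mean()
        if m_head <= 0 or m_tail <= 0:
            ok[i] = False
            continue
        out[i] = float(head @ tail) / (n - k) / (m_head * m_tail)
    return out, ok


def correlate_trace(
    counts: np.ndarray,
    bin_width: float,
    m: int = 16,
    min_lag_bins: int = 2,
) -> CorrelationCurve:
    """Multiple-tau autocorrelation of a binned photon-count trace.

    Parameters
    ----------
    counts : array of counts per bin (length >= 2^14).
    bin_width : bin width in seconds.
    m : lags per block before each factor-2 coarsening.
    min_lag_bins : discard lags shorter than this many bins.

    Returns
    -------
    CorrelationCurve with the "+1" baseline convention and the trace's
    mean intensity in counts/s.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("trace must be 1D")
    if counts.size < MIN_TRACE_BINS:
        raise ValueError(f"trace too short: {counts.size} < {MIN_TRACE_BINS} bins")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not np.any(counts > 0):
        raise DegenerateTraceError("all-zero trace has no defined correlation")

    lags: list[np.ndarray] = []
    values: list[np.ndarray] = []

    z = counts.copy()
    scale = 1  # bins per element at the current level
    level = 0
    while z.size >= 2 * m:
        if level == 0:
            ks = np.arange(1, m)
        else:
            ks = np.arange(m // 2, m)
        g, ok = _level_correlation(z, ks)
        tau = ks * scale * bin_width
        keep = ok & (ks * scale >= min_lag_bins)
        lags.append(tau[keep])
        values.append(g[keep])
        # coarsen: average adjacent bins (normalization is scale-invariant)
        n2 = (z.size // 2) * 2
        z = 0.5 * (z[0:n2:2] + z[1:n2:2])
        scale *= 2
        level += 1

    lag = np.concatenate(lags)
    val = np.concatenate(values)
    order = np.argsort(lag)
    return CorrelationCurve(
        lags=lag[order],
        values=val[order],
        duration=counts.size * bin_width,
        mean_intensity=counts.mean() / bin_width,
    )


def direct_correlation(counts: np.ndarray, bin_width: float, max_lag_bins: int) -> CorrelationCurve:
    """Brute-force linear-lag autocorrelation (oracle for correlate_trace).

    O(N·max_lag) — intended for short traces in tests only.
    """
    counts = np.asarray(counts, dtype=float)
    ks = np.arange(1, max_lag_bins + 1)
    g, ok = _level_correlation(counts, ks)
    return CorrelationCurve(
        lags=ks[ok] * bin_width,
        values=g[ok],
        duration=counts.size * bin_width,
        mean_intensity=counts.mean() / bin_width,
    )
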