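"""Real Fourier series utilities for periodic cardiac waveforms.

A series of order ``K`` with period ``T`` is stored as a coefficient array
whose last axis has length ``2K + 1`` and layout::

    [mean, a_1 .. a_K, b_1 .. b_K]

so that ``f(t) = mean + sum_k a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T)``.
Leading axes are arbitrary (e.g. per-vertex, per-coordinate), which lets the
same routines drive scalar volume curves and whole-surface displacement
models.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "n_coeffs",
    "order_of",
    "evaluate",
    "derivative",
    "fit",
    "design_matrix",
]


def n_coeffs(order: int) -> int:
    """Number of coefficients of a real series of the given harmonic order."""
    return 2 * int(order) + 1


def order_of(coeffs: np.ndarray) -> int:
    """Harmonic order K implied by the last axis of a coefficient array."""
    n = np.asarray(coeffs).shape[-1]
    if n % 2 != 1:
        raise ValueError(f"coefficient axis length {n} is not odd (mean + K cos + K sin)")
    return (n - 1) // 2


def design_matrix(t: np.ndarray, period: float, order: int) -> np.ndarray:
    """Evaluation matrix ``M`` with ``f(t) = M @ coeffs`` for scalar series.

    Shape ``(len(t), 2*order + 1)``.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k = np.arange(1, order + 1)
    ang = 2.0 * np.pi * np.outer(t, k) / period
    return np.concatenate(
        [np.ones((t.size, 1)), np.cos(ang), np.sin(ang)], axis=1
    )


def evaluate(coeffs: np.ndarray, t, period: float):
    """Evaluate the series at time(s) ``t`` (exactly ``period``-periodic).

    ``coeffs`` may have leading axes; the result has shape
    ``coeffs.shape[:-1]`` for scalar ``t`` or ``t.shape + coeffs.shape[:-1]``
    for array ``t``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    order = order_of(coeffs)
    scalar = np.isscalar(t) or np.ndim(t) == 0
    m = design_matrix(t, period, order)  # (nt, 2K+1)
    out = np.tensordot(m, coeffs, axes=([1], [coeffs.ndim - 1]))
    return out[0] if scalar else out


def derivative(coeffs: np.ndarray, period: float) -> np.ndarray:
    """Coefficients of the time derivative of the series (same layout).

    d/dt [a_k cos + b_k sin] = (2 pi k / T) [b_k cos - a_k sin].
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    coeffs = np.asarray(coeffs, dtype=float)
    order = order_of(coeffs)
    out = np.zeros_like(coeffs)
    if order == 0:
        return out
    k = np.arange(1, order + 1)
    w = 2.0 * np.pi * k / period
    a = coeffs[..., 1 : order + 1]
    b = coeffs[..., order + 1 :]
    out[..., 1 : order + 1] = w * b
    out[..., order + 1 :] = -w * a
    return out


def fit(t: np.ndarray, samples: np.ndarray, period: float, order: int) -> np.ndarray:
    """Least-squares Fourier fit of periodic samples.

    Parameters
    ----------
    t : (n,) sample times.
    samples : (n, ...) sample values; trailing axes are fitted independently.
    period, order : series period and harmonic order K.

    Returns
    -------
    coeffs : (..., 2K+1) array. With ``n == 2K+1`` distinct times per period
        the system is square and the fit interpolates the samples exactly
        (to numerical precision).

    Raises
    ------
    ValueError : if ``n < 2K+1`` (underdetermined).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    samples = np.asarray(samples, dtype=float)
    nc = n_coeffs(order)
    if t.size < nc:
        raise ValueError(
            f"{t.size} samples cannot determine a Fourier series of order {order} "
            f"({nc} coefficients); need n_samples >= 2K+1"
        )
    m = design_matrix(t, period, order)
    flat = samples.reshape(t.size, -1)
    coeffs, *_ = np.linalg.lstsq(m, flat, rcond=None)
    # move coefficient axis last: (nc, ...) -> (..., nc)
    return np.moveaxis(coeffs.reshape((nc,) + samples.shape[1:]), 0, -1)
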