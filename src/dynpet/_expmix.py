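"""Closed-form evaluation and integration of exponential-polynomial mixtures.

A mixture is a set of terms ``c * u**n * exp(-rate * u)`` with n in {0, 1, 2},
supported on u >= 0.  Tissue curves produced by convolving a compartmental
impulse response with a multi-exponential input function are exactly of this
form, so frame averages can be computed without quadrature.

Stability: the scaled integrals phi_n(x) = integral_0^1 s**n exp(-x*s) ds are
computed with ``expm1`` or truncated series for small x to avoid catastrophic
cancellation near degenerate rate pairs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ExpMixture", "integrate_mixture", "evaluate_mixture"]

_SMALL_X = 1e-3


def _phi0(x: np.ndarray) -> np.ndarray:
    # integral_0^1 exp(-x s) ds = (1 - e^-x)/x
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-12
    xs = np.where(small, 1.0, x)
    out = -np.expm1(-xs) / xs
    return np.where(small, 1.0 - x / 2.0, out)


def _phi1(x: np.ndarray) -> np.ndarray:
    # integral_0^1 s exp(-x s) ds = (1 - (1+x) e^-x)/x^2
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SMALL_X
    xs = np.where(small, 1.0, x)
    exact = (1.0 - (1.0 + xs) * np.exp(-xs)) / xs**2
    series = 0.5 - x / 3.0 + x**2 / 8.0 - x**3 / 30.0
    return np.where(small, series, exact)


def _phi2(x: np.ndarray) -> np.ndarray:
    # integral_0^1 s^2 exp(-x s) ds = (2 - (2+2x+x^2) e^-x)/x^3
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SMALL_X
    xs = np.where(small, 1.0, x)
    exact = (2.0 - (2.0 + 2.0 * xs + xs**2) * np.exp(-xs)) / xs**3
    series = 1.0 / 3.0 - x / 4.0 + x**2 / 10.0 - x**3 / 36.0
    return np.where(small, series, exact)


class ExpMixture:
    """A sum of ``c * u**n * exp(-rate*u)`` terms on u >= 0."""

    __slots__ = ("coef", "rate", "order")

    def __init__(self, coef, rate, order):
        self.coef = np.asarray(coef, dtype=float)
        self.rate = np.asarray(rate, dtype=float)
        self.order = np.asarray(order, dtype=int)
        if not (self.coef.shape == self.rate.shape == self.order.shape):
            raise ValueError("mixture term arrays must share a shape")
        if np.any(self.rate < 0):
            raise ValueError("mixture rates must be nonnegative")
        if np.any((self.order < 0) | (self.order > 2)):
            raise ValueError("polynomial order must be 0, 1 or 2")

    @classmethod
    def from_terms(cls, terms) -> "ExpMixture":
        if len(terms) == 0:
            return cls([], [], [])
        c, r, n = zip(*terms)
        return cls(c, r, n)

    def scaled(self, factor: float) -> "ExpMixture":
        return ExpMixture(self.coef * factor, self.rate, self.order)

    def __add__(self, other: "ExpMixture") -> "ExpMixture":
        return ExpMixture(
            np.concatenate([self.coef, other.coef]),
            np.concatenate([self.rate, other.rate]),
            np.concatenate([self.order, other.order]),
        )


def evaluate_mixture(mix: ExpMixture, u: np.ndarray) -> np.ndarray:
    """Pointwise value of the mixture at u (zero for u < 0)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    c = mix.coef[:, None]
    lam = mix.rate[:, None]
    n = mix.order[:, None]
    uu = np.clip(u[None, :], 0.0, None)
    vals = c * uu**n * np.exp(-lam * uu)
    out = vals.sum(axis=0)
    out[u < 0] = 0.0
    return out


def integrate_mixture(mix: ExpMixture, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact integral of the mixture over each interval [a_i, b_i], a_i >= 0.

    Intervals with b <= a contribute zero.  Shapes of ``a`` and ``b`` must
    match; the result has the same shape.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("interval bounds must share a shape")
    if mix.coef.size == 0:
        return np.zeros_like(a)
    delta = np.clip(b - a, 0.0, None)[None, :]  # (1, F)
    aa = a[None, :]
    lam = mix.rate[:, None]
    c = mix.coef[:, None]
    n = mix.order[:, None]
    x = lam * delta
    ea = np.exp(-lam * aa)
    p0 = _phi0(x)
    p1 = _phi1(x)
    e0 = delta * p0
    e1 = aa * e0 + delta**2 * p1
    e2 = aa**2 * e0 + 2.0 * aa * delta**2 * p1 + delta**3 * _phi2(x)
    en = np.where(n == 0, e0, np.where(n == 1, e1, e2))
    return (c * ea * en).sum(axis=0)
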