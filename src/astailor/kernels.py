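"""Kernel functions and bandwidth rules shared by all estimators.

The Epanechnikov kernel K(u) = 0.75(1 - u^2) 1{|u| <= 1} is used throughout:
it is a second-order kernel with compact support, which matches the
bandwidth rates h = C_b n^{-1/5} (one-dimensional smoothing over biopsy
times) and h~ = C_b n^{-1/6} (two-dimensional smoothing over adjacent
biopsy-pair times).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BandwidthSpec", "kernel_1d", "kernel_2d", "boundary_mass_fraction"]


@dataclass(frozen=True)
class BandwidthSpec:
    """Bandwidths derived from a single constant C_b and the sample size.

    h scales as n^{-1/5} (univariate rate) and h_tilde as n^{-1/6}
    (bivariate rate), so h < h_tilde for n > 1 at equal C_b.
    """

    C_b: float
    n: int

    def __post_init__(self):
        if self.C_b <= 0:
            raise ValueError(f"C_b must be positive, got {self.C_b}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def h(self) -> float:
        return self.C_b * self.n ** (-1 / 5)

    @property
    def h_tilde(self) -> float:
        return self.C_b * self.n ** (-1 / 6)


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)


def kernel_1d(x, h: float):
    """Scaled univariate Epanechnikov kernel K_h(x) = K(x/h)/h.

    Nonnegative, symmetric, zero outside [-h, h], integrates to one.
    """
    if h <= 0:
        raise ValueError(f"bandwidth h must be positive, got {h}")
    return _epanechnikov(np.asarray(x, dtype=float) / h) / h


def kernel_2d(x1, x2, h: float):
    """Scaled product Epanechnikov kernel K~_h(x1, x2) = K(x1/h)K(x2/h)/h^2."""
    if h <= 0:
        raise ValueError(f"bandwidth h must be positive, got {h}")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return _epanechnikov(x1 / h) * _epanechnikov(x2 / h) / (h * h)


def _epanechnikov_cdf(u: np.ndarray) -> np.ndarray:
    # closed-form CDF of K on [-1, 1]
    u = np.clip(np.asarray(u, dtype=float), -1.0, 1.0)
    return 0.25 * (2.0 + 3.0 * u - u**3)


def boundary_mass_fraction(t: float, h: float, lo: float, hi: float) -> float:
    """Fraction of the kernel mass centred at t falling outside [lo, hi]."""
    inside = _epanechnikov_cdf((hi - t) / h) - _epanechnikov_cdf((lo - t) / h)
    return float(1.0 - inside)


def warn_if_boundary(t: float, h: float, lo: float, hi: float, what: str = "kernel"):
    """Warn when more than 20% of the kernel mass leaves the observed range."""
    frac = boundary_mass_fraction(t, h, lo, hi)
    if frac > 0.20:
        warnings.warn(
            f"{what} at t={t:.1f} (h={h:.2f}): {100 * frac:.0f}% of kernel mass "
            f"falls outside the observed biopsy-time range [{lo:.1f}, {hi:.1f}]",
            stacklevel=3,
        )
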