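"""Dispersal kernels, their d-dimensional mass, and effective neighbors.

A kernel f(x) gives the colonization strength between two patches at scaled
distance x = r / xi, where xi is the typical dispersal length.  Supported
families (unit-scale forms; any other scale constant is absorbed into xi):

* ``rectangular`` -- f(x) = 1 for x < 1, else 0 (random-geometric-graph case)
* ``gaussian``    -- f(x) = exp(-x^2 / 2)
* ``exponential`` -- f(x) = exp(-x)
* ``ring``        -- f(x) = exp(-(x - mu)^2 / (2 s^2)), a hump peaked away
  from the origin, modelling dispersal that is most effective at an
  intermediate distance (e.g. wind- or animal-dispersed seeds).

The kernel mass ``G_f(d) = \\int_{R^d} f(|u|) du`` is the dimensionless
volume reached by dispersal; with patch density N / L^d it yields the
expected number of effective neighbors ``n_e = (N / L^d) G_f(d) xi^d``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

__all__ = [
    "KernelSpec",
    "KERNEL_FAMILIES",
    "evaluate_kernel",
    "kernel_mass",
    "kernel_mass_quadrature",
    "effective_neighbors_analytic",
    "effective_neighbors_mc",
    "xi_for_effective_neighbors",
]

KERNEL_FAMILIES = ("rectangular", "gaussian", "exponential", "ring")


@dataclass(frozen=True)
class KernelSpec:
    """A dispersal-kernel family plus its parameters.

    ``dispersal_length`` is xi, in the same length units as the landscape.
    ``ring_center`` (mu) and ``ring_width`` (s) are in scaled-distance units
    and only meaningful for the ring family.
    """

    family: str
    dispersal_length: float
    ring_center: float = 1.0
    ring_width: float = 0.2

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of {KERNEL_FAMILIES}"
            )
        if self.dispersal_length < 0:
            raise ValueError(f"dispersal length must be nonnegative, got {self.dispersal_length}")
        if self.family == "ring" and (self.ring_center <= 0 or self.ring_width <= 0):
            raise ValueError("ring kernel requires positive ring_center and ring_width")

    def __call__(self, x) -> np.ndarray:
        return evaluate_kernel(self, x)


def evaluate_kernel(kernel: KernelSpec, x) -> np.ndarray | float:
    """Evaluate f at scaled distance(s) x >= 0.

    The rectangular kernel uses the open-interval convention f(1) = 0; the
    choice at the single point x = 1 has measure zero for continuous
    landscapes.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("scaled distance must be nonnegative")
    fam = kernel.family
    if fam == "rectangular":
        out = (x < 1.0).astype(float)
    elif fam == "gaussian":
        out = np.exp(-0.5 * x * x)
    elif fam == "exponential":
        out = np.exp(-x)
    else:  # ring
        z = (x - kernel.ring_center) / kernel.ring_width
        out = np.exp(-0.5 * z * z)
    return out if out.ndim else float(out)


def _surface_area(d: int) -> float:
    """Surface area of the unit (d-1)-sphere: S_{d-1} = 2 pi^{d/2} / Gamma(d/2)."""
    return 2.0 * math.pi ** (d / 2.0) / special.gamma(d / 2.0)


def kernel_mass_quadrature(kernel: KernelSpec, d: int, rtol: float = 1e-8) -> float:
    """G_f(d) by adaptive radial quadrature of S_{d-1} x^{d-1} f(x).

    The integration interval is truncated where an analytic bound puts the
    remaining tail mass below 1e-12.
    """
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got d={d}")
    fam = kernel.family
    if fam == "rectangular":
        upper = 1.0
    elif fam == "gaussian":
        upper = 12.0  # x^{d-1} exp(-x^2/2) tail beyond 12 is < 1e-25 for d <= 3
    elif fam == "exponential":
        upper = 60.0 + 10.0 * d
    else:  # ring: Gaussian bump, 15 widths covers the tail
        upper = kernel.ring_center + 15.0 * kernel.ring_width

    def integrand(x: float) -> float:
        return x ** (d - 1) * float(evaluate_kernel(kernel, x))

    val, err = integrate.quad(integrand, 0.0, upper, epsrel=rtol, epsabs=0.0, limit=200)
    if not math.isfinite(val):
        raise ValueError(f"kernel mass diverges for family={fam}, d={d}")
    return _surface_area(d) * val


def kernel_mass(kernel: KernelSpec | str, d: int) -> float:
    """Kernel mass G_f(d) = integral of f(|u|) over R^d.

    Closed forms: gaussian (2 pi)^{d/2}; rectangular the unit-ball volume
    pi^{d/2} / Gamma(d/2 + 1); exponential S_{d-1} Gamma(d).  The ring family
    falls back to radial quadrature (relative tolerance 1e-8).
    """
    if isinstance(kernel, str):
        kernel = KernelSpec(family=kernel, dispersal_length=1.0)
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got d={d}")
    fam = kernel.family
    if fam == "gaussian":
        return (2.0 * math.pi) ** (d / 2.0)
    if fam == "rectangular":
        return math.pi ** (d / 2.0) / special.gamma(d / 2.0 + 1.0)
    if fam == "exponential":
        return _surface_area(d) * special.gamma(d)
    return kernel_mass_quadrature(kernel, d)


def effective_neighbors_analytic(n: int, d: int, L: float, kernel: KernelSpec) -> float:
    """Analytic effective-neighbor number n_e = (N / L^d) G_f(d) xi^d.

    Valid in the regime L >> xi (edge effects negligible); a warning is
    emitted when L < 10 xi.
    """
    if n < 1 or d < 1 or L <= 0:
        raise ValueError("need n >= 1, d >= 1, L > 0")
    xi = kernel.dispersal_length
    if xi == 0.0:
        return 0.0
    if L < 10.0 * xi:
        warnings.warn(
            f"L = {L} is not large compared to xi = {xi}; the analytic n_e "
            "ignores edge effects and may overestimate the empirical row sum",
            stacklevel=2,
        )
    return (n / L**d) * kernel_mass(kernel, d) * xi**d


def effective_neighbors_mc(
    n: int,
    d: int,
    L: float,
    kernel: KernelSpec,
    n_samples: int = 200_000,
    seed: int | None = None,
) -> float:
    """Effective neighbors by Monte Carlo integration over the finite box.

    Estimates ``(N - 1) E[f(|x - y| / xi)]`` for independent uniform points
    x, y in [0, L]^d.  Unlike the asymptotic formula this accounts for hard
    edges, which depress n_e when xi is not tiny compared to L; it converges
    to :func:`effective_neighbors_analytic` as xi / L -> 0.
    """
    if n < 1 or d < 1 or L <= 0:
        raise ValueError("need n >= 1, d >= 1, L > 0")
    xi = kernel.dispersal_length
    if xi == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, L, size=(n_samples, d))
    y = rng.uniform(0.0, L, size=(n_samples, d))
    r = np.linalg.norm(x - y, axis=1)
    return (n - 1) * float(np.mean(evaluate_kernel(kernel, r / xi)))


def xi_for_effective_neighbors(
    target: float, n: int, d: int, L: float, family: str = "gaussian", **kw
) -> float:
    """Dispersal length xi giving a requested analytic n_e (inverse of n_e)."""
    if target <= 0:
        raise ValueError("target n_e must be positive")
    G = kernel_mass(KernelSpec(family=family, dispersal_length=1.0, **kw), d)
    return (target * L**d / (n * G)) ** (1.0 / d)
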