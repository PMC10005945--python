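"""Gumbel extremes of the annual maximum CWD and conversion to rooting depth.

The magnitude of the CWD reached with a return period of T years, S_CWDXT,
follows from a Gumbel (type-I extreme value) fit to the annual maximum CWD
values:

    S_CWDXT = mu - beta * ln(-ln(1 - 1/T))

S_CWDXT is translated into an apparent rooting depth z_CWDXT as the depth
whose integrated plant-available water-holding capacity (WHC, field capacity
minus wilting point per unit depth) equals the storage: a two-layer profile
with a topsoil of fixed thickness (default 30 cm) over a uniform subsoil
extending indefinitely below.  The pedotransfer function that maps soil
texture to WHC is pluggable; the default follows the widely used
Saxton-Rawls regression form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

EULER_GAMMA = float(np.euler_gamma)


class DegenerateFitError(ValueError):
    """Raised when the annual maxima carry no spread to fit."""


@dataclass(frozen=True)
class GumbelParams:
    """Location/scale of a fitted Gumbel distribution with standard errors."""

    location_mu: float
    scale_beta: float
    n_years: int
    se_mu: float = np.nan
    se_beta: float = np.nan

    def __post_init__(self) -> None:
        if not self.scale_beta > 0:
            raise ValueError("scale_beta must be positive")

    def return_level(self, t_return: float) -> float:
        return return_level(self, t_return)


@dataclass(frozen=True)
class SoilProfile:
    """Two-layer plant-available water-holding-capacity profile.

    WHC values are volumetric (mm water per mm depth, in (0, 1)); the
    subsoil extends indefinitely below ``topsoil_thickness`` (mm).
    """

    topsoil_whc: float
    subsoil_whc: float
    topsoil_thickness: float = 300.0

    def __post_init__(self) -> None:
        for name in ("topsoil_whc", "subsoil_whc"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.topsoil_thickness > 0:
            raise ValueError("topsoil_thickness must be positive")

    @property
    def topsoil_capacity(self) -> float:
        """Total plant-available water held by the topsoil layer (mm)."""
        return self.topsoil_whc * self.topsoil_thickness


def fit_gumbel(annual_maxima, method: str = "mle") -> GumbelParams:
    """Fit a Gumbel distribution to annual maxima.

    ``method`` is ``"mle"`` (maximum likelihood, the default) or
    ``"lmom"`` (L-moments).  Standard errors use the closed-form asymptotic
    Fisher information of the Gumbel (exact for MLE, reported for both
    estimators).  NaN entries (e.g. years lost to runaway events) are
    dropped first.
    """
    x = np.asarray(annual_maxima, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 5:
        raise ValueError(f"need >= 5 annual maxima, got {n}")
    if np.ptp(x) <= 0:
        raise DegenerateFitError("annual maxima have zero spread")

    if method == "mle":
        mu, beta = stats.gumbel_r.fit(x)
    elif method == "lmom":
        xs = np.sort(x)
        i = np.arange(1, n + 1)
        l1 = xs.mean()
        b1 = np.sum((i - 1) / (n - 1) * xs) / n
        l2 = 2.0 * b1 - l1
        beta = l2 / np.log(2.0)
        mu = l1 - EULER_GAMMA * beta
    else:
        raise ValueError(f"unknown method {method!r}")

    # asymptotic variances from the Gumbel Fisher information
    se_beta = beta * np.sqrt(6.0 / np.pi**2 / n)
    se_mu = beta * np.sqrt((1.0 + 6.0 * (1.0 - EULER_GAMMA) ** 2 / np.pi**2) / n)
    return GumbelParams(
        location_mu=float(mu),
        scale_beta=float(beta),
        n_years=n,
        se_mu=float(se_mu),
        se_beta=float(se_beta),
    )


def return_level(params: GumbelParams, t_return) -> float | np.ndarray:
    """Gumbel return level: value exceeded once in ``t_return`` years on average.

    Closed form ``mu - beta * ln(-ln(1 - 1/T))``; strictly increasing in T.
    Requires T > 1.
    """
    t = np.asarray(t_return, dtype=float)
    if np.any(t <= 1.0):
        raise ValueError("t_return must exceed 1 year")
    out = params.location_mu - params.scale_beta * np.log(-np.log(1.0 - 1.0 / t))
    return float(out) if np.isscalar(t_return) else out


def whc_from_texture(
    sand_frac: float,
    clay_frac: float,
    organic_frac: float = 0.0,
    pedotransfer=None,
) -> float:
    """Plant-available WHC (mm water per mm depth) from soil texture.

    ``pedotransfer``, when given, is any callable
    ``f(sand_frac, clay_frac, organic_frac) -> whc`` and is used verbatim
    (plug-in contract).  The default is the Saxton-Rawls regression for
    volumetric water content at field capacity (-33 kPa) minus wilting
    point (-1500 kPa), with the result clipped into (0, 0.35).
    Fractions are by mass, in [0, 1], sand + clay <= 1.
    """
    for name, v in (("sand_frac", sand_frac), ("clay_frac", clay_frac),
                    ("organic_frac", organic_frac)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if sand_frac + clay_frac > 1.0 + 1e-12:
        raise ValueError("sand_frac + clay_frac must not exceed 1")

    if pedotransfer is not None:
        return float(pedotransfer(sand_frac, clay_frac, organic_frac))

    s, c = sand_frac, clay_frac
    om = 100.0 * organic_frac  # regression expects percent organic matter

    th1500t = (-0.024 * s + 0.487 * c + 0.006 * om
               + 0.005 * s * om - 0.013 * c * om + 0.068 * s * c + 0.031)
    th1500 = th1500t + (0.14 * th1500t - 0.02)
    th33t = (-0.251 * s + 0.195 * c + 0.011 * om
             + 0.006 * s * om - 0.027 * c * om + 0.452 * s * c + 0.299)
    th33 = th33t + (1.283 * th33t**2 - 0.374 * th33t - 0.015)
    whc = th33 - th1500
    return float(np.clip(whc, 1e-3, 0.35 - 1e-3))


def storage_to_depth(s: float, profile: SoilProfile) -> float:
    """Depth z (mm) whose integrated WHC equals the storage ``s`` (mm).

    Exact piecewise-linear inverse of the two-layer profile: the topsoil is
    filled first, the remainder maps into the uniform subsoil.
    """
    if s < 0:
        raise ValueError("storage must be non-negative")
    cap = profile.topsoil_capacity
    if s <= cap:
        return s / profile.topsoil_whc
    return profile.topsoil_thickness + (s - cap) / profile.subsoil_whc


def depth_to_storage(z: float, profile: SoilProfile) -> float:
    """Plant-available storage (mm) integrated over the top ``z`` mm of soil."""
    if z < 0:
        raise ValueError("depth must be non-negative")
    if z <= profile.topsoil_thickness:
        return z * profile.topsoil_whc
    return profile.topsoil_capacity + (z - profile.topsoil_thickness) * profile.subsoil_whc
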