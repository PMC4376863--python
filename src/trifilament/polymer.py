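"""Force-extension laws for titin's serial compartments.

Two polymer elasticity models are provided:

* a standard worm-like chain (WLC) used for folded and unfolded
  immunoglobulin (IG) domains, where force diverges as the end-to-end
  extension approaches the contour length, and
* an extensible ("modified") WLC used for the PEVK segment, which adds an
  enthalpic stretching term with elastic modulus ``K_0`` so that the
  end-to-end length may exceed the contour length at high force.

Both laws are strictly increasing in extension and are provided with exact
inverses (extension as a function of force), which the serial-chain solver
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kbt

__all__ = [
    "WLCParams",
    "ExtensibleWLCParams",
    "wlc_force",
    "wlc_extension",
    "ewlc_force",
    "ewlc_extension",
]


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters.

    Parameters
    ----------
    persistence_length
        Bending stiffness length scale in nm; scales the force.
    contour_length
        Maximum end-to-end length in nm; sets the divergence point.
    temperature
        Absolute temperature in K.
    """

    persistence_length: float
    contour_length: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError(
                f"persistence_length must be > 0, got {self.persistence_length}"
            )
        if self.contour_length <= 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def force_scale(self) -> float:
        """k_B T / persistence_length in pN."""
        return kbt(self.temperature) / self.persistence_length


@dataclass(frozen=True)
class ExtensibleWLCParams(WLCParams):
    """WLC parameters plus an enthalpic elastic modulus (pN)."""

    elastic_modulus: float = 75.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.elastic_modulus <= 0:
            raise ValueError(
                f"elastic_modulus must be > 0, got {self.elastic_modulus}"
            )


def _wlc_shape(u):
    """Dimensionless WLC force 1/(4(1-u)^2) - 1/4 + u for fractional extension u."""
    return 0.25 / (1.0 - u) ** 2 - 0.25 + u


def _wlc_shape_prime(u):
    return 1.0 + 0.5 / (1.0 - u) ** 3


def _wlc_shape_inverse(c):
    """Invert the dimensionless WLC law: find u in [0, 1) with shape(u) = c.

    The shape function is strictly increasing and convex on [0, 1), so
    Newton started from an upper bound of the root converges monotonically
    downward; two analytic upper bounds (shape >= 1.5u and
    shape >= 1/(4(1-u)^2) - 1/4) provide the start.  Vectorised.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("dimensionless force must be >= 0")
    u = np.minimum(c / 1.5, 1.0 - 0.5 / np.sqrt(c + 0.25))
    u = np.clip(u, 0.0, 1.0 - 1e-16)
    for _ in range(100):
        du = (_wlc_shape(u) - c) / _wlc_shape_prime(u)
        u = np.clip(u - du, 0.0, 1.0 - 1e-16)
        if np.max(np.abs(du)) < 1e-15:
            break
    return u


def wlc_force(extension, params: WLCParams):
    """WLC force (pN) at a given end-to-end ``extension`` (nm).

    Raises
    ------
    ValueError
        If extension is negative or >= contour length (the chain solvers
        must stay inside the bracket; failing loudly beats returning inf).
    """
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be >= 0")
    if np.any(x >= params.contour_length):
        raise ValueError(
            f"extension must be < contour_length ({params.contour_length} nm)"
        )
    out = params.force_scale * _wlc_shape(x / params.contour_length)
    return out if out.ndim else float(out)


def wlc_extension(force, params: WLCParams):
    """Inverse WLC: end-to-end extension (nm) at a given ``force`` (pN)."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    u = _wlc_shape_inverse(f / params.force_scale)
    out = params.contour_length * u
    return out if out.ndim else float(out)


def ewlc_force(extension, params: ExtensibleWLCParams):
    """Extensible-WLC force (pN) at end-to-end ``extension`` (nm).

    Solves the implicit law in which the entropic WLC shape is evaluated at
    the effective fractional extension ``u = x/cl - f/K_0``.  The extension
    may exceed the contour length; the enthalpic term absorbs the excess.
    """
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be >= 0")
    cl = params.contour_length
    k0 = params.elastic_modulus
    fs = params.force_scale
    target = x / cl
    # g(u) = u + f(u)/K0 is strictly increasing and convex on [0, 1) with
    # g(0) = 0, so the root is unique and Newton from an upper bound
    # converges monotonically.  Two bounds: g(u) >= u gives root <= target,
    # and g(u) >= fs*shape(u)/K0 gives shape(root) <= target*K0/fs.
    c_bound = target * k0 / fs
    u = np.minimum(target, 1.0 - 0.5 / np.sqrt(c_bound + 0.25))
    u = np.clip(u, 0.0, 1.0 - 1e-16)
    for _ in range(100):
        g = u + fs * _wlc_shape(u) / k0 - target
        gp = 1.0 + fs * _wlc_shape_prime(u) / k0
        du = g / gp
        u = np.clip(u - du, 0.0, 1.0 - 1e-16)
        if np.max(np.abs(du)) < 1e-15:
            break
    out = fs * _wlc_shape(u)
    if not np.all(np.isfinite(out)):
        raise ArithmeticError(
            "extensible-WLC root search produced a non-finite force "
            f"(extension={extension!r}, params={params!r})"
        )
    return out if out.ndim else float(out)


def ewlc_extension(force, params: ExtensibleWLCParams):
    """Inverse extensible WLC: extension (nm) carrying ``force`` (pN).

    Given f, the effective fractional extension u follows from the plain
    WLC inverse and the end-to-end length is cl * (u + f/K_0).
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    u = _wlc_shape_inverse(f / params.force_scale)
    out = params.contour_length * (u + f / params.elastic_modulus)
    return out if out.ndim else float(out)
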