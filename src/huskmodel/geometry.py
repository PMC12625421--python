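"""Spherical husk/kernel geometry of a hemp seed.

A seed is modelled as a sphere of outer radius ``R`` whose outer shell of
thickness ``t_H`` is the THC-rich husk; everything inside radius
``r_c_max = R - t_H`` is the nut kernel.  Peeling/extraction removes material
from the outside in, leaving a concentric core of radius ``r_c``.  The removed
volume fraction ``x`` (relative to the whole seed) and the core radius are
linked by ``x = 1 - (r_c / R)**3``.

Lengths are millimetres and volumes cubic millimetres throughout; units are
carried in reports only, never in arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


def sphere_volume(r: float) -> float:
    """Volume of a sphere of radius ``r``."""
    if r < 0:
        raise DomainError(f"radius must be non-negative, got {r}")
    return _FOUR_THIRDS_PI * r**3


def sphere_shell_volume(R: float, r_c: float) -> float:
    """Volume of the shell between the outer radius ``R`` and core radius ``r_c``.

    This is the removed volume ``V_red = (4*pi/3) * (R**3 - r_c**3)``; it is
    zero iff nothing has been removed (``r_c == R``).
    """
    if R < 0 or r_c < 0:
        raise DomainError(f"radii must be non-negative, got R={R}, r_c={r_c}")
    if r_c > R:
        raise DomainError(f"core radius r_c={r_c} exceeds outer radius R={R}")
    return _FOUR_THIRDS_PI * (R**3 - r_c**3)


def thickness_from_husk_fraction(f_H: float) -> float:
    """Relative husk thickness ``t_H / R`` for a husk volume fraction ``f_H``.

    Solves ``1 - (1 - t)**3 = f_H`` for the relative thickness ``t``:
    ``t = 1 - (1 - f_H)**(1/3)``.  Strictly increasing on ``[0, 1)``.
    """
    if not 0.0 <= f_H < 1.0:
        raise DomainError(f"husk volume fraction must be in [0, 1), got {f_H}")
    return 1.0 - (1.0 - f_H) ** (1.0 / 3.0)


def husk_fraction_from_thickness(t_rel: float) -> float:
    """Husk volume fraction for a relative thickness ``t_rel = t_H / R``.

    Exact inverse of :func:`thickness_from_husk_fraction`.
    """
    if not 0.0 <= t_rel < 1.0:
        raise DomainError(f"relative thickness must be in [0, 1), got {t_rel}")
    return 1.0 - (1.0 - t_rel) ** 3


@dataclass(frozen=True)
class SeedGeometry:
    """Outer radius and husk thickness of one seed archetype (mm).

    ``t_H = 0`` (a huskless seed) is accepted as a degenerate case.
    """

    R: float
    t_H: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise DomainError(f"outer radius must be positive, got {self.R}")
        if not 0.0 <= self.t_H < self.R:
            raise DomainError(
                f"husk thickness must satisfy 0 <= t_H < R, got t_H={self.t_H}, R={self.R}"
            )

    @property
    def r_c_max(self) -> float:
        """Maximum kernel radius, ``R - t_H``."""
        return self.R - self.t_H

    @property
    def husk_fraction(self) -> float:
        """Husk volume fraction ``V_H / V_R``."""
        return husk_fraction_from_thickness(self.t_H / self.R)

    @classmethod
    def from_husk_fraction(cls, R: float, f_H: float) -> "SeedGeometry":
        """Build a geometry from outer radius and husk volume fraction."""
        return cls(R=R, t_H=R * thickness_from_husk_fraction(f_H))


@dataclass(frozen=True)
class RemovalState:
    """Core radius, removed volume fraction and over-extraction thickness."""

    r_c: float
    x: float
    t_OE: float


@dataclass(frozen=True)
class VolumeBreakdown:
    """Volume bookkeeping for one removal state (mm^3).

    Invariants: ``V_R = V_H + V_C_max``; ``V_red = V_R - V_r``; whenever the
    core has shrunk inside the kernel (``r_c <= r_c_max``),
    ``V_red = V_H + V_OE``.
    """

    V_R: float
    V_H: float
    V_C_max: float
    V_r: float
    V_red: float
    V_OE: float


def removal_state(geom: SeedGeometry, x: float) -> tuple[RemovalState, VolumeBreakdown]:
    """State of a seed after removing the volume fraction ``x`` from outside in.

    ``x = f_H`` corresponds to perfect dehulling (``t_OE = 0``); ``x = 1``
    removes everything, leaving ``r_c = 0`` and ``t_OE = R - t_H``.
    """
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"removed volume fraction must be in [0, 1], got {x}")
    r_c = geom.R * (1.0 - x) ** (1.0 / 3.0)
    t_OE = max(0.0, geom.R - r_c - geom.t_H)
    V_R = sphere_volume(geom.R)
    V_C_max = sphere_volume(geom.r_c_max)
    V_H = V_R - V_C_max
    V_r = sphere_volume(r_c)
    V_red = V_R - V_r
    V_OE = max(0.0, V_C_max - V_r) if r_c <= geom.r_c_max else 0.0
    state = RemovalState(r_c=r_c, x=x, t_OE=t_OE)
    volumes = VolumeBreakdown(V_R=V_R, V_H=V_H, V_C_max=V_C_max, V_r=V_r, V_red=V_red, V_OE=V_OE)
    return state, volumes


def removed_mass_fraction(geom: SeedGeometry, x: float, rho_c: float, rho_H: float) -> float:
    """Removed fraction on a MASS basis for a volume-removed fraction ``x``.

    The canonical ``x`` of this package is a volume fraction; this converter is
    for reporting against field practice quoted by weight.  The removed shell
    is husk down to ``r_c_max`` and kernel beyond it.
    """
    if rho_c <= 0 or rho_H <= 0:
        raise DomainError("densities must be positive")
    state, vol = removal_state(geom, x)
    if state.r_c >= geom.r_c_max:
        removed_mass = rho_H * vol.V_red
    else:
        removed_mass = rho_H * vol.V_H + rho_c * vol.V_OE
    total_mass = rho_H * vol.V_H + rho_c * vol.V_C_max
    return removed_mass / total_mass
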