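"""Remainder density / Delta9-THC concentration under partial husk removal.

The seed is a two-component mixture: a dense, THC-rich husk occupying the
volume fraction ``f_H`` and a near-THC-free kernel occupying the rest.  When
the removed volume fraction is ``x`` (0 = intact seed, ``x = f_H`` = perfect
dehulling), the remaining material is the whole kernel plus the unremoved part
of the husk, and any intensive husk/kernel property ``p`` (density, THC
concentration) mixes volume-wise as

    p_remain(x) = p_H - (p_H - p_c) * (1 - f_H) / (1 - x),   0 <= x <= f_H.

Density and concentration are deliberately the SAME formula (the model treats
concentration as a density-like intensive property); both public functions
call one shared kernel.  Beyond ``x = f_H`` only kernel remains, so the value
plateaus at the kernel value rather than extrapolating to non-physical
negatives.

The compliance solver inverts the formula in closed form:

    x* = 1 - (C_H - C_C) * (1 - f_H) / (C_H - limit),

the smallest removed fraction whose remainder meets the ceiling.  With the
reference parameters (f_H = 0.10, C_H = 300, C_C = 2 mg/kg, limit 5 mg/kg)
this gives x* = 9.1 % of the whole-seed volume.

Concentrations are mg of analyte per kg of matrix throughout; an explicit
density-aware converter handles mg/L inputs, because regulatory ceilings are
mass-per-mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .errors import DomainError, EstimationError, InfeasibleError

__all__ = [
    "RegulatoryLimit",
    "KOREA_SEED",
    "KOREA_OIL",
    "BUNDLED_LIMITS",
    "MaterialComposition",
    "RemovalResult",
    "ComplianceReport",
    "PeelingFit",
    "mg_per_L_to_mg_per_kg",
    "remainder_density",
    "remainder_concentration",
    "whole_seed_concentration",
    "min_removal_for_limit",
    "simulate_removal_curve",
    "fit_peeling_series",
    "compliance_check",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegulatoryLimit:
    """A jurisdiction's THC ceiling for one product class (mg/kg)."""

    jurisdiction: str
    product: str
    limit: float

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise DomainError(f"regulatory limit must be positive, got {self.limit}")


#: Korean Food Code ceilings; other jurisdictions are user-supplied config.
KOREA_SEED = RegulatoryLimit("Korea", "seed", 5.0)
KOREA_OIL = RegulatoryLimit("Korea", "oil", 10.0)
BUNDLED_LIMITS = {"korea_seed": KOREA_SEED, "korea_oil": KOREA_OIL}


@dataclass(frozen=True)
class MaterialComposition:
    """Densities and THC concentrations of the husk/kernel pair.

    Densities may be in relative units (e.g. multiples of the kernel
    density); only their ratio enters the model.
    """

    rho_c: float
    rho_H: float
    C_H_THC: float
    C_C_THC: float
    f_H: float = 0.10

    def __post_init__(self) -> None:
        if self.rho_c <= 0 or self.rho_H <= 0:
            raise DomainError("densities must be positive")
        if not (self.C_H_THC >= self.C_C_THC >= 0):
            raise DomainError("need C_H_THC >= C_C_THC >= 0")
        if not 0.0 <= self.f_H < 1.0:
            raise DomainError(f"husk volume fraction must be in [0, 1), got {self.f_H}")

    @property
    def rho_R(self) -> float:
        """Volume-weighted whole-seed density."""
        return self.rho_H * self.f_H + self.rho_c * (1.0 - self.f_H)

    @property
    def husk_mass_fraction(self) -> float:
        """Mass share of the husk implied by densities and ``f_H``."""
        w_h = self.rho_H * self.f_H
        return w_h / (w_h + self.rho_c * (1.0 - self.f_H))


@dataclass(frozen=True)
class RemovalResult:
    """Remainder density and THC concentration for one removal state."""

    rho_remain: float
    C_remain_THC: float
    regime: str  # 'partial_husk' | 'exact_husk' | 'over_extracted'


@dataclass(frozen=True)
class ComplianceReport:
    """Pass/fail of a measured concentration against a regulatory ceiling."""

    concentration: float
    limit: RegulatoryLimit
    passed: bool
    margin: float  # limit - concentration; negative when failing

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "PASS" if self.passed else "FAIL"
        return (
            f"{verdict}: {self.concentration:g} mg/kg vs {self.limit.jurisdiction} "
            f"{self.limit.product} ceiling {self.limit.limit:g} mg/kg "
            f"(margin {self.margin:+g} mg/kg)"
        )


# --------------------------------------------------------------------------
# shared mixing kernel
# --------------------------------------------------------------------------

def _remainder_mixture(p_H: float, p_c: float, f_H: float, x: float) -> float:
    """Shared kernel: intensive property of the remainder after removing x.

    Implements ``p_H - (p_H - p_c) * (1 - f_H) / (1 - x)`` on the
    partial-husk branch and the kernel plateau beyond ``x = f_H``.
    """
    if not 0.0 <= f_H < 1.0:
        raise DomainError(f"husk volume fraction must be in [0, 1), got {f_H}")
    if x < 0.0:
        raise DomainError(f"removed fraction must be non-negative, got {x}")
    if x > f_H:
        return p_c
    return p_H - (p_H - p_c) * (1.0 - f_H) / (1.0 - x)


def _regime(f_H: float, x: float) -> str:
    if x < f_H:
        return "partial_husk"
    if x == f_H:
        return "exact_husk"
    return "over_extracted"


def mg_per_L_to_mg_per_kg(c_mg_per_L: float, density_kg_per_L: float) -> float:
    """Convert a mass-per-volume concentration to mass-per-mass.

    The model's canonical unit is mg/kg of matrix; solution measurements in
    mg/L divide by the matrix density (kg/L).
    """
    if density_kg_per_L <= 0:
        raise DomainError("density must be positive")
    return c_mg_per_L / density_kg_per_L


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def remainder_density(f_H: float, rho_c: float, rho_H: float, x: float) -> float:
    """Density of the remaining material after removing the volume fraction x.

    Bounded by ``rho_c <= rho_remain <= rho_H``; with ``f_H = 0.10`` and
    ``rho_H = 1.5 rho_c`` the intact seed sits at ``1.05 rho_c``.  Beyond
    ``x = f_H`` only kernel remains and ``rho_c`` is returned.
    """
    if rho_c <= 0 or rho_H <= 0:
        raise DomainError("densities must be positive")
    if x > 1.0:
        raise DomainError(f"removed fraction must be <= 1, got {x}")
    return _remainder_mixture(rho_H, rho_c, f_H, x)


def remainder_concentration(f_H: float, C_H: float, C_C: float, x: float) -> float:
    """THC concentration (mg/kg) of the remainder after removing x.

    Same mixing kernel as :func:`remainder_density` with concentrations in
    place of densities.  Strictly decreasing on ``[0, f_H]``, from the
    whole-seed mixture value down to the kernel value ``C_C``; errors for
    ``x >= 1`` (nothing remains).
    """
    if C_H < 0 or C_C < 0:
        raise DomainError("concentrations must be non-negative")
    if C_C > C_H:
        raise DomainError("husk concentration must be >= kernel concentration")
    if x >= 1.0:
        raise DomainError(f"removed fraction must be < 1 (nothing remains), got {x}")
    return _remainder_mixture(C_H, C_C, f_H, x)


def removal_result(comp: MaterialComposition, x: float) -> RemovalResult:
    """Evaluate both remainder density and concentration at one removal state."""
    return RemovalResult(
        rho_remain=remainder_density(comp.f_H, comp.rho_c, comp.rho_H, x),
        C_remain_THC=remainder_concentration(comp.f_H, comp.C_H_THC, comp.C_C_THC, x),
        regime=_regime(comp.f_H, x),
    )


def whole_seed_concentration(
    f_H: float,
    C_H: float,
    C_C: float,
    rho_c: float | None = None,
    rho_H: float | None = None,
):
    """Mixture THC concentration of the intact seed.

    The canonical value is volume-weighted, ``f_H*C_H + (1-f_H)*C_C``
    (identical to the remainder model at ``x = 0``).  When both densities are
    supplied, a tuple ``(volume_weighted, mass_weighted)`` is returned; the
    mass-weighted variant is a clearly non-canonical extension.
    """
    vol = remainder_concentration(f_H, C_H, C_C, 0.0)
    if rho_c is None and rho_H is None:
        return vol
    if rho_c is None or rho_H is None:
        raise DomainError("supply both densities or neither")
    if rho_c <= 0 or rho_H <= 0:
        raise DomainError("densities must be positive")
    w_h = f_H * rho_H
    w_c = (1.0 - f_H) * rho_c
    mass = (w_h * C_H + w_c * C_C) / (w_h + w_c)
    return vol, mass


def min_removal_for_limit(
    f_H: float,
    C_H: float,
    C_C: float,
    limit: RegulatoryLimit | float,
    method: str = "closed_form",
) -> float:
    """Smallest removed volume fraction x* whose remainder meets the ceiling.

    Closed form ``x* = 1 - (C_H - C_C)(1 - f_H)/(C_H - limit)``; the
    ``method='bisect'`` route solves the same equation numerically with
    Brent's method as an independent cross-check.  Returns 0 when the intact
    seed is already compliant; raises :class:`InfeasibleError` when even the
    pure kernel exceeds the ceiling.
    """
    L = limit.limit if isinstance(limit, RegulatoryLimit) else float(limit)
    if L <= 0:
        raise DomainError("limit must be positive")
    if L <= C_C:
        raise InfeasibleError(
            f"limit {L} mg/kg is at or below the kernel concentration {C_C} mg/kg; "
            "no amount of husk removal can comply"
        )
    c0 = remainder_concentration(f_H, C_H, C_C, 0.0)
    if L >= c0:
        return 0.0
    if method == "closed_form":
        return 1.0 - (C_H - C_C) * (1.0 - f_H) / (C_H - L)
    if method == "bisect":
        return float(
            brentq(
                lambda x: remainder_concentration(f_H, C_H, C_C, x) - L,
                0.0,
                f_H,
                xtol=1e-15,
                rtol=1e-15,
            )
        )
    raise ValueError(f"unknown method {method!r}")


def simulate_removal_curve(
    f_H: float, C_H: float, C_C: float, x_grid: Sequence[float]
) -> pd.DataFrame:
    """Remainder-THC curve over a grid of removal fractions.

    One row per grid point with columns ``x`` and ``C_remain_THC``; the curve
    is strictly decreasing and joins the whole-seed mixture value at ``x = 0``
    to the kernel value at ``x = f_H``.
    """
    xs = np.asarray(list(x_grid), dtype=float)
    c = [remainder_concentration(f_H, C_H, C_C, float(x)) for x in xs]
    return pd.DataFrame({"x": xs, "C_remain_THC": c})


def compliance_check(C: float, limit: RegulatoryLimit) -> ComplianceReport:
    """Check a concentration against a ceiling; the boundary is inclusive.

    The ceiling is treated as "at or below" (a product measuring exactly the
    ceiling passes).
    """
    if C < 0:
        raise DomainError(f"concentration must be non-negative, got {C}")
    return ComplianceReport(
        concentration=C, limit=limit, passed=C <= limit.limit, margin=limit.limit - C
    )


# --------------------------------------------------------------------------
# parameter recovery from peeling series
# --------------------------------------------------------------------------

@dataclass
class PeelingFit:
    """Least-squares estimates of (C_H, C_C, f_H) from a peeling series."""

    C_H: float
    C_C: float
    f_H: float
    se_C_H: float
    se_C_C: float
    se_f_H: float
    residual_sd: float
    n: int
    bootstrap_ci: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "C_H": self.C_H,
            "C_C": self.C_C,
            "f_H": self.f_H,
            "se_C_H": self.se_C_H,
            "se_C_C": self.se_C_C,
            "se_f_H": self.se_f_H,
            "residual_sd": self.residual_sd,
            "n": self.n,
        }


def _design_matrix(x: np.ndarray, f_H: float) -> np.ndarray:
    # Model is linear in (C_H, C_C) once f_H is fixed:
    #   x <  f_H : C = C_H * (1 - w) + C_C * w,  w = (1 - f_H)/(1 - x)
    #   x >= f_H : C = C_C
    w = (1.0 - f_H) / (1.0 - x)
    below = x < f_H
    return np.column_stack(
        [np.where(below, 1.0 - w, 0.0), np.where(below, w, 1.0)]
    )


def _profile_sse(x: np.ndarray, y: np.ndarray, f_H: float) -> tuple[float, np.ndarray]:
    A = _design_matrix(x, f_H)
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ theta
    return float(r @ r), theta


def fit_peeling_series(
    data,
    f_H_upper: float = 0.75,
    n_boot: int = 0,
    random_state: int | None = 0,
) -> PeelingFit:
    """Recover (C_H, C_C, f_H) from an observed peeling series by least squares.

    ``data`` is a DataFrame with columns ``x`` and a concentration column (or
    any two-column table x, C).  The model is linear in the two concentrations
    for fixed ``f_H``, so the fit profiles the residual sum of squares over
    ``f_H`` (piecewise-smooth in ``f_H``; each smooth piece is refined with a
    bounded scalar minimizer) with an inner linear solve.

    Identifiability requires the series to cross the kink at ``x = f_H``: on
    the partial-husk branch alone, ``C_C`` and ``f_H`` enter only through the
    product ``(C_H - C_C)(1 - f_H)``.  Series that never reach the kernel
    plateau raise :class:`EstimationError`.

    Standard errors come from the Jacobian at the optimum (delta method);
    ``n_boot > 0`` adds percentile bootstrap intervals by residual resampling.
    """
    if isinstance(data, pd.DataFrame):
        x = np.asarray(data.iloc[:, 0], dtype=float)
        y = np.asarray(data.iloc[:, 1], dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in data)
    if x.size != y.size:
        raise EstimationError("x and C series must have equal length")
    if np.unique(x).size < 4:
        raise EstimationError("need at least 4 distinct x values (under-determined)")
    if np.any((x < 0) | (x >= 1)):
        raise DomainError("x values must lie in [0, 1)")
    if np.any(x >= f_H_upper):
        raise EstimationError("all x values must be below the f_H search upper bound")

    xs = np.sort(np.unique(x))
    # candidate intervals for f_H between consecutive data points (+ above max)
    edges = np.concatenate([[0.0], xs[xs > 0], [f_H_upper]])
    edges = np.unique(edges)
    best = (np.inf, None, None)  # sse, f_H, interval
    eps = 1e-12
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        sse, _ = _profile_sse(x, y, mid)
        if sse < best[0]:
            best = (sse, mid, (lo, hi))
    lo, hi = best[2]
    res = minimize_scalar(
        lambda f: _profile_sse(x, y, f)[0],
        bounds=(lo + eps, hi - eps),
        method="bounded",
        options={"xatol": 1e-12},
    )
    f_hat = float(res.x)
    sse, theta = _profile_sse(x, y, f_hat)
    # keep the better of the interval midpoint and the refined point
    if best[0] < sse:
        f_hat = best[1]
        sse, theta = _profile_sse(x, y, f_hat)
    c_h, c_c = float(theta[0]), float(theta[1])

    if f_hat > xs[-1]:
        raise EstimationError(
            "f_H is not identifiable: the series never reaches the kernel plateau; "
            "extend the peeling series beyond the husk fraction"
        )

    n = x.size
    dof = max(n - 3, 1)
    s2 = sse / dof
    J = _jacobian(x, c_h, c_c, f_hat)
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)

    fit = PeelingFit(
        C_H=c_h,
        C_C=c_c,
        f_H=f_hat,
        se_C_H=float(se[0]),
        se_C_C=float(se[1]),
        se_f_H=float(se[2]),
        residual_sd=float(np.sqrt(s2)),
        n=n,
    )
    if n_boot > 0:
        fit.bootstrap_ci = _bootstrap_ci(x, y, fit, n_boot, random_state)
    return fit


def _jacobian(x: np.ndarray, c_h: float, c_c: float, f_H: float) -> np.ndarray:
    u = 1.0 / (1.0 - x)
    w = (1.0 - f_H) * u
    below = x < f_H
    d_ch = np.where(below, 1.0 - w, 0.0)
    d_cc = np.where(below, w, 1.0)
    d_fh = np.where(below, (c_h - c_c) * u, 0.0)
    return np.column_stack([d_ch, d_cc, d_fh])


def _bootstrap_ci(
    x: np.ndarray, y: np.ndarray, fit: PeelingFit, n_boot: int, random_state: int | None
) -> dict:
    rng = np.random.default_rng(random_state)
    yhat = np.array(
        [remainder_concentration(fit.f_H, fit.C_H, fit.C_C, float(xi)) for xi in x]
    )
    resid = y - yhat
    draws = []
    for _ in range(n_boot):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        try:
            fb = fit_peeling_series(
                pd.DataFrame({"x": x, "C": yb}), n_boot=0, random_state=None
            )
            draws.append([fb.C_H, fb.C_C, fb.f_H])
        except EstimationError:
            continue
    if not draws:
        return {}
    arr = np.asarray(draws)
    lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    names = ["C_H", "C_C", "f_H"]
    return {k: (float(a), float(b)) for k, a, b in zip(names, lo, hi)}
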