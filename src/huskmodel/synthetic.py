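"""Synthetic inputs with known ground truth for the whole pipeline.

Every generator takes an explicit integer seed, draws from its own
``numpy.random.Generator`` (no global RNG state), and is bit-reproducible for
identical arguments.  Chromatogram and peeling-series generators attach their
ground truth so closed-loop accuracy tests can compare recovered values
against what was generated.

Central parameter values are the reference-lot values (husk fraction 10 %,
density ratio 1.5, husk 300 mg/kg and kernel 2 mg/kg THC); the spreads around
them are repository conventions chosen to look like lot-to-lot variation and
detector noise, and every one is an explicit argument.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .chromatography import PEAK_CENTERS, Chromatogram, D9_THC
from .composition import remainder_concentration
from .errors import DomainError

__all__ = [
    "gen_seed_lot",
    "gen_peeling_series",
    "gen_chromatogram",
    "gen_calibration_set",
    "DEFAULT_RESPONSE_FACTOR",
]

#: Detector response factor (peak area per mg/L) used by the generators.
DEFAULT_RESPONSE_FACTOR = 12.5


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) truncated to (lo, hi) by resampling."""
    if sd < 0:
        raise DomainError("standard deviation must be non-negative")
    if not lo < hi:
        raise DomainError("truncation bounds must satisfy lo < hi")
    if sd == 0:
        if not lo < mean < hi:
            raise DomainError(f"degenerate mean {mean} outside truncation bounds")
        return np.full(n, mean)
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw > lo) & (draw < hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise DomainError("truncation bounds reject nearly all probability mass")


def gen_seed_lot(
    n: int,
    seed: int = 0,
    f_H: tuple[float, float] = (0.10, 0.01),
    rho_ratio: tuple[float, float] = (1.5, 0.05),
    C_H: tuple[float, float] = (300.0, 20.0),
    C_C: tuple[float, float] = (2.0, 0.2),
) -> pd.DataFrame:
    """A lot of seed archetypes, one row per seed.

    Each parameter is a (mean, sd) pair; husk fractions are truncated to
    (0.02, 0.75) and the rest to positive values.  Zero sds give an exact,
    degenerate lot.
    """
    if n < 0:
        raise DomainError("lot size must be non-negative")
    rng = np.random.default_rng(seed)
    cols = {
        "f_H": _truncated_normal(rng, *f_H, 0.02, 0.75, n) if n else np.empty(0),
        "rho_ratio": _truncated_normal(rng, *rho_ratio, 0.0, np.inf, n) if n else np.empty(0),
        "C_H_mg_kg": _truncated_normal(rng, *C_H, 0.0, np.inf, n) if n else np.empty(0),
        "C_C_mg_kg": _truncated_normal(rng, *C_C, 0.0, np.inf, n) if n else np.empty(0),
    }
    return pd.DataFrame(cols)


def gen_peeling_series(
    x_grid: Sequence[float],
    C_H: float = 300.0,
    C_C: float = 2.0,
    f_H: float = 0.10,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy observations of the remainder-THC curve along a removal grid.

    ``C_observed = C_remain(x) + Normal(0, noise_sd)``.  The grid may extend
    past the husk fraction into the kernel plateau — series used for full
    parameter recovery must do so.  Ground-truth parameters travel in
    ``df.attrs['truth']``.
    """
    rng = np.random.default_rng(seed)
    xs = np.asarray(list(x_grid), dtype=float)
    c = np.array([remainder_concentration(f_H, C_H, C_C, float(x)) for x in xs])
    obs = c + rng.normal(0.0, noise_sd, size=xs.size) if noise_sd > 0 else c.copy()
    df = pd.DataFrame({"x": xs, "C_mg_per_kg": obs})
    df.attrs["truth"] = {"C_H": C_H, "C_C": C_C, "f_H": f_H, "noise_sd": noise_sd}
    return df


def gen_chromatogram(
    truth: dict[str, float],
    method: str = "PK16",
    noise_sd: float = 0.2,
    drift_amplitude: float = 0.5,
    seed: int = 0,
    span_min: float = 12.0,
    sampling_rate: float = 100.0,
    response_factor: float = DEFAULT_RESPONSE_FACTOR,
    peak_sd_min: float = 0.08,
    impurity_area: float = 400.0,
) -> Chromatogram:
    """A synthetic detector trace for a map of analyte concentrations (mg/L).

    Gaussian peaks sit at the method's nominal retention times with area
    ``response_factor * concentration`` and SD ``peak_sd_min``; an early,
    broad impurity/solvent front elutes at 1 min; the baseline carries
    additive Gaussian noise plus a slow sinusoidal drift.  Ground truth
    (concentration, area, retention time per analyte) is attached as
    ``chrom.truth``.
    """
    centers = PEAK_CENTERS[method]
    unknown = set(truth) - set(centers)
    if unknown:
        raise DomainError(f"unknown analytes for {method}: {sorted(unknown)}")
    if any(c < 0 for c in truth.values()):
        raise DomainError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, span_min + 0.5 / sampling_rate, 1.0 / sampling_rate)
    y = np.zeros_like(t)

    def gaussian(center: float, area: float, sd: float) -> np.ndarray:
        return area / (sd * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * ((t - center) / sd) ** 2)

    meta = {}
    for analyte, conc in truth.items():
        area = response_factor * conc
        rt = centers[analyte]
        y += gaussian(rt, area, peak_sd_min)
        meta[analyte] = {"concentration_mg_L": conc, "area": area, "retention_time": rt}
    if impurity_area > 0:
        y += gaussian(1.0, impurity_area, 0.15)
    if drift_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        y += drift_amplitude * np.sin(2.0 * np.pi * t / (2.0 * span_min) + phase)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=t.size)
    return Chromatogram(time=t, signal=y, method=method, truth=meta)


def gen_calibration_set(
    top_level_mg_L: float = 50.0,
    n_levels: int = 8,
    dilution_factor: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
    analytes: Sequence[str] = (D9_THC,),
    response_factor: float = DEFAULT_RESPONSE_FACTOR,
) -> pd.DataFrame:
    """A serial-dilution calibration table (one row per analyte x level).

    Levels are ``top / dilution_factor**i`` for ``i = 0..n_levels-1`` (the
    default is the eight-level twofold ladder from the 50 mg/L stock standard
    mixture); areas are ``response_factor * level`` with optional
    multiplicative Gaussian noise.
    """
    if n_levels < 2:
        raise DomainError("need at least 2 calibration levels")
    if top_level_mg_L <= 0 or dilution_factor <= 1:
        raise DomainError("need a positive top level and dilution factor > 1")
    rng = np.random.default_rng(seed)
    levels = top_level_mg_L / dilution_factor ** np.arange(n_levels)
    rows = []
    for analyte in analytes:
        areas = response_factor * levels
        if noise > 0:
            areas = areas * (1.0 + rng.normal(0.0, noise, size=levels.size))
        for lv, ar in zip(levels, areas):
            rows.append({"analyte": analyte, "level_mg_per_L": lv, "area": ar})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {"response_factor": response_factor}
    return df
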