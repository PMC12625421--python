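"""PK-16-style chromatogram quantification.

Pipeline: detect peaks on a time/signal trace, integrate them (trapezoid over
a peak region with a linear local baseline), assign analytes by retention
window, convert areas to concentrations through per-analyte linear
calibration, and combine the THC isomers into a compliance verdict.

The method's published anchors are: matrix impurities elute in a front before
2 min, CBD near 3 min, and Delta9-THC between 5 and 6 min under PK-16 (near
7 min under the slower AOA condition), with every analyte through the column
by 10 min.  The full 16-analyte window table below is a repository
convention — non-overlapping windows inside 2–10 min honouring those anchors —
not a vendor table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .composition import ComplianceReport, RegulatoryLimit
from .errors import CalibrationError, ConfigurationError, DomainError

__all__ = [
    "Chromatogram",
    "CalibrationCurve",
    "QuantResult",
    "TotalTHCReport",
    "RETENTION_WINDOWS",
    "PEAK_CENTERS",
    "IMPURITY_LABEL",
    "D9_THC",
    "D8_THC",
    "detect_peaks",
    "assign_peaks",
    "fit_calibration",
    "quantify",
    "quantify_chromatogram",
    "total_thc_verdict",
]

D9_THC = "delta9-THC"
D8_THC = "delta8-THC"
THCA = "THCA-A"
IMPURITY_LABEL = "impurity_front"
UNASSIGNED = "unassigned"

#: Acid forms are quantified but never folded into the total-THC figure.
ACID_FORMS = {"THCA-A", "CBDA", "CBGA", "CBNA", "CBCA", "CBDVA", "THCVA"}

# analyte -> (window_lo, window_hi) in minutes.  Anchored windows: impurity
# front < 2 min, CBD 2.7-3.3, delta8 4.0-5.0, delta9 5.0-6.0; the other 13
# analytes get synthetic non-overlapping windows within 2-10 min.
RETENTION_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "PK16": {
        "CBDV": (2.0, 2.3),
        "CBDVA": (2.35, 2.65),
        "CBD": (2.7, 3.3),
        "CBG": (3.35, 3.65),
        "CBGA": (3.7, 3.95),
        D8_THC: (4.0, 5.0),
        D9_THC: (5.0, 6.0),
        "CBN": (6.05, 6.35),
        "CBNA": (6.45, 6.75),
        "THCV": (6.85, 7.15),
        "THCVA": (7.25, 7.55),
        "CBC": (7.65, 7.95),
        "CBCA": (8.05, 8.35),
        "CBL": (8.45, 8.75),
        "THCA-A": (8.85, 9.15),
        "CBDA": (9.25, 9.55),
    },
    # slower alternative operating condition: delta9 near 7 min
    "AOA": {
        "CBD": (3.6, 4.4),
        D8_THC: (5.5, 6.5),
        D9_THC: (6.5, 7.5),
    },
}

#: Nominal elution time per analyte = centre of its retention window.
PEAK_CENTERS = {
    method: {a: 0.5 * (lo + hi) for a, (lo, hi) in table.items()}
    for method, table in RETENTION_WINDOWS.items()
}

IMPURITY_CUTOFF_MIN = 2.0


@dataclass
class Chromatogram:
    """A detector trace: time (min) vs signal (absorbance units at 220 nm)."""

    time: np.ndarray
    signal: np.ndarray
    method: str = "PK16"
    truth: dict | None = None  # ground truth attached by the synthetic generator

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size == 0:
            raise DomainError("empty chromatogram")
        if self.time.size != self.signal.size:
            raise DomainError("time and signal must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time axis must be strictly increasing")
        if self.method == "PK16" and self.span < 10.0:
            raise DomainError("PK16 chromatograms must span at least 10 min")

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        """Mean sampling density, points per minute."""
        return (self.time.size - 1) / self.span

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.time, "signal_au": self.signal})

    @classmethod
    def from_csv(cls, path, method: str = "PK16") -> "Chromatogram":
        df = pd.read_csv(path)
        if not {"time_min", "signal_au"} <= set(df.columns):
            raise DomainError("chromatogram CSV needs columns time_min, signal_au")
        return cls(df["time_min"].to_numpy(), df["signal_au"].to_numpy(), method=method)


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-analyte linear response: area = slope*conc + intercept."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    top_level: float
    levels: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class QuantResult:
    """Quantified concentration for one assigned peak."""

    analyte: str
    concentration_mg_L: float        # in the injected solution
    dilution_factor: float
    matrix_factor: float
    concentration_in_sample: float   # mg/kg after back-calculation
    area: float
    retention_time: float


@dataclass(frozen=True)
class TotalTHCReport:
    """Total THC (delta8 + delta9 neutral forms) vs a regulatory ceiling."""

    total_thc: float
    components: dict
    acid_forms: dict
    compliance: ComplianceReport

    @property
    def passed(self) -> bool:
        return self.compliance.passed


# --------------------------------------------------------------------------
# peak detection and integration
# --------------------------------------------------------------------------

def _moving_average(y: np.ndarray, w: int = 5) -> np.ndarray:
    kernel = np.ones(w) / w
    return np.convolve(y, kernel, mode="same")


def _integrate_region(t: np.ndarray, y: np.ndarray, lo: int, hi: int) -> float:
    # baseline anchors: median of up to 9 raw samples around each boundary,
    # so a single noisy endpoint cannot tilt the baseline
    def anchor(i: int) -> float:
        a, b = max(0, i - 4), min(y.size, i + 5)
        return float(np.median(y[a:b]))

    base = np.interp(t[lo : hi + 1], [t[lo], t[hi]], [anchor(lo), anchor(hi)])
    return float(np.trapezoid(y[lo : hi + 1] - base, t[lo : hi + 1]))


def detect_peaks(
    chrom: Chromatogram,
    min_height: float = 3.0,
    min_prominence: float = 3.0,
    merge_window_min: float = 0.1,
    region_half_width_min: float = 0.35,
) -> pd.DataFrame:
    """Locate and integrate peaks; returns a table sorted by retention time.

    Local maxima above the height/prominence thresholds are kept; maxima
    closer than ``merge_window_min`` are merged (tallest wins).  Each peak is
    integrated over ``+/- region_half_width_min`` (truncated at the midpoint
    to a neighbouring peak) with a linear baseline between the region
    endpoints.
    """
    t, y = chrom.time, chrom.signal
    if t.size < 3:
        raise DomainError("chromatogram too short for peak detection")
    idx, _ = find_peaks(y, height=min_height, prominence=min_prominence)
    # merge peaks closer than the resolution window, keeping the taller one
    merged: list[int] = []
    for i in idx:
        if merged and t[i] - t[merged[-1]] < merge_window_min:
            if y[i] > y[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)

    dt = chrom.span / (t.size - 1)
    half = max(1, int(round(region_half_width_min / dt)))
    rows = []
    for j, i in enumerate(merged):
        lo = max(0, i - half)
        hi = min(t.size - 1, i + half)
        if j > 0:
            lo = max(lo, (merged[j - 1] + i) // 2)
        if j < len(merged) - 1:
            hi = min(hi, (i + merged[j + 1]) // 2)
        rows.append(
            {
                "retention_time": float(t[i]),
                "area": max(0.0, _integrate_region(t, y, lo, hi)),
                "height": float(y[i]),
                "assignment": UNASSIGNED,
            }
        )
    return pd.DataFrame(rows, columns=["retention_time", "area", "height", "assignment"])


def _validate_windows(table: dict[str, tuple[float, float]]) -> None:
    spans = sorted(table.items(), key=lambda kv: kv[1][0])
    for (a1, (lo1, hi1)), (a2, (lo2, hi2)) in zip(spans, spans[1:]):
        if hi1 < lo1 or hi2 < lo2:
            raise ConfigurationError(f"inverted retention window for {a1 if hi1 < lo1 else a2}")
        if lo2 < hi1:
            raise ConfigurationError(f"retention windows of {a1} and {a2} overlap")


def assign_peaks(
    peaks: pd.DataFrame,
    method: str = "PK16",
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Label peaks by retention window; deterministic and order-independent.

    Peaks before 2 min are the solvent/impurity front (excluded from
    potency); peaks matching no window stay unassigned.
    """
    table = RETENTION_WINDOWS[method] if windows is None else windows
    _validate_windows(table)
    out = peaks.copy()
    labels = []
    for rt in out["retention_time"]:
        if rt < IMPURITY_CUTOFF_MIN:
            labels.append(IMPURITY_LABEL)
            continue
        name = UNASSIGNED
        for analyte, (lo, hi) in table.items():
            if lo <= rt <= hi:
                name = analyte
                break
        labels.append(name)
    out["assignment"] = labels
    return out


# --------------------------------------------------------------------------
# calibration and quantification
# --------------------------------------------------------------------------

def fit_calibration(levels, analyte: str = "") -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, area) levels.

    ``levels`` is a DataFrame with columns ``level_mg_per_L`` and ``area`` (or
    any two-column concentration/area table).  The intercept is fitted, not
    forced through the origin.
    """
    if isinstance(levels, pd.DataFrame):
        cols = levels.columns
        conc = np.asarray(levels["level_mg_per_L" if "level_mg_per_L" in cols else cols[0]], float)
        area = np.asarray(levels["area" if "area" in cols else cols[1]], float)
    else:
        conc, area = (np.asarray(v, dtype=float) for v in zip(*levels))
    if np.unique(conc).size < 2:
        raise CalibrationError("need at least 2 distinct calibration concentrations")
    slope, intercept = np.polyfit(conc, area, 1)
    pred = slope * conc + intercept
    ss_tot = float(np.sum((area - area.mean()) ** 2))
    ss_res = float(np.sum((area - pred) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    df = pd.DataFrame({"level_mg_per_L": conc, "area": area})
    return CalibrationCurve(
        analyte=analyte, slope=float(slope), intercept=float(intercept),
        r_squared=r2, top_level=float(conc.max()), levels=df,
    )


def quantify(
    peak,
    cal: CalibrationCurve,
    dilution_factor: float = 1.0,
    matrix_factor: float = 1.0,
) -> QuantResult:
    """Area -> concentration through a calibration line.

    ``peak`` is a row of a peak table (or a bare area in signal*min).  The
    solution concentration is ``(area - intercept)/slope`` clipped at zero;
    the sample value multiplies in the composed dilution factor and any
    matrix back-calculation factor.  Refuses to extrapolate beyond 1.5x the
    top calibration level.
    """
    if cal.slope <= 0:
        raise CalibrationError(f"calibration slope must be positive, got {cal.slope}")
    if isinstance(peak, pd.Series):
        area = float(peak["area"])
        rt = float(peak.get("retention_time", np.nan))
        label = peak.get("assignment", cal.analyte)
        if cal.analyte and label not in (cal.analyte, UNASSIGNED):
            raise CalibrationError(
                f"peak assigned to {label!r} quantified against {cal.analyte!r} calibration"
            )
    else:
        area, rt, label = float(peak), float("nan"), cal.analyte
    conc = max(0.0, (area - cal.intercept) / cal.slope)
    if conc > 1.5 * cal.top_level:
        raise CalibrationError(
            f"concentration {conc:.3g} mg/L is beyond 1.5x the top calibration "
            f"level ({cal.top_level:g} mg/L); dilute and re-run"
        )
    return QuantResult(
        analyte=label or cal.analyte,
        concentration_mg_L=conc,
        dilution_factor=dilution_factor,
        matrix_factor=matrix_factor,
        concentration_in_sample=conc * dilution_factor * matrix_factor,
        area=area,
        retention_time=rt,
    )


def quantify_chromatogram(
    chrom: Chromatogram,
    calibrations: dict[str, CalibrationCurve],
    dilution_factor: float = 1.0,
    matrix_factor: float = 1.0,
    **detect_kwargs,
) -> list[QuantResult]:
    """Detect, assign and quantify every calibrated analyte in a trace."""
    peaks = assign_peaks(detect_peaks(chrom, **detect_kwargs), method=chrom.method)
    results = []
    for _, row in peaks.iterrows():
        name = row["assignment"]
        if name in (IMPURITY_LABEL, UNASSIGNED) or name not in calibrations:
            continue
        results.append(quantify(row, calibrations[name], dilution_factor, matrix_factor))
    return results


def total_thc_verdict(
    results: list[QuantResult], limit: RegulatoryLimit
) -> TotalTHCReport:
    """Combine the THC isomers and check the ceiling.

    Total THC = delta8 + delta9 neutral forms (missing = 0).  Acid forms
    (THCA-A etc.) are echoed separately and never totalled, since no
    decarboxylation weighting is defined for this protocol.
    """
    from .composition import compliance_check

    components = {}
    acids = {}
    for r in results:
        bucket = acids if r.analyte in ACID_FORMS else components
        bucket[r.analyte] = bucket.get(r.analyte, 0.0) + r.concentration_in_sample
    total = components.get(D8_THC, 0.0) + components.get(D9_THC, 0.0)
    return TotalTHCReport(
        total_thc=total,
        components={k: v for k, v in components.items() if k in (D8_THC, D9_THC)},
        acid_forms=acids,
        compliance=compliance_check(total, limit),
    )
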