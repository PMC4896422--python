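"""Construct quality control: thermal-shift melting points and SEC oligomer state.

Thermofluor melt curves (temperature vs. dye fluorescence) are reduced to a
melting temperature Tm, defined as the temperature of the maximum first
derivative of the smoothed fluorescence; curves without a clear sigmoidal
transition (aggregated or natively unstructured constructs) yield a
"no clear melting point" verdict instead of a number.  A Boltzmann sigmoid
fit is available as an alternative estimator.

Analytical size-exclusion chromatography is calibrated log-linearly
(log10(mass) = a·V_el + b) from standards; the oligomeric state of a
construct follows from the ratio of its apparent mass to its sequence mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MeltCurve",
    "MeltResult",
    "MeltCurveModel",
    "estimate_tm",
    "boltzmann",
    "SECCalibration",
    "SECCalibrationResult",
    "sec_calibrate",
    "SECResult",
    "classify_oligomer",
    "OligomerCall",
    "load_melt_curve",
    "load_sec_table",
]

NO_TRANSITION = "no clear melting point"


@dataclass(frozen=True)
class MeltCurve:
    """A thermal-shift curve: strictly increasing temperatures (°C) and
    fluorescence (arbitrary units)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if t.size != f.size:
            raise ValueError("temperature and fluorescence lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def boltzmann(t: np.ndarray, baseline: float, amplitude: float,
              tm: float, slope: float) -> np.ndarray:
    """Two-state Boltzmann sigmoid: baseline + amplitude/(1+exp((tm−t)/slope))."""
    return baseline + amplitude / (1.0 + np.exp((tm - t) / slope))


@dataclass
class MeltResult:
    """Outcome of a melt-curve analysis.

    ``tm`` is None when no clear melting point was found; ``verdict`` is
    either ``"tm"`` or ``"no clear melting point"``.
    """

    tm: float | None
    verdict: str
    amplitude: float
    noise: float
    smoothed: np.ndarray
    derivative: np.ndarray
    method: str = "derivative"

    @property
    def has_transition(self) -> bool:
        return self.tm is not None

    def summary(self) -> str:
        lines = ["thermal-shift analysis", "-" * 30,
                 f"method:     {self.method}",
                 f"verdict:    {self.verdict}"]
        if self.tm is not None:
            lines.append(f"Tm:         {self.tm:.2f} °C")
        lines.append(f"amplitude:  {self.amplitude:.3g}")
        lines.append(f"noise est.: {self.noise:.3g}")
        return "\n".join(lines)


class MeltCurveModel:
    """Melting-point estimator for one thermofluor curve.

    The default estimator smooths with a 5-point centred moving average and
    takes Tm at the maximum of the first derivative (with parabolic
    sub-grid refinement).  ``fit(method="boltzmann")`` instead fits a
    two-state sigmoid and reports its midpoint.

    A curve is called "no clear melting point" when the rising-phase
    amplitude is below ``min_amplitude_frac`` of the full observed range,
    when the transition amplitude does not exceed 5x the estimated noise
    (a genuine unfolding transition is orders of magnitude above the point
    noise), or when the derivative maximum sits on a boundary point.
    """

    #: minimum points and temperature span for a meaningful analysis
    MIN_POINTS = 20
    MIN_SPAN = 30.0

    def __init__(self, curve: MeltCurve, min_amplitude_frac: float = 0.2,
                 smooth_window: int = 5):
        if curve.temperatures.size < self.MIN_POINTS:
            raise ValueError(f"need >= {self.MIN_POINTS} points")
        span = curve.temperatures[-1] - curve.temperatures[0]
        if span < self.MIN_SPAN:
            raise ValueError(f"temperature span {span:.1f} °C < {self.MIN_SPAN} °C")
        self.curve = curve
        self.min_amplitude_frac = min_amplitude_frac
        self.smooth_window = smooth_window

    def _smooth(self) -> np.ndarray:
        w = self.smooth_window
        f = self.curve.fluorescence
        pad = w // 2
        padded = np.concatenate([np.full(pad, f[0]), f, np.full(pad, f[-1])])
        return np.convolve(padded, np.ones(w) / w, mode="valid")

    def fit(self, method: str = "derivative") -> MeltResult:
        if method == "boltzmann":
            return self._fit_boltzmann()
        if method != "derivative":
            raise ValueError(f"unknown method {method!r}")
        t = self.curve.temperatures
        raw = self.curve.fluorescence
        smoothed = self._smooth()
        deriv = np.gradient(smoothed, t)
        peak = int(np.argmax(deriv))

        # robust noise estimate from the smoothing residuals
        resid = raw - smoothed
        noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))

        # rising phase: contiguous region of positive derivative around the peak
        lo = peak
        while lo > 0 and deriv[lo - 1] > 0:
            lo -= 1
        hi = peak
        while hi < deriv.size - 1 and deriv[hi + 1] > 0:
            hi += 1
        amplitude = float(smoothed[hi] - smoothed[lo])
        full_range = float(np.max(raw) - np.min(raw))

        no_transition = (
            peak in (0, deriv.size - 1)
            or full_range == 0
            or amplitude < self.min_amplitude_frac * full_range
            or amplitude <= 5.0 * noise
        )
        if no_transition:
            return MeltResult(None, NO_TRANSITION, amplitude, noise,
                              smoothed, deriv)
        # sub-grid refinement: least-squares parabola over the derivative
        # peak and its neighbours (±5 points, i.e. ±2.5 °C at the standard
        # scan rate — averages point noise without leaving the transition)
        tm = float(t[peak])
        w0, w1 = max(0, peak - 5), min(deriv.size, peak + 6)
        if w1 - w0 >= 3:
            coeff = np.polyfit(t[w0:w1] - tm, deriv[w0:w1], 2)
            if coeff[0] < 0:
                vertex = -coeff[1] / (2 * coeff[0])
                half_window = float(t[w1 - 1] - t[w0]) / 2
                if abs(vertex) <= half_window:
                    tm += float(vertex)
        return MeltResult(tm, "tm", amplitude, noise, smoothed, deriv)

    def _fit_boltzmann(self) -> MeltResult:
        import lmfit

        t = self.curve.temperatures
        raw = self.curve.fluorescence
        deriv_result = self.fit("derivative")
        if not deriv_result.has_transition:
            deriv_result.method = "boltzmann"
            return deriv_result
        model = lmfit.Model(boltzmann)
        params = model.make_params(
            baseline=float(np.min(raw)),
            amplitude=float(np.max(raw) - np.min(raw)),
            tm=deriv_result.tm,
            slope=2.0,
        )
        params["slope"].set(min=1e-3)
        out = model.fit(raw, params, t=t)
        tm = float(out.params["tm"].value)
        return MeltResult(tm, "tm", float(out.params["amplitude"].value),
                          deriv_result.noise, deriv_result.smoothed,
                          deriv_result.derivative, method="boltzmann")


def estimate_tm(curve: MeltCurve, min_amplitude_frac: float = 0.2,
                method: str = "derivative") -> MeltResult:
    """Estimate the melting point of a thermofluor curve (wrapper over
    :class:`MeltCurveModel`)."""
    return MeltCurveModel(curve, min_amplitude_frac).fit(method)


# --------------------------------------------------------------------------
# size-exclusion chromatography
# --------------------------------------------------------------------------

@dataclass
class SECCalibrationResult:
    """Log-linear SEC calibration: log10(mass) = a·v_el + b."""

    a: float
    b: float
    r_squared: float
    stderr_a: float
    n_standards: int

    def mass(self, v_el: float) -> float:
        """Apparent mass (kDa) at an elution coordinate."""
        return float(10.0 ** (self.a * v_el + self.b))

    def summary(self) -> str:
        return (
            "SEC calibration  log10(M) = a·V_el + b\n"
            f"  a = {self.a:.5g} ± {self.stderr_a:.2g}\n"
            f"  b = {self.b:.5g}\n"
            f"  R² = {self.r_squared:.5f}  (n = {self.n_standards})"
        )


class SECCalibration:
    """Least-squares log-linear column calibration from standards."""

    def __init__(self, standards: Sequence[tuple[float, float]]):
        standards = list(standards)
        if len(standards) < 3:
            raise ValueError(f"need >= 3 standards, got {len(standards)}")
        v = np.array([s[1] for s in standards], dtype=float)
        if np.unique(v).size != v.size:
            raise ValueError("standards must have distinct elution volumes")
        m = np.array([s[0] for s in standards], dtype=float)
        if np.any(m <= 0):
            raise ValueError("standard masses must be positive")
        self.masses = m
        self.v_el = v

    def fit(self) -> SECCalibrationResult:
        res = stats.linregress(self.v_el, np.log10(self.masses))
        return SECCalibrationResult(
            a=float(res.slope), b=float(res.intercept),
            r_squared=float(res.rvalue ** 2),
            stderr_a=float(res.stderr), n_standards=self.v_el.size,
        )


def sec_calibrate(standards: Sequence[tuple[float, float]]) -> SECCalibrationResult:
    """Fit log10(mass) = a·v_el + b from (mass kDa, elution volume) standards."""
    return SECCalibration(standards).fit()


@dataclass(frozen=True)
class SECResult:
    """One construct's SEC readout."""

    v_el: float
    m_app: float
    m_calc: float

    def __post_init__(self) -> None:
        if self.m_app <= 0 or self.m_calc <= 0:
            raise ValueError("masses must be positive")


@dataclass(frozen=True)
class OligomerCall:
    status: str        # monomer / dimer / multimer
    ratio: float
    multiplicity: int


def classify_oligomer(m_app: float, m_calc: float) -> OligomerCall:
    """Oligomeric state from the apparent/sequence mass ratio.

    The ratio is rounded half-up to the nearest integer k; k <= 1 is a
    monomer, k == 2 a dimer, k >= 3 a multimer.
    """
    if m_app <= 0 or m_calc <= 0:
        raise ValueError("masses must be positive")
    ratio = m_app / m_calc
    k = int(math.floor(ratio + 0.5))
    if k <= 1:
        status = "monomer"
    elif k == 2:
        status = "dimer"
    else:
        status = "multimer"
    return OligomerCall(status, ratio, max(k, 1))


def is_void_aggregate(v_el: float, void_threshold: float) -> bool:
    """Constructs eluting at or before the void volume are soluble
    high-molecular-weight aggregates (no default threshold: column
    geometry dependent)."""
    return v_el <= void_threshold


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def _normalize_decimal(tok: str) -> float:
    """Parse a number allowing European decimal commas ("51,3" -> 51.3)."""
    return float(tok.replace(",", "."))


def load_melt_curve(path: str | Path, sample_id: str | None = None) -> MeltCurve:
    """Read a melt-curve TSV: columns temperature, fluorescence."""
    path = Path(path)
    t, f = [], []
    with path.open() as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if parts[0].lower().startswith("temp"):
                continue
            t.append(_normalize_decimal(parts[0]))
            f.append(_normalize_decimal(parts[1]))
    if not t:
        raise ValueError(f"{path}: empty melt curve")
    return MeltCurve(np.array(t), np.array(f),
                     sample_id=path.stem if sample_id is None else sample_id)


def load_sec_table(path: str | Path) -> list[dict]:
    """Read a construct QC table.

    Columns: id, tm (number or '-'), v_el, m_app (or '-'), m_calc, and
    optionally the annotated status.  Decimal commas are accepted.
    """
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if parts[0].lower() == "id":
                continue
            row = {
                "id": parts[0],
                "tm": None if parts[1] == "-" else _normalize_decimal(parts[1]),
                "v_el": None if parts[2] == "-" else _normalize_decimal(parts[2]),
                "m_app": None if parts[3] == "-" else _normalize_decimal(parts[3]),
                "m_calc": None if parts[4] == "-" else _normalize_decimal(parts[4]),
                "status": parts[5] if len(parts) > 5 else None,
            }
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty table")
    return rows
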