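"""Circular dichroism spectra: containers, file I/O, preprocessing, unit conversion.

A CD spectrum is stored on an ascending wavelength grid (nm).  Raw instrument
output is ellipticity in millidegrees (``mdeg``); quantitative analysis uses the
mean-residue molar circular dichroism Δε (M⁻¹ cm⁻¹), obtained by normalising the
ellipticity by the mean-residue molar concentration and the optical path length:

    Δε(λ) = θ(λ)[mdeg] · MRW / (32980 · c[mg/ml] · l[cm])

where MRW is the mean residue weight (protein mass divided by residue count).
The factor 32980 = 3298 · 10 combines the molar-ellipticity/Δε conversion
([θ] = 3298·Δε) with the mdeg and concentration unit handling.

The canonical analysis grid is 170–255 nm at 1 nm steps, covering the
vacuum-UV region where the six secondary-structure components are most
distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CANONICAL_GRID",
    "DELTA_EPS_FACTOR",
    "Spectrum",
    "SampleMeta",
    "load_spectrum",
    "save_spectrum",
    "preprocess",
    "to_delta_epsilon",
    "from_delta_epsilon",
    "resample_grid",
]

#: Canonical vacuum-UV wavelength grid, 170–255 nm at 1 nm resolution.
CANONICAL_GRID = np.arange(170.0, 256.0, 1.0)

#: Combined unit factor in Δε = θ[mdeg]·MRW / (32980 · c[mg/ml] · l[cm]).
DELTA_EPS_FACTOR = 32980.0

_UNITS = ("mdeg", "delta_epsilon")


@dataclass(frozen=True)
class Spectrum:
    """A CD spectrum on an ascending wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing, no duplicates.
    values : array of float
        Signal at each wavelength; units given by ``units``.
    sample_id : str
        Free-text sample identifier.
    units : {"mdeg", "delta_epsilon"}
        ``mdeg`` for raw ellipticity, ``delta_epsilon`` for mean-residue Δε.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_id: str = ""
    units: str = "delta_epsilon"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be one-dimensional")
        if wl.size != vals.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("spectrum contains non-finite entries")
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}, got {self.units!r}")

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float),
                       units=self.units if units is None else units)

    def on_grid(self, grid: np.ndarray) -> bool:
        grid = np.asarray(grid, dtype=float)
        return self.wavelengths.shape == grid.shape and np.allclose(
            self.wavelengths, grid
        )


@dataclass(frozen=True)
class SampleMeta:
    """Sample metadata needed for the mdeg → Δε conversion.

    concentration in mg/ml, pathlength in μm, mrw (mean residue weight) in Da.
    ``n_residues`` must equal the sequence length when a sequence is given.
    """

    concentration: float
    pathlength: float
    mrw: float
    n_residues: int
    sequence: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")
        if self.pathlength <= 0:
            raise ValueError(f"pathlength must be > 0, got {self.pathlength}")
        if not (80.0 <= self.mrw <= 200.0):
            raise ValueError(f"mean residue weight {self.mrw} outside [80, 200] Da")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError(
                f"n_residues={self.n_residues} but sequence has {len(self.sequence)} residues"
            )


def load_spectrum(path: str | Path, units_tag: str = "delta_epsilon",
                  sample_id: str | None = None) -> Spectrum:
    """Read a two-column (wavelength, value) delimited text file.

    Columns may be separated by whitespace or commas; lines starting with '#'
    are comments.  Rows are sorted by wavelength if needed.
    """
    path = Path(path)
    wl: list[float] = []
    vals: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {text!r}") from exc
            wl.append(w)
            vals.append(v)
    if not wl:
        raise ValueError(f"{path}: no data rows")
    order = np.argsort(wl, kind="stable")
    wl_arr = np.asarray(wl, dtype=float)[order]
    val_arr = np.asarray(vals, dtype=float)[order]
    if np.any(np.diff(wl_arr) == 0):
        dup = wl_arr[:-1][np.diff(wl_arr) == 0][0]
        raise ValueError(f"{path}: duplicate wavelength {dup} nm")
    return Spectrum(wl_arr, val_arr,
                    sample_id=path.stem if sample_id is None else sample_id,
                    units=units_tag)


def save_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text (wavelength, value)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_id: {spectrum.sample_id}\n")
        fh.write(f"# units: {spectrum.units}\n")
        fh.write("# wavelength_nm\tvalue\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{w:.6g}\t{v:.10g}\n")


def preprocess(scans: Sequence[Spectrum], baseline: Spectrum) -> Spectrum:
    """Average repeated accumulations and subtract the buffer baseline.

    All scans and the baseline must share one wavelength grid.  Returns the
    pointwise mean of the scans minus the baseline, inheriting the first
    scan's units and sample id.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("need at least one scan")
    grid = scans[0].wavelengths
    for s in scans[1:]:
        if not s.on_grid(grid):
            raise ValueError(f"scan {s.sample_id!r} is not on the common grid")
    if not baseline.on_grid(grid):
        raise ValueError("baseline is not on the scan grid")
    mean = np.mean([s.values for s in scans], axis=0) - baseline.values
    return Spectrum(grid.copy(), mean, sample_id=scans[0].sample_id,
                    units=scans[0].units)


def to_delta_epsilon(raw: Spectrum, meta: SampleMeta) -> Spectrum:
    """Convert raw ellipticity (mdeg) to mean-residue Δε (M⁻¹ cm⁻¹).

    Δε = θ[mdeg] · MRW / (32980 · c[mg/ml] · l[cm]); the pathlength in
    ``meta`` is in μm and converted internally.
    """
    if raw.units != "mdeg":
        raise ValueError(f"expected units 'mdeg', got {raw.units!r}")
    path_cm = meta.pathlength * 1e-4
    factor = meta.mrw / (DELTA_EPS_FACTOR * meta.concentration * path_cm)
    return Spectrum(raw.wavelengths.copy(), raw.values * factor,
                    sample_id=raw.sample_id or meta.sample_id,
                    units="delta_epsilon")


def from_delta_epsilon(spec: Spectrum, meta: SampleMeta) -> Spectrum:
    """Inverse of :func:`to_delta_epsilon` (Δε back to mdeg)."""
    if spec.units != "delta_epsilon":
        raise ValueError(f"expected units 'delta_epsilon', got {spec.units!r}")
    path_cm = meta.pathlength * 1e-4
    factor = meta.mrw / (DELTA_EPS_FACTOR * meta.concentration * path_cm)
    return Spectrum(spec.wavelengths.copy(), spec.values / factor,
                    sample_id=spec.sample_id, units="mdeg")


def resample_grid(spectrum: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linear interpolation onto a new grid; extrapolation is an error."""
    grid = np.asarray(list(grid), dtype=float)
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"requested grid [{grid.min()}, {grid.max()}] extends beyond the "
            f"measured range [{lo}, {hi}]; refusing to extrapolate"
        )
    vals = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return Spectrum(grid, vals, sample_id=spectrum.sample_id, units=spectrum.units)
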