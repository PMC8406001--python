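"""Fluorescence emission-spectrum observables used as folding probes.

Tryptophan emission red-shifts when transthyretin unfolds and the indole
ring becomes solvent exposed.  Two scalar probes condense a spectrum into a
foldedness index:

* the centre of spectral mass (CSM), the intensity-weighted mean emission
  wavenumber ``CSM = sum(nu_i * F_i) / sum(F_i)`` with ``nu_i = 1e7 /
  lambda_i`` (lambda in nm, CSM in cm^-1) — lower CSM means red-shifted,
  i.e. more unfolded;
* the 355/335 intensity ratio, emission at the unfolded-state peak over the
  folded-state peak — higher means more unfolded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import logger

__all__ = [
    "EmissionSpectrum",
    "subtract_background",
    "center_of_spectral_mass",
    "intensity_ratio",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission spectrum on an ascending wavelength grid.

    Parameters
    ----------
    wavelengths : ndarray
        Emission wavelengths, nm, strictly increasing.
    intensities : ndarray
        Fluorescence intensities, arbitrary units, same length.
    meta : dict
        Condition metadata (probe, denaturant type, denaturant_M,
        protein concentration, ...); carried through arithmetic.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or inten.ndim != 1 or wl.size != inten.size:
            raise ValueError("wavelength and intensity grids must be 1-D and the same length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")


def subtract_background(sample: EmissionSpectrum, blank: EmissionSpectrum) -> EmissionSpectrum:
    """Pointwise buffer-background subtraction.

    The grids must be identical; no silent interpolation is performed.
    Sample metadata is preserved.
    """
    if sample.wavelengths.size != blank.wavelengths.size or not np.array_equal(
        sample.wavelengths, blank.wavelengths
    ):
        raise ValueError("sample and blank wavelength grids differ; refusing to interpolate")
    return replace(sample, intensities=sample.intensities - blank.intensities)


def center_of_spectral_mass(s: EmissionSpectrum) -> float:
    """Intensity-weighted mean emission wavenumber, cm^-1.

    ``CSM = sum(nu_i F_i) / sum(F_i)`` with ``nu_i = 1e7 / lambda_i`` and
    lambda in nm.  Raw intensities are used as weights (no Jacobian
    re-weighting on the nm -> cm^-1 conversion).
    """
    total = float(np.sum(s.intensities))
    if total <= 0.0:
        raise ValueError("CSM undefined: spectrum total intensity is not positive")
    nu = 1.0e7 / s.wavelengths
    return float(np.sum(nu * s.intensities) / total)


def intensity_ratio(s: EmissionSpectrum, num_nm: float = 355.0, den_nm: float = 335.0) -> float:
    """Unfolded/folded intensity ratio F(num_nm)/F(den_nm).

    Off-grid wavelengths are linearly interpolated; both must lie inside
    the grid.  The denominator intensity must be positive.
    """
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    for wl in (num_nm, den_nm):
        if wl < lo or wl > hi:
            raise ValueError(f"wavelength {wl} nm is outside the grid [{lo}, {hi}] nm")
    num = float(np.interp(num_nm, s.wavelengths, s.intensities))
    den = float(np.interp(den_nm, s.wavelengths, s.intensities))
    if den <= 0.0:
        raise ValueError(f"denominator intensity at {den_nm} nm is not positive ({den})")
    return num / den


# ---------------------------------------------------------------------------
# CSV I/O: two columns wavelength_nm,intensity with metadata in commented
# "# key=value" header lines.
# ---------------------------------------------------------------------------


def write_spectrum_csv(s: EmissionSpectrum, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in sorted(s.meta.items())]
    lines.append("wavelength_nm,intensity")
    lines += [f"{wl:.6g},{inten:.10g}" for wl, inten in zip(s.wavelengths, s.intensities)]
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path) -> EmissionSpectrum:
    path = Path(path)
    meta: dict = {}
    wl: list[float] = []
    inten: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = _coerce(v.strip())
            continue
        if line.lower().startswith("wavelength"):
            continue
        a, b = line.split(",")
        wl.append(float(a))
        inten.append(float(b))
    logger.debug("read spectrum with %d points from %s", len(wl), path)
    return EmissionSpectrum(np.array(wl), np.array(inten), meta)


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v
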