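"""Resveratrol-binding quantification of tetramer content.

Resveratrol binds the TTR tetramer (not the monomer) and its fluorescence
at 394 nm is linear in tetramer concentration over the 0-2 uM calibration
range.  A linear calibration ``F394 = slope * [tetramer] + intercept``
therefore converts the F394 signal measured along a denaturation series
into percent tetramer remaining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .config import logger
from .denaturation import DenaturationCurve

__all__ = ["Calibration", "fit_calibration", "tetramer_percent"]


@dataclass(frozen=True)
class Calibration:
    """Linear F394-vs-tetramer-concentration calibration."""

    slope: float          # intensity per mol/L tetramer
    intercept: float      # intensity
    r_squared: float
    conc_range: tuple[float, float]   # mol/L validity range

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "Calibration":
        d = json.loads(Path(path).read_text())
        d["conc_range"] = tuple(d["conc_range"])
        return cls(**d)


def fit_calibration(concs, F394) -> Calibration:
    """Ordinary least-squares line through (tetramer conc, F394) points.

    Needs at least 2 distinct concentrations (>= 3 recommended); two points
    give the exact interpolating line with r^2 = 1.
    """
    c = np.asarray(concs, float)
    F = np.asarray(F394, float)
    if c.size != F.size or c.size < 2:
        raise ValueError("need matching concentration/intensity arrays with >= 2 points")
    if np.ptp(c) == 0:
        raise ValueError("all concentrations equal: calibration line is rank-deficient")
    res = stats.linregress(c, F)
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc_range=(float(c.min()), float(c.max())),
    )


def tetramer_percent(
    curve: DenaturationCurve,
    cal: Calibration,
    total_tetramer: float,
    noise_tolerance: float = 0.02,
) -> np.ndarray:
    """Percent tetramer at each denaturant point of an F394 curve.

    ``percent = 100 * ((F - intercept) / slope) / total_tetramer``, clipped
    to [0, 100].  Points falling below the intercept by more than
    ``noise_tolerance`` of the calibration span at ``total_tetramer`` are
    flagged in the log before clipping — small negative estimates in the
    unfolded baseline are routine, large ones point at a calibration
    mismatch.
    """
    if total_tetramer <= 0:
        raise ValueError("total_tetramer must be positive")
    lo, hi = cal.conc_range
    if not lo <= total_tetramer <= hi:
        raise ValueError(
            f"total_tetramer = {total_tetramer} M outside calibration range [{lo}, {hi}] M"
        )
    F = curve.signal
    span = cal.slope * total_tetramer
    est = (F - cal.intercept) / cal.slope / total_tetramer * 100.0
    low = F < cal.intercept - noise_tolerance * span
    if np.any(low):
        logger.warning(
            "%d F394 point(s) below the calibration intercept beyond noise "
            "tolerance; clipped to 0%%", int(np.sum(low)),
        )
    n_clip = int(np.sum((est < 0) | (est > 100)))
    if n_clip:
        logger.info("clipped %d tetramer-percent estimate(s) into [0, 100]", n_clip)
    return np.clip(est, 0.0, 100.0)
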