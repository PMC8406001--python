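"""Analytical-ultracentrifugation reductions.

Sedimentation-velocity experiments on TTR denaturation intermediates are
run at 25 degC in phosphate/KCl buffer containing urea.  This module
performs the standard desk reductions on their outputs:

* standardization of observed sedimentation coefficients to water at
  20 degC and infinite dilution (s20,w), via buffer density/viscosity
  correlations and the buoyancy/viscosity correction

      s20,w = s_obs * (eta_buf,T / eta_w,20)
                    * (1 - vbar_20 * rho_w,20) / (1 - vbar_T * rho_buf,T)

* frictional ratios f/f0 against the anhydrous-sphere limit,
  ``f/f0 = s_max / s20,w`` with
  ``s_max = M (1 - vbar rho) / (N_A 6 pi eta R_min)`` and
  ``R_min = (3 M vbar / 4 pi N_A)^(1/3)``;

* integration of continuous c(s) distributions into species classes
  (monomer < 2 S, tetramer 2-5 S, higher-order oligomers > 5 S).

Solvent property correlations and their sources
-----------------------------------------------
Water density: Kell (1975) polynomial (0-40 degC); water viscosity:
Viswanath-Natarajan/CRC log-ratio form anchored at eta(20) = 1.002 cP.
Cosolute increments are additive on top of water at the working
temperature:

* urea: relative viscosity 1 + 0.0378 c + 0.000644 c^3 (Kawahara-Tanford
  style polynomial); density increment from the apparent molal volume of
  urea (44.24 mL/mol at infinite dilution, weak linear c-dependence),
  reproducing handbook densities of aqueous urea to ~1e-3 g/mL up to 8 M.
* KCl: density from the apparent molal volume (26.85 mL/mol);
  Jones-Dole viscosity 1 + 0.0052 sqrt(c) - 0.0140 c.
* sodium phosphate (pH ~7, treated as Na2HPO4): density increment
  0.129 g/mL per mol/L (handbook solution densities); Jones-Dole
  viscosity with A = 0.02, B = 0.554 L/mol (2 Na+ + HPO4^2- ionic
  B-coefficients).

The additive-increment convention is adequate at the concentrations used
here (<= 2.5 M urea, <= 0.1 M salts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .config import (
    DVBAR_DT,
    SPECIES_BOUNDARIES,
    TTR_MATURE_SEQUENCE,
    VBAR_25,
    logger,
)

__all__ = [
    "SolventConditions",
    "SedSpecies",
    "CsDistribution",
    "solvent_properties",
    "s20w",
    "frictional_ratio",
    "integrate_species",
    "monomer_mass",
    "vbar_at_temperature",
    "read_cs_distribution",
    "write_cs_distribution",
]

#: Avogadro's number, mol^-1
N_A = 6.02214076e23

#: Handbook anchors for pure water.
RHO_W20 = 0.99823      # g/mL at 20 degC
ETA_W20 = 1.002        # cP at 20 degC


# ---------------------------------------------------------------------------
# Solvent conditions and property correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolventConditions:
    """Buffer composition and temperature of a sedimentation experiment."""

    temperature: float = 20.0   # degC
    urea: float = 0.0           # mol/L
    gdmhcl: float = 0.0         # mol/L
    kcl: float = 0.0            # mol/L
    phosphate: float = 0.0      # mol/L (total sodium phosphate, pH ~7)

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 40.0:
            raise ValueError("temperature correlation valid for 0-40 degC only")
        for name, limit in (("urea", 9.0), ("gdmhcl", 8.0), ("kcl", 1.0), ("phosphate", 0.5)):
            c = getattr(self, name)
            if c < 0:
                raise ValueError(f"{name} concentration must be non-negative")
            if c > limit:
                raise ValueError(
                    f"{name} = {c} M exceeds the validity range of the "
                    f"{name} density/viscosity correlation (<= {limit} M)"
                )


WATER_20C = SolventConditions(temperature=20.0)


def water_density(t_celsius: float) -> float:
    """Density of air-free water, g/mL (Kell 1975, 0-40 degC)."""
    t = t_celsius
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.879850e-3 * t) / 1000.0


def water_viscosity(t_celsius: float) -> float:
    """Viscosity of water, cP, anchored at 1.002 cP at 20 degC."""
    t = t_celsius
    exponent = (1.3272 * (20.0 - t) - 0.001053 * (t - 20.0) ** 2) / (t + 105.0)
    return ETA_W20 * 10.0**exponent


def _urea_density_increment(c: float) -> float:
    # apparent molal volume 44.24 + 0.14 c mL/mol at 25 degC
    return c * (60.055 - 0.99705 * (44.24 + 0.14 * c)) / 1000.0


def _gdmhcl_density_increment(c: float) -> float:
    # guanidinium chloride, apparent molal volume ~71.8 mL/mol
    return c * (95.53 - 0.99705 * 71.8) / 1000.0


def _kcl_density_increment(c: float) -> float:
    return c * (74.551 - 0.99705 * 26.85) / 1000.0


def _phosphate_density_increment(c: float) -> float:
    return 0.129 * c


def _relative_viscosity(cond: SolventConditions) -> float:
    rel = 1.0
    if cond.urea:
        rel *= 1.0 + 0.0378 * cond.urea + 0.000644 * cond.urea**3
    if cond.gdmhcl:
        # Kawahara-Tanford style polynomial for GdmHCl
        rel *= 1.0 + 0.0187 * cond.gdmhcl + 0.00157 * cond.gdmhcl**2
    if cond.kcl:
        rel *= 1.0 + 0.0052 * np.sqrt(cond.kcl) - 0.0140 * cond.kcl
    if cond.phosphate:
        rel *= 1.0 + 0.02 * np.sqrt(cond.phosphate) + 0.554 * cond.phosphate
    return rel


def solvent_properties(cond: SolventConditions) -> tuple[float, float]:
    """(density g/mL, viscosity cP) of the buffer at its temperature.

    Pure water at 20 degC reproduces (0.99823, 1.002) to the precision of
    the anchor correlations.
    """
    rho = (
        water_density(cond.temperature)
        + _urea_density_increment(cond.urea)
        + _gdmhcl_density_increment(cond.gdmhcl)
        + _kcl_density_increment(cond.kcl)
        + _phosphate_density_increment(cond.phosphate)
    )
    eta = water_viscosity(cond.temperature) * _relative_viscosity(cond)
    return float(rho), float(eta)


# ---------------------------------------------------------------------------
# Sequence-derived quantities
# ---------------------------------------------------------------------------

def monomer_mass(sequence: str = TTR_MATURE_SEQUENCE) -> float:
    """Average molar mass of the (mature) monomer from its sequence, g/mol."""
    return float(ProteinAnalysis(sequence).molecular_weight())


def vbar_at_temperature(t_celsius: float, vbar25: float = VBAR_25) -> float:
    """Partial specific volume at temperature t, mL/g.

    Standard linear convention: vbar(T) = vbar25 + 4.25e-4 (T - 25).
    """
    return vbar25 + DVBAR_DT * (t_celsius - 25.0)


# ---------------------------------------------------------------------------
# s20,w standardization and frictional ratio
# ---------------------------------------------------------------------------

def s20w(s_obs: float, cond: SolventConditions, vbar25: float = VBAR_25) -> float:
    """Standardize an observed sedimentation coefficient to water, 20 degC.

    ``s_obs`` in Svedberg; returns s20,w in Svedberg.  The correction is a
    species-independent factor for fixed conditions and vbar.
    """
    if s_obs <= 0:
        raise ValueError("s_obs must be positive")
    rho_b, eta_b = solvent_properties(cond)
    # reference state from the same property tables, so that water/20 degC
    # conditions leave s unchanged exactly
    rho_w20, eta_w20 = solvent_properties(WATER_20C)
    vbar_T = vbar_at_temperature(cond.temperature, vbar25)
    vbar_20 = vbar_at_temperature(20.0, vbar25)
    buoy_w20 = 1.0 - vbar_20 * rho_w20
    buoy_cond = 1.0 - vbar_T * rho_b
    if buoy_cond <= 0 or buoy_w20 <= 0:
        raise ValueError("non-positive buoyancy term: protein would float")
    factor = (eta_b / eta_w20) * (buoy_w20 / buoy_cond)
    logger.debug("s20w correction factor %.5f (vbar25=%.4f)", factor, vbar25)
    return s_obs * factor


def max_sphere_s(M: float, vbar20: float, rho: float = RHO_W20, eta: float = ETA_W20) -> float:
    """Sedimentation coefficient of the anhydrous sphere of mass M, in S.

    M in g/mol, vbar in mL/g, rho in g/mL, eta in cP.  CGS internally;
    1 S = 1e-13 s.
    """
    if M <= 0 or vbar20 <= 0:
        raise ValueError("M and vbar must be positive")
    eta_poise = eta * 1e-2
    vol = M * vbar20 / N_A                      # cm^3 per molecule
    r_min = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)   # cm
    s_sec = M * (1.0 - vbar20 * rho) / (N_A * 6.0 * np.pi * eta_poise * r_min)
    return s_sec / 1e-13


def frictional_ratio(s20w_value: float, M: float, vbar20: float) -> float:
    """Frictional ratio f/f0 = s_max / s20,w against the anhydrous sphere.

    1.0 is a compact anhydrous sphere; larger values indicate elongation,
    expansion and/or hydration.  ``s20w_value`` may not exceed the sphere
    limit.
    """
    if s20w_value <= 0:
        raise ValueError("s20w must be positive")
    s_max = max_sphere_s(M, vbar20)
    if s20w_value > s_max:
        raise ValueError(
            f"s20,w = {s20w_value} S exceeds the anhydrous-sphere limit "
            f"{s_max:.3f} S for M = {M} g/mol"
        )
    return s_max / s20w_value


# ---------------------------------------------------------------------------
# Species and c(s) handling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SedSpecies:
    """A sedimenting species with observed and standardized coefficients."""

    s_obs: float                  # S
    s20w: float                   # S
    fraction: float               # of total loading signal
    f_f0: float = float("nan")
    species_class: str = ""       # monomer | tetramer | higher-order

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.s20w <= 0:
            raise ValueError("s20w must be positive")
        if not np.isnan(self.f_f0) and self.f_f0 < 1.0 - 5e-2:
            raise ValueError("f/f0 below the sphere limit beyond tolerance")


@dataclass(frozen=True)
class CsDistribution:
    """A continuous sedimentation-coefficient distribution c(s)."""

    s_grid: np.ndarray     # S, ascending
    values: np.ndarray     # signal per S, non-negative

    def __post_init__(self) -> None:
        s = np.asarray(self.s_grid, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "s_grid", s)
        object.__setattr__(self, "values", v)
        if s.size != v.size or s.size < 2:
            raise ValueError("c(s) needs matching grids with at least 2 points")
        if not np.all(np.diff(s) > 0):
            raise ValueError("s grid must be strictly ascending")
        if np.any(v < -1e-12):
            raise ValueError("c(s) values must be non-negative")

    def total_signal(self) -> float:
        return float(np.trapezoid(self.values, self.s_grid))


def integrate_species(
    dist: CsDistribution,
    boundaries: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Percentage of total c(s) signal per species class.

    Trapezoidal integration with the distribution linearly interpolated at
    interior class boundaries, so the class percentages sum to exactly 100.
    """
    bounds = SPECIES_BOUNDARIES if boundaries is None else boundaries
    total = dist.total_signal()
    if total <= 0:
        raise ValueError("empty c(s) distribution")
    s, v = dist.s_grid, dist.values
    out: dict[str, float] = {}
    for name, (lo, hi) in bounds.items():
        lo_eff = max(lo, float(s[0]))
        hi_eff = min(hi, float(s[-1]))
        if hi_eff <= lo_eff:
            out[name] = 0.0
            continue
        # refine the grid with the class edges, then integrate the window
        edges = [x for x in (lo_eff, hi_eff) if s[0] < x < s[-1]]
        grid = np.unique(np.concatenate([s, np.asarray(edges)]))
        vals = np.interp(grid, s, v)
        mask = (grid >= lo_eff) & (grid <= hi_eff)
        out[name] = 100.0 * float(np.trapezoid(vals[mask], grid[mask])) / total
    return out


# ---------------------------------------------------------------------------
# Two-column c(s) text I/O (SEDFIT-export compatible)
# ---------------------------------------------------------------------------

def write_cs_distribution(dist: CsDistribution, path: str | Path) -> None:
    path = Path(path)
    lines = [f"{s:.8g}\t{c:.10g}" for s, c in zip(dist.s_grid, dist.values)]
    path.write_text("\n".join(lines) + "\n")


def read_cs_distribution(path: str | Path) -> CsDistribution:
    path = Path(path)
    s: list[float] = []
    c: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "%")):
            continue
        parts = line.replace(",", " ").split()
        s.append(float(parts[0]))
        c.append(float(parts[1]))
    return CsDistribution(np.array(s), np.array(c))
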