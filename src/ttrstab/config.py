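"""Shared constants, default parameter values and region definitions.

Everything that more than one analysis module needs to agree on lives here:
the gas constant and working temperature, the mature transthyretin (TTR)
sequence and quantities derived from it, the partial specific volume
convention, the sedimentation-coefficient class boundaries, and the named
loop regions of the TTR fold.  All of these are defaults — the functions
that consume them accept overrides.
"""

from __future__ import annotations

import logging

logger = logging.getLogger("ttrstab")

# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------

#: Gas constant, kcal mol^-1 K^-1
R_KCAL: float = 1.9872041e-3

#: Working temperature for all equilibrium modelling, K (25 degC)
T_REF: float = 298.15

#: R*T at 25 degC, kcal/mol
RT: float = R_KCAL * T_REF

# ---------------------------------------------------------------------------
# Transthyretin sequence and hydrodynamic conventions
# ---------------------------------------------------------------------------

#: Mature human transthyretin chain (127 residues, UniProt P02766 21-147).
TTR_MATURE_SEQUENCE: str = (
    "GPTGTGESKCPLMVKVLDAVRGSPAINVAVHVFRKAADDTWEPFASGKTSESGELHGLTT"
    "EEEFVEGIYKVEIDTKSYWKALGISPFHEHAEVVFTANDSGPRRYTIAALLSPYSYSTTA"
    "VVTNPKE"
)

#: Partial specific volume of TTR at 25 degC, mL/g (sequence-based,
#: Cohn-Edsall residue volumes; coincides with the SEDNTERP-convention value).
VBAR_25: float = 0.7346

#: Temperature coefficient of the partial specific volume, mL g^-1 degC^-1.
DVBAR_DT: float = 4.25e-4

#: Protomers per tetramer; concentrations are kept in protomer units
#: internally and converted at the I/O boundary.
PROTOMERS_PER_TETRAMER: int = 4

# ---------------------------------------------------------------------------
# Sedimentation species classes (S units)
# ---------------------------------------------------------------------------

#: c(s) integration boundaries: monomer below 2 S, tetramer 2-5 S,
#: higher-order oligomers beyond 5 S.
SPECIES_BOUNDARIES: dict[str, tuple[float, float]] = {
    "monomer": (0.0, 2.0),
    "tetramer": (2.0, 5.0),
    "higher-order": (5.0, float("inf")),
}

# ---------------------------------------------------------------------------
# TTR loop regions (mature-sequence numbering)
# ---------------------------------------------------------------------------

#: Named loop regions of the TTR fold, inclusive residue ranges.  The BC and
#: DE loops are the flexibility hotspots of the R34/K35 variants; the AB/GH
#: loops form the hydrophobic contact region of the tetramer interface.
LOOP_REGIONS: dict[str, tuple[int, int]] = {
    "AB": (18, 28),
    "BC": (36, 40),
    "CD": (49, 53),
    "DE": (55, 64),
    "EF": (74, 90),
    "FG": (98, 104),
    "GH": (105, 122),
}

# ---------------------------------------------------------------------------
# Spectral defaults
# ---------------------------------------------------------------------------

#: Tryptophan emission acquisition window, nm.
WAVELENGTH_WINDOW: tuple[float, float] = (310.0, 410.0)

#: Folded / unfolded tryptophan emission peak centres, nm.
FOLDED_PEAK_NM: float = 335.0
UNFOLDED_PEAK_NM: float = 355.0

#: Default replicate count for residual-resampling bootstrap CIs.
BOOTSTRAP_REPLICATES: int = 200


def region_residues(name: str, regions: dict[str, tuple[int, int]] | None = None) -> range:
    """Inclusive residue range of a named region as a ``range``."""
    table = LOOP_REGIONS if regions is None else regions
    lo, hi = table[name]
    return range(lo, hi + 1)
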