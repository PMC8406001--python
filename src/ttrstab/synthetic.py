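"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with
prescribed parameters, so each downstream stage is testable end to end
without external measurements:

* tryptophan emission spectra across a denaturant series, as mixtures of
  folded/unfolded Gaussian basis spectra weighted by the thermodynamic
  model's population fractions;
* denaturation curves from the two-population signal model plus i.i.d.
  Gaussian noise;
* harmonic-fluctuation multi-chain trajectories with prescribed
  per-residue displacement amplitudes and prescribed on/off side-chain
  contact schedules;
* c(s) distributions as Gaussian peak mixtures.

All generators are pure functions of (spec, seed): random streams are
split per observable from a single master seed, so adding one generator
call does not shift the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import FOLDED_PEAK_NM, UNFOLDED_PEAK_NM, logger
from .denaturation import DenaturationCurve, StabilityModelParams, population_fractions, predict_signal
from .spectra import EmissionSpectrum
from .structdyn import StructureModel, Trajectory

__all__ = [
    "GaussianBasis",
    "SpectrumSeriesSpec",
    "TrajectorySpec",
    "gen_spectra_series",
    "gen_denaturation_curve",
    "gen_trajectory",
    "gen_cs_distribution",
    "make_reference_structure",
]

#: Atom name displaced to realize scheduled contacts.
DESIGNATED_SC_ATOM = "CG"
#: Realized side-chain distances for scheduled contacts (Angstrom).
CONTACT_ON_DISTANCE = 3.0
CONTACT_OFF_DISTANCE = 8.0


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianBasis:
    """A Gaussian basis emission spectrum in wavelength."""

    center_nm: float
    width_nm: float = 25.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0 or self.amplitude <= 0:
            raise ValueError("basis width and amplitude must be positive")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -((wavelengths - self.center_nm) ** 2) / (2.0 * self.width_nm**2)
        )


@dataclass(frozen=True)
class SpectrumSeriesSpec:
    """Specification of a synthetic denaturant series of emission spectra."""

    wavelength_start: float = 310.0
    wavelength_stop: float = 410.0
    wavelength_step: float = 1.0
    folded_basis: GaussianBasis = field(
        default_factory=lambda: GaussianBasis(FOLDED_PEAK_NM)
    )
    unfolded_basis: GaussianBasis = field(
        default_factory=lambda: GaussianBasis(UNFOLDED_PEAK_NM)
    )
    denaturant_grid: tuple = tuple(np.arange(0.0, 9.01, 0.5))
    noise_sd: float = 0.0
    seed: int = 0
    intermediate_weight: float = 0.5   # folded-basis share of the intermediate state

    def __post_init__(self) -> None:
        if self.wavelength_start >= self.wavelength_stop:
            raise ValueError("wavelength_start must be below wavelength_stop")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.intermediate_weight <= 1.0:
            raise ValueError("intermediate_weight must lie in [0, 1]")

    def wavelengths(self) -> np.ndarray:
        return np.arange(
            self.wavelength_start,
            self.wavelength_stop + self.wavelength_step / 2.0,
            self.wavelength_step,
        )


def gen_spectra_series(
    spec: SpectrumSeriesSpec,
    model: StabilityModelParams,
    protomer_conc: float,
) -> list[EmissionSpectrum]:
    """One emission spectrum per denaturant concentration.

    Each spectrum is ``folded * B_F + unfolded * B_U + intermediate *
    (w * B_F + (1 - w) * B_U)`` with population fractions from the
    denaturation model, plus homoscedastic Gaussian noise.  The
    intermediate (partially folded monomer) has no basis of its own; it is
    a fixed mixture of the two bases.
    """
    wl = spec.wavelengths()
    bF = spec.folded_basis(wl)
    bU = spec.unfolded_basis(wl)
    w = spec.intermediate_weight
    rngs = _child_rngs(spec.seed, len(spec.denaturant_grid))
    out: list[EmissionSpectrum] = []
    for D, rng in zip(spec.denaturant_grid, rngs):
        f = population_fractions(float(D), model, protomer_conc)
        inten = (
            f["folded"][0] * bF
            + f["unfolded"][0] * bU
            + f["intermediate"][0] * (w * bF + (1.0 - w) * bU)
        )
        if spec.noise_sd > 0:
            inten = inten + rng.normal(0.0, spec.noise_sd, size=wl.size)
        out.append(
            EmissionSpectrum(
                wl.copy(), inten,
                meta={
                    "probe": "trp", "denaturant": "urea",
                    "denaturant_M": float(D), "protomer_conc": protomer_conc,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Denaturation curves
# ---------------------------------------------------------------------------

def gen_denaturation_curve(
    model: StabilityModelParams,
    protomer_conc: float,
    grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    denaturant_type: str = "urea",
    observable: str = "ratio",
) -> DenaturationCurve:
    """Model observable on a denaturant grid plus i.i.d. Gaussian noise."""
    grid = np.asarray(grid, float)
    if grid.size and not np.all(np.diff(grid) >= 0):
        raise ValueError("denaturant grid must be sorted ascending")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    y = predict_signal(grid, model, protomer_conc)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=grid.size)
    return DenaturationCurve(grid, y, protomer_conc, denaturant_type, observable)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Specification of a harmonic-fluctuation synthetic trajectory.

    ``per_residue_sigma`` is the per-coordinate Gaussian displacement SD in
    Angstrom applied to every atom of the residue (same profile in every
    chain); the analytic C-alpha RMSF of residue i is ``sigma_i *
    sqrt(3)``.  ``contact_schedule`` maps residue pairs — ``(i, j)`` with
    plain numbers (chain defaults to the first chain) or ``((chain, i),
    (chain, j))`` — to target contact persistences realized by a Bernoulli
    on/off placement of the designated side-chain atom.
    """

    n_residues: int
    chain_ids: tuple[str, ...] = ("A",)
    n_frames: int = 100
    frame_interval_ps: float = 4.0
    per_residue_sigma: tuple | float = 0.0
    contact_schedule: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame interval must be positive")
        sig = self.sigma_array()
        if np.any(sig < 0):
            raise ValueError("per-residue sigma must be non-negative")
        for pair, p in self.contact_schedule:
            if not 0.0 <= p <= 1.0:
                raise ValueError("target persistence must lie in [0, 1]")

    def sigma_array(self) -> np.ndarray:
        sig = np.asarray(self.per_residue_sigma, float)
        if sig.ndim == 0:
            sig = np.full(self.n_residues, float(sig))
        if sig.size != self.n_residues:
            raise ValueError("per_residue_sigma length must equal n_residues")
        return sig

    def normalized_schedule(self) -> list[tuple[tuple[str, int], tuple[str, int], float]]:
        out = []
        for pair, p in self.contact_schedule:
            a, b = pair
            a = (self.chain_ids[0], int(a)) if np.isscalar(a) else (str(a[0]), int(a[1]))
            b = (self.chain_ids[0], int(b)) if np.isscalar(b) else (str(b[0]), int(b[1]))
            out.append((a, b, float(p)))
        return out


def make_reference_structure(
    n_residues: int,
    chain_ids: Sequence[str] = ("A",),
    spacing: float = 5.0,
    chain_offset: float = 30.0,
    gly_positions: Sequence[int] = (),
) -> StructureModel:
    """An extended-chain reference model for trajectory generation.

    Residues are laid out along x at ``spacing`` Angstrom, chains offset in
    z.  Each residue carries backbone N, CA, C, O and side-chain CB, CG
    heavy atoms at fixed local offsets; residues listed in
    ``gly_positions`` are glycines with no side chain.
    """
    offsets = {
        "N": (-1.2, 0.6, 0.0), "CA": (0.0, 0.0, 0.0), "C": (1.2, 0.6, 0.0),
        "O": (1.3, 1.8, 0.0), "CB": (0.0, -1.5, 0.0), "CG": (0.0, -2.9, 0.0),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C"}
    gly = set(gly_positions)
    chain, resnum, resname, name, element, xyz = [], [], [], [], [], []
    for ci, ch in enumerate(chain_ids):
        for ri in range(1, n_residues + 1):
            is_gly = ri in gly
            atoms = ("N", "CA", "C", "O") if is_gly else ("N", "CA", "C", "O", "CB", "CG")
            for a in atoms:
                dx, dy, dz = offsets[a]
                chain.append(str(ch))
                resnum.append(ri)
                resname.append("GLY" if is_gly else "UNK")
                name.append(a)
                element.append(elements[a])
                xyz.append((ri * spacing + dx, dy, ci * chain_offset + dz))
    n = len(chain)
    return StructureModel(
        np.array(chain), np.array(resnum, int), np.array(resname),
        np.array(name), np.array(element), np.array(xyz, float),
        np.zeros(n), np.ones(n),
    )


def gen_trajectory(spec: TrajectorySpec, reference: StructureModel) -> Trajectory:
    """Reference coordinates plus Gaussian fluctuations and scheduled contacts.

    Every atom of residue i receives independent per-coordinate
    N(0, sigma_i^2) displacements in each frame.  For each scheduled pair
    the designated side-chain atom of the second residue is then placed at
    a fixed offset from the first residue's designated atom — inside the
    contact cutoff in Bernoulli(persistence) "on" frames, outside it
    otherwise — so the realized contact statistic is exactly controllable.
    """
    expected = len(spec.chain_ids) * spec.n_residues
    n_found = len(reference.residue_keys())
    if n_found != expected:
        raise ValueError(
            f"reference has {n_found} residues; spec requires {expected}"
        )
    sched = spec.normalized_schedule()
    used: set[tuple[str, int]] = set()
    for a, b, _ in sched:
        if a in used or b in used or a == b:
            raise ValueError("contact_schedule residues must be distinct and disjoint")
        used |= {a, b}

    def atom_idx(key: tuple[str, int], atom: str) -> int:
        m = (reference.chain == key[0]) & (reference.resnum == key[1]) & (reference.name == atom)
        idx = np.flatnonzero(m)
        if idx.size != 1:
            raise ValueError(f"residue {key} lacks designated atom {atom!r}")
        return int(idx[0])

    # contradiction check: pair within cutoff by fixed geometry alone
    sc = reference.sidechain_mask()
    for a, b, _ in sched:
        ia = atom_idx(a, DESIGNATED_SC_ATOM)
        ib = atom_idx(b, DESIGNATED_SC_ATOM)
        mask_a = (reference.chain == a[0]) & (reference.resnum == a[1])
        mask_b = (reference.chain == b[0]) & (reference.resnum == b[1])
        keep_b = mask_b.copy()
        keep_b[ib] = False   # the movable atom is exempt
        d = np.linalg.norm(
            reference.xyz[mask_a][:, None, :] - reference.xyz[keep_b][None, :, :], axis=2
        )
        if d.size and d.min() <= 4.5:
            raise ValueError(
                f"contact pair {a}-{b} is within the cutoff by fixed geometry alone"
            )

    noise_ss, sched_ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng_noise = np.random.default_rng(noise_ss)
    sigma = spec.sigma_array()
    # per-atom sigma from the rank of the residue number within its chain
    res_pos: dict[tuple[str, int], int] = {}
    for ch in set(reference.chain):
        nums = sorted({int(r) for c, r in zip(reference.chain, reference.resnum) if c == ch})
        res_pos.update({(ch, r): k for k, r in enumerate(nums)})
    atom_sigma = np.array([
        sigma[res_pos[(c, r)]] for c, r in zip(reference.chain, reference.resnum.tolist())
    ])
    frames = (
        reference.xyz[None, :, :]
        + rng_noise.normal(size=(spec.n_frames, reference.n_atoms, 3))
        * atom_sigma[None, :, None]
    )
    pair_rngs = [np.random.default_rng(s) for s in sched_ss.spawn(max(1, len(sched)))]
    offset_dir = np.array([0.0, -1.0, 0.0])   # outward, away from the backbone
    for (a, b, p), rng in zip(sched, pair_rngs):
        ia = atom_idx(a, DESIGNATED_SC_ATOM)
        ib = atom_idx(b, DESIGNATED_SC_ATOM)
        on = rng.random(spec.n_frames) < p
        dist = np.where(on, CONTACT_ON_DISTANCE, CONTACT_OFF_DISTANCE)
        frames[:, ib, :] = frames[:, ia, :] + dist[:, None] * offset_dir[None, :]
        logger.debug("scheduled pair %s-%s realized persistence %.4f",
                     a, b, float(on.mean()))
    return Trajectory(reference, frames, spec.frame_interval_ps)


# ---------------------------------------------------------------------------
# c(s) distributions
# ---------------------------------------------------------------------------

def gen_cs_distribution(
    species: Sequence[tuple[float, float, float]],
    grid: Sequence[float],
    seed: int = 0,
    noise_sd: float = 0.0,
    loading_signal: float = 1.0,
):
    """Sum of Gaussian c(s) peaks, area-normalized to the loading signal.

    ``species`` is a list of (s20w in S, signal fraction, peak width in S);
    fractions must sum to 1 within 1e-9.  Optional Gaussian noise (then
    clipped at zero) is seeded.
    """
    from .hydro import CsDistribution

    grid = np.asarray(grid, float)
    fracs = np.array([f for _, f, _ in species])
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"species fractions sum to {fracs.sum()}, not 1")
    if any(w <= 0 for _, _, w in species):
        raise ValueError("peak widths must be positive")
    values = np.zeros_like(grid)
    for s0, frac, width in species:
        values += frac * np.exp(-((grid - s0) ** 2) / (2.0 * width**2)) / (
            width * np.sqrt(2.0 * np.pi)
        )
    area = np.trapezoid(values, grid)
    if area <= 0:
        raise ValueError("degenerate c(s): zero area on the given grid")
    values *= loading_signal / area
    if noise_sd > 0:
        values = np.clip(
            values + np.random.default_rng(seed).normal(0.0, noise_sd, grid.size),
            0.0, None,
        )
    return CsDistribution(grid, values)
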