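"""Trajectory and static-structure analytics.

Implements the flexibility and contact metrics used to compare TTR
variants: least-squares (Kabsch) rigid superposition and RMSD, per-residue
C-alpha RMSF averaged over fixed-length time windows, pairwise RMSF
comparison over named loop regions, side-chain contact persistence
(fraction of frames with any side-chain heavy-atom pair within a cutoff),
main-chain N...O hydrogen-bond distances, and crystallographic B-factor
profiling.

Structures and multi-model PDB trajectories are parsed with Biopython
(Bio.PDB) into flat array containers that the numerical routines operate
on directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .config import LOOP_REGIONS, logger

__all__ = [
    "StructureModel",
    "Trajectory",
    "ContactRecord",
    "RMSFProfile",
    "SuperposeResult",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "superpose",
    "rmsf_windowed",
    "rmsf_compare",
    "contact_persistence",
    "region_contact_frequency",
    "hbond_distance",
    "bfactor_profile",
]

#: Main-chain heavy-atom names; everything else heavy is side chain.
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """A static structure as flat per-atom arrays.

    ``(chain, resnum, name)`` keys are unique; coordinates in Angstrom,
    B-factors in Angstrom^2.
    """

    chain: np.ndarray      # dtype str
    resnum: np.ndarray     # int
    resname: np.ndarray    # str
    name: np.ndarray       # atom name, str
    element: np.ndarray    # str
    xyz: np.ndarray        # (n_atoms, 3) float, Angstrom
    bfactor: np.ndarray    # float
    occupancy: np.ndarray  # float

    def __post_init__(self) -> None:
        n = len(self.chain)
        for arr_name in ("resnum", "resname", "name", "element", "bfactor", "occupancy"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError("per-atom arrays must share one length")
        self.xyz = np.asarray(self.xyz, float)
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if np.any(np.asarray(self.bfactor) < 0):
            raise ValueError("B-factors must be non-negative")
        keys = list(zip(self.chain, self.resnum, self.name))
        if len(set(keys)) != n:
            raise ValueError("(chain, residue, atom) keys must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def atom_keys(self) -> list[tuple[str, int, str]]:
        return list(zip(self.chain, self.resnum.tolist(), self.name))

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue number) keys."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain, self.resnum.tolist()):
            seen.setdefault((c, r), None)
        return list(seen)

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chain[mask], self.resnum[mask], self.resname[mask],
            self.name[mask], self.element[mask], self.xyz[mask],
            self.bfactor[mask], self.occupancy[mask],
        )

    def mask_atom_name(self, atom_name: str) -> np.ndarray:
        return self.name == atom_name

    def sidechain_mask(self) -> np.ndarray:
        """Heavy side-chain atoms: non-hydrogen, non-backbone."""
        heavy = ~np.isin(np.char.upper(self.element.astype(str)), ("H", "D"))
        return heavy & ~np.isin(self.name, tuple(BACKBONE_ATOMS))


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed topology."""

    topology: StructureModel
    xyz: np.ndarray            # (n_frames, n_atoms, 3), Angstrom
    frame_interval_ps: float = 4.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, float)
        if self.xyz.ndim != 3 or self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError("frames must match the topology atom count")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def frame(self, i: int) -> StructureModel:
        m = self.topology
        return StructureModel(
            m.chain, m.resnum, m.resname, m.name, m.element,
            self.xyz[i], m.bfactor, m.occupancy,
        )


@dataclass(frozen=True)
class ContactRecord:
    """A residue-residue side-chain contact and its persistence."""

    residue_i: tuple[str, int]   # (chain, resnum), canonically ordered i < j
    residue_j: tuple[str, int]
    persistence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        if self.residue_j < self.residue_i:
            raise ValueError("contact records must be canonically ordered (i < j)")


@dataclass
class RMSFProfile:
    """Per-residue RMSF, per window and window-averaged."""

    residues: list[tuple[str, int]]
    per_window: np.ndarray       # (n_windows, n_residues), Angstrom
    mean: np.ndarray             # (n_residues,), Angstrom
    window_ns: float


@dataclass
class SuperposeResult:
    rotation: np.ndarray         # (3, 3), proper rotation
    translation: np.ndarray      # (3,); x' = R x + t maps mobile onto reference
    rmsd: float                  # Angstrom, over matched atoms after fitting
    n_matched: int
    skipped: list[tuple[str, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PDB I/O (Biopython behind the surface)
# ---------------------------------------------------------------------------

def _model_to_arrays(model) -> StructureModel:
    chain, resnum, resname, name, element, xyz, bfac, occ = [], [], [], [], [], [], [], []
    for ch in model:
        for res in ch:
            het, seq, icode = res.get_id()
            if het.strip():
                continue  # skip waters/heteroatoms
            for atom in res:
                chain.append(ch.id)
                resnum.append(int(seq))
                resname.append(res.get_resname().strip())
                name.append(atom.get_name().strip())
                element.append((atom.element or "").strip() or atom.get_name()[0])
                xyz.append(atom.get_coord())
                bfac.append(float(atom.get_bfactor() or 0.0))
                occ.append(float(atom.get_occupancy() if atom.get_occupancy() is not None else 1.0))
    return StructureModel(
        np.array(chain), np.array(resnum, int), np.array(resname),
        np.array(name), np.array(element), np.array(xyz, float),
        np.array(bfac, float), np.array(occ, float),
    )


def _parse(path: str | Path):
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PDBParser(QUIET=True).get_structure(Path(path).stem, str(path))


def read_structure(path: str | Path) -> StructureModel:
    """First model of a PDB file as a StructureModel (with B-factors)."""
    structure = _parse(path)
    return _model_to_arrays(next(iter(structure)))


def read_trajectory(path: str | Path, frame_interval_ps: float = 4.0) -> Trajectory:
    """All MODEL records of a multi-model PDB as an ordered Trajectory."""
    structure = _parse(path)
    models = [_model_to_arrays(m) for m in structure]
    if not models:
        raise ValueError(f"no models found in {path}")
    topo = models[0]
    ref_keys = topo.atom_keys()
    frames = []
    for i, m in enumerate(models):
        if m.atom_keys() != ref_keys:
            raise ValueError(f"model {i + 1} atom list differs from model 1")
        frames.append(m.xyz)
    return Trajectory(topo, np.stack(frames), frame_interval_ps)


def _to_biopython(frames: Sequence[np.ndarray], topo: StructureModel):
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("ttrstab")
    for i, coords in enumerate(frames):
        builder.init_model(i)
        builder.init_seg("    ")
        current_chain = None
        current_res = None
        for j in range(topo.n_atoms):
            ch = topo.chain[j]
            if ch != current_chain:
                builder.init_chain(str(ch))
                current_chain = ch
                current_res = None
            key = (ch, int(topo.resnum[j]))
            if key != current_res:
                builder.init_residue(str(topo.resname[j]), " ", int(topo.resnum[j]), " ")
                current_res = key
            builder.init_atom(
                str(topo.name[j]), np.asarray(coords[j], float), float(topo.bfactor[j]),
                float(topo.occupancy[j]), " ", str(topo.name[j]).ljust(4),
                j + 1, element=str(topo.element[j]).upper(),
            )
    return builder.get_structure()


def write_structure(model: StructureModel, path: str | Path) -> None:
    write_trajectory(Trajectory(model, model.xyz[None, :, :], 1.0), path)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    from Bio.PDB import PDBIO

    io = PDBIO()
    io.set_structure(_to_biopython(list(traj.xyz), traj.topology))
    io.save(str(path))


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of P onto Q (both (n, 3)).

    Returns (R, t, rmsd) with the proper rotation R (det = +1, reflections
    corrected by the standard sign flip) such that ``P @ R.T + t`` best
    matches Q.
    """
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need at least 3 matched coordinate pairs")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection: str = "CA",
) -> SuperposeResult:
    """Rigid-body superposition of matched atoms and its RMSD.

    Atoms are matched by (chain, residue number, atom name) on the chosen
    atom-name selection; unmatched atoms are skipped and reported.
    """
    mob_mask = mobile.mask_atom_name(selection)
    ref_mask = reference.mask_atom_name(selection)
    mob_idx = {k: i for k, i in zip(
        (tuple(x) for x in zip(mobile.chain[mob_mask], mobile.resnum[mob_mask].tolist())),
        np.flatnonzero(mob_mask),
    )}
    ref_idx = {k: i for k, i in zip(
        (tuple(x) for x in zip(reference.chain[ref_mask], reference.resnum[ref_mask].tolist())),
        np.flatnonzero(ref_mask),
    )}
    common = [k for k in mob_idx if k in ref_idx]
    skipped = [
        (c, r, selection)
        for c, r in sorted(set(mob_idx) ^ set(ref_idx))
    ]
    if skipped:
        logger.info("superpose: skipped %d unmatched %s atoms: %s",
                    len(skipped), selection, skipped[:10])
    if len(common) < 3:
        raise ValueError(f"only {len(common)} matched pairs; need at least 3")
    P = mobile.xyz[[mob_idx[k] for k in common]]
    Q = reference.xyz[[ref_idx[k] for k in common]]
    R, t, rmsd = _kabsch(P, Q)
    return SuperposeResult(R, t, rmsd, len(common), skipped)


# ---------------------------------------------------------------------------
# Windowed RMSF
# ---------------------------------------------------------------------------

def rmsf_windowed(
    traj: Trajectory, window_ns: float = 10.0, selection: str = "CA"
) -> RMSFProfile:
    """Average per-residue RMSF over fixed-length time windows.

    Within each window every frame is superposed onto the window-average
    structure (mean recomputed and the fit iterated once), then
    ``RMSF_i = sqrt(<|r_i - <r_i>|^2>)``.  The profile is the mean over
    complete windows; a trailing partial window is discarded.
    """
    mask = traj.topology.mask_atom_name(selection)
    if not np.any(mask):
        raise ValueError(f"selection {selection!r} matches no atoms")
    frames_per_window = int(round(window_ns * 1000.0 / traj.frame_interval_ps))
    if frames_per_window < 2:
        raise ValueError("window shorter than two frames")
    n_windows = traj.n_frames // frames_per_window
    if n_windows < 1:
        raise ValueError(
            f"trajectory spans {traj.n_frames} frames "
            f"(< one {window_ns} ns window of {frames_per_window} frames)"
        )
    residues = [
        (c, r) for c, r in zip(
            traj.topology.chain[mask], traj.topology.resnum[mask].tolist()
        )
    ]
    X_all = traj.xyz[:, mask, :]
    per_window = np.empty((n_windows, len(residues)))
    for w in range(n_windows):
        X = X_all[w * frames_per_window:(w + 1) * frames_per_window].copy()
        mean = X.mean(axis=0)
        for _ in range(2):  # fit -> recompute mean -> fit (iterated once)
            for f in range(X.shape[0]):
                R, t, _ = _kabsch(X[f], mean)
                X[f] = X[f] @ R.T + t
            mean = X.mean(axis=0)
        per_window[w] = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    return RMSFProfile(residues, per_window, per_window.mean(axis=0), window_ns)


def rmsf_compare(
    a: RMSFProfile,
    b: RMSFProfile,
    regions: dict[str, tuple[int, int]] | None = None,
) -> dict:
    """Per-residue RMSF difference (a - b) and per-region summaries.

    Residue keys must match exactly.  ``regions`` maps names to inclusive
    residue-number ranges; summaries report mean and max difference per
    region over all chains.  An explicitly requested region with no
    profiled residues is an error; regions of the default TTR loop table
    that fall outside the profile are skipped with a log entry.
    """
    if a.residues != b.residues:
        missing = sorted(set(a.residues) ^ set(b.residues))
        raise ValueError(f"RMSF profiles cover different residues: {missing[:20]}")
    explicit = regions is not None
    regions = LOOP_REGIONS if regions is None else regions
    delta = a.mean - b.mean
    resnums = np.array([r for _, r in a.residues])
    summary: dict[str, dict[str, float]] = {}
    for name, (lo, hi) in regions.items():
        m = (resnums >= lo) & (resnums <= hi)
        if not np.any(m):
            if explicit:
                raise ValueError(
                    f"region {name!r} ({lo}-{hi}) contains no profiled residues"
                )
            logger.info("rmsf_compare: default region %s outside profile; skipped", name)
            continue
        summary[name] = {
            "mean_delta": float(delta[m].mean()),
            "max_delta": float(delta[m].max()),
            "n_residues": int(m.sum()),
        }
    return {"residues": a.residues, "delta": delta, "regions": summary}


# ---------------------------------------------------------------------------
# Side-chain contact persistence
# ---------------------------------------------------------------------------

def contact_persistence(
    traj: Trajectory, cutoff: float = 4.5, min_seq_sep: int = 2
) -> list[ContactRecord]:
    """Side-chain contact persistence over a trajectory.

    Two residues are in contact in a frame if any pair of their side-chain
    heavy atoms lies within ``cutoff`` Angstrom and they are either on
    different chains or separated by at least ``min_seq_sep`` in sequence
    (the default 2 excludes nearest neighbours).  Persistence is the
    fraction of frames in contact; pairs never in contact are omitted.
    Glycines carry no side-chain heavy atoms and so contribute no contacts.
    """
    topo = traj.topology
    sc = topo.sidechain_mask()
    residues = topo.residue_keys()
    res_index = {k: i for i, k in enumerate(residues)}
    no_sc = [k for k in residues if not np.any(
        sc & (topo.chain == k[0]) & (topo.resnum == k[1])
    )]
    if no_sc:
        logger.info("contact_persistence: %d residue(s) without side-chain "
                    "heavy atoms (e.g. Gly) yield no contacts", len(no_sc))
    sc_idx = np.flatnonzero(sc)
    if sc_idx.size == 0:
        return []
    atom_res = np.array([res_index[(c, r)] for c, r in zip(
        topo.chain[sc], topo.resnum[sc].tolist()
    )])
    n_res = len(residues)
    chains = np.array([c for c, _ in residues])
    nums = np.array([r for _, r in residues])
    eligible = (chains[:, None] != chains[None, :]) | (
        np.abs(nums[:, None] - nums[None, :]) >= min_seq_sep
    )
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    for f in range(traj.n_frames):
        xyz = traj.xyz[f, sc_idx, :]
        close = cdist(xyz, xyz) <= cutoff
        frame_contact = np.zeros((n_res, n_res), dtype=bool)
        ai, aj = np.nonzero(close)
        frame_contact[atom_res[ai], atom_res[aj]] = True
        counts += frame_contact
    records: list[ContactRecord] = []
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if not eligible[i, j]:
                continue
            c = max(counts[i, j], counts[j, i])
            if c == 0:
                continue
            records.append(ContactRecord(residues[i], residues[j], c / traj.n_frames))
    return records


def region_contact_frequency(
    records: Iterable[ContactRecord],
    region_residues: Iterable[int],
    chain: str,
) -> dict:
    """Count and mean persistence of contacts touching a region of a chain.

    A record is counted if at least one partner lies in ``region_residues``
    on ``chain``.  Differencing two trajectories is done by calling this on
    each record list and subtracting the summaries.
    """
    region = set(region_residues)
    if not region:
        raise ValueError("empty region")
    hits = [
        r for r in records
        if (r.residue_i[0] == chain and r.residue_i[1] in region)
        or (r.residue_j[0] == chain and r.residue_j[1] in region)
    ]
    return {
        "count": len(hits),
        "mean_persistence": float(np.mean([r.persistence for r in hits])) if hits else 0.0,
        "records": hits,
    }


# ---------------------------------------------------------------------------
# Static-structure profiling
# ---------------------------------------------------------------------------

def hbond_distance(
    model: StructureModel,
    resA: int,
    resB: int,
    atomsA: Sequence[str] = ("N", "O"),
    atomsB: Sequence[str] = ("N", "O"),
    cross_only: bool = True,
) -> list[dict]:
    """Main-chain donor-acceptor distances between two residues, per chain.

    For every chain containing both residues, all requested cross
    distances (by default N...O and O...N; ``cross_only=False`` also
    returns like-atom pairs) are computed and returned sorted ascending,
    each labelled with chain and atom names.  Zero-distance self pairs
    (same residue, same atom) are excluded; missing atoms raise an error
    naming them.
    """
    out: list[dict] = []
    chains = sorted(set(model.chain))
    seen_pair = False
    for ch in chains:
        maskA = (model.chain == ch) & (model.resnum == resA)
        maskB = (model.chain == ch) & (model.resnum == resB)
        if not (np.any(maskA) and np.any(maskB)):
            continue
        seen_pair = True
        missing = [
            f"{ch}/{num}/{nm}"
            for nm_list, num, msk in ((atomsA, resA, maskA), (atomsB, resB, maskB))
            for nm in nm_list
            if nm not in set(model.name[msk])
        ]
        if missing:
            raise ValueError(f"missing atoms: {', '.join(missing)}")
        coordsA = {nm: model.xyz[maskA & (model.name == nm)][0] for nm in atomsA}
        coordsB = {nm: model.xyz[maskB & (model.name == nm)][0] for nm in atomsB}
        for na in atomsA:
            for nb in atomsB:
                if resA == resB and na == nb:
                    continue  # zero-distance self pair
                if cross_only and na == nb:
                    continue
                d = float(np.linalg.norm(coordsA[na] - coordsB[nb]))
                out.append({
                    "chain": ch, "atomA": f"{resA}/{na}", "atomB": f"{resB}/{nb}",
                    "distance": d,
                })
    if not seen_pair:
        raise ValueError(f"no chain contains both residues {resA} and {resB}")
    return sorted(out, key=lambda r: r["distance"])


def bfactor_profile(
    model: StructureModel,
    selection: str = "CA",
    regions: dict[str, tuple[int, int]] | None = None,
) -> dict:
    """Per-residue B-factors of a selection and region/chain mean ratios.

    Returns per-chain residue numbers and B values, the per-region mean B,
    and the ratio of each region mean to the whole-chain mean.  Residues
    lacking the selected atom are skipped with a log entry.
    """
    regions = LOOP_REGIONS if regions is None else regions
    mask = model.mask_atom_name(selection)
    if not np.any(mask):
        raise ValueError(f"selection {selection!r} matches no atoms")
    out: dict = {"per_chain": {}, "region_means": {}, "region_ratio": {}}
    for ch in sorted(set(model.chain)):
        m = mask & (model.chain == ch)
        resnums = model.resnum[m]
        bvals = model.bfactor[m]
        all_res = sorted({int(r) for c, r in zip(model.chain, model.resnum) if c == ch})
        skipped = sorted(set(all_res) - set(resnums.tolist()))
        if skipped:
            logger.info("bfactor_profile: chain %s residues without %s skipped: %s",
                        ch, selection, skipped[:10])
        chain_mean = float(bvals.mean())
        out["per_chain"][ch] = {"resnum": resnums.copy(), "b": bvals.copy()}
        out["region_means"][ch] = {}
        out["region_ratio"][ch] = {}
        for name, (lo, hi) in regions.items():
            rm = (resnums >= lo) & (resnums <= hi)
            if not np.any(rm):
                continue
            region_mean = float(bvals[rm].mean())
            out["region_means"][ch][name] = region_mean
            out["region_ratio"][ch][name] = region_mean / chain_mean
    return out
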