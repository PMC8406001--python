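"""End-to-end orchestration: simulate -> analyze -> report.

A :class:`RunConfig` (read from YAML or JSON) names the stages to run and
their inputs; :func:`run` executes them in dependency order, writes
per-stage TSV/JSON outputs plus a single machine-readable ``summary.json``
(fitted midpoints, s20,w table, species percentages, region flexibility
summaries), and records every inherited default in the log.  One master
seed is split deterministically per stage so toggling a stage does not
shift another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import VBAR_25, logger
from .denaturation import (
    DenaturationCurve,
    StabilityModelParams,
    fit_curve,
    read_curve_csv,
    write_curve_csv,
)
from .hydro import SolventConditions, integrate_species, read_cs_distribution, s20w, write_cs_distribution
from .spectra import center_of_spectral_mass, intensity_ratio, read_spectrum_csv, write_spectrum_csv
from .structdyn import (
    contact_persistence,
    read_structure,
    read_trajectory,
    rmsf_windowed,
    superpose,
    write_trajectory,
)
from .synthetic import (
    GaussianBasis,
    SpectrumSeriesSpec,
    TrajectorySpec,
    gen_cs_distribution,
    gen_denaturation_curve,
    gen_spectra_series,
    gen_trajectory,
    make_reference_structure,
)

__all__ = ["RunConfig", "run"]

_STAGE_ORDER = (
    "simulate", "csm", "fit_denat", "s20w", "cs_integrate",
    "traj_rmsf", "traj_contacts", "struct_rmsd",
)


@dataclass
class RunConfig:
    """Validated run configuration.

    ``stages`` maps stage names (a subset of the known stages) to their
    option dicts; unknown stages are rejected.  The configuration
    round-trips unchanged through :meth:`to_dict`.
    """

    outdir: str = "ttrstab_out"
    seed: int = 0
    stages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            outdir=d.get("outdir", "ttrstab_out"),
            seed=int(d.get("seed", 0)),
            stages=dict(d.get("stages", {})),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {"outdir": self.outdir, "seed": self.seed, "stages": self.stages}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _model_from_dict(d: dict) -> StabilityModelParams:
    return StabilityModelParams(**d)


def run(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the summary dict (also written to ``<outdir>/summary.json``).
    A stage failure preserves the partial results and re-raises after
    recording the cause in the summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "tool": "ttrstab",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    artifacts: dict = {}
    try:
        for stage in _STAGE_ORDER:
            if stage not in config.stages:
                continue
            opts = config.stages[stage] or {}
            seed = _stage_seed(config.seed, stage)
            logger.info("running stage %s (seed %d)", stage, seed)
            summary["stages"][stage] = _STAGE_FUNCS[stage](opts, seed, outdir, artifacts)
    except Exception as exc:
        summary["error"] = f"{type(exc).__name__}: {exc}"
        _write_summary(summary, outdir)
        raise
    _write_summary(summary, outdir)
    return summary


def _write_summary(summary: dict, outdir: Path) -> None:
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _grid(spec: dict) -> np.ndarray:
    return np.linspace(float(spec["start"]), float(spec["stop"]), int(spec["n"]))


def _stage_simulate(opts: dict, seed: int, outdir: Path, artifacts: dict) -> dict:
    info: dict = {}
    if "curve" in opts:
        o = opts["curve"]
        model = _model_from_dict(o["params"])
        curve = gen_denaturation_curve(
            model, float(o["protomer_conc"]), _grid(o["grid"]),
            noise_sd=float(o.get("noise_sd", 0.0)), seed=seed,
            observable=o.get("observable", "ratio"),
        )
        path = outdir / "curve.csv"
        write_curve_csv(curve, path)
        artifacts["curve"] = curve
        artifacts["curve_truth"] = model
        info["curve"] = {"path": str(path), "n_points": int(curve.denaturant.size)}
    if "spectra" in opts:
        o = opts["spectra"]
        sspec = SpectrumSeriesSpec(
            denaturant_grid=tuple(o.get("denaturant_grid", np.arange(0.0, 9.01, 0.5))),
            noise_sd=float(o.get("noise_sd", 0.0)),
            seed=seed,
            folded_basis=GaussianBasis(**o.get("folded_basis", {"center_nm": 335.0})),
            unfolded_basis=GaussianBasis(**o.get("unfolded_basis", {"center_nm": 355.0})),
        )
        series = gen_spectra_series(
            sspec, _model_from_dict(o["params"]), float(o["protomer_conc"])
        )
        paths = []
        for i, s in enumerate(series):
            p = outdir / f"spectrum_{i:03d}.csv"
            write_spectrum_csv(s, p)
            paths.append(str(p))
        artifacts["spectra"] = series
        info["spectra"] = {"n": len(series), "paths": paths[:3] + (["..."] if len(paths) > 3 else [])}
    if "cs" in opts:
        o = opts["cs"]
        dist = gen_cs_distribution(
            [tuple(map(float, sp)) for sp in o["species"]], _grid(o["grid"]),
            seed=seed, noise_sd=float(o.get("noise_sd", 0.0)),
        )
        path = outdir / "cs_distribution.txt"
        write_cs_distribution(dist, path)
        artifacts["cs"] = dist
        info["cs"] = {"path": str(path)}
    if "trajectory" in opts:
        o = opts["trajectory"]
        tspec = TrajectorySpec(
            n_residues=int(o["n_residues"]),
            chain_ids=tuple(o.get("chain_ids", ("A",))),
            n_frames=int(o.get("n_frames", 100)),
            frame_interval_ps=float(o.get("frame_interval_ps", 4.0)),
            per_residue_sigma=o.get("per_residue_sigma", 0.3),
            contact_schedule=tuple(
                (tuple(pair), float(p)) for pair, p in o.get("contact_schedule", [])
            ),
            seed=seed,
        )
        ref = make_reference_structure(tspec.n_residues, tspec.chain_ids)
        traj = gen_trajectory(tspec, ref)
        path = outdir / "trajectory.pdb"
        write_trajectory(traj, path)
        artifacts["trajectory"] = traj
        info["trajectory"] = {"path": str(path), "n_frames": traj.n_frames}
    return info


def _resolve_curve(opts: dict, artifacts: dict) -> DenaturationCurve:
    src = opts.get("curve", "simulated")
    if src == "simulated":
        if "curve" not in artifacts:
            raise ValueError("fit_denat: no simulated curve available; add a simulate stage")
        return artifacts["curve"]
    return read_curve_csv(src)


def _stage_fit_denat(opts: dict, seed: int, outdir: Path, artifacts: dict) -> dict:
    curve = _resolve_curve(opts, artifacts)
    if "init" in opts:
        init = _model_from_dict(opts["init"])
    elif "curve_truth" in artifacts:
        init = artifacts["curve_truth"]
        logger.info("fit_denat: using simulation ground truth as the initial guess")
    else:
        raise ValueError("fit_denat: an init parameter set is required for external curves")
    result = fit_curve(
        curve,
        model=opts.get("model", "two_population"),
        init=init,
        fixed=tuple(opts.get("fixed", ())),
        n_boot=int(opts.get("n_boot", 0)),
        seed=seed,
    )
    result.to_json(outdir / "fit_denat.json")
    return {
        "success": result.success,
        "Cm1": result.midpoints[0],
        "Cm2": result.midpoints[1],
        "cost": result.cost,
    }


def _stage_csm(opts: dict, seed: int, outdir: Path, artifacts: dict) -> dict:
    if "paths" in opts:
        series = [read_spectrum_csv(p) for p in opts["paths"]]
    elif "spectra" in artifacts:
        series = artifacts["spectra"]
    else:
        raise ValueError("csm: no spectra given or simulated")
    rows = []
    for s in series:
        rows.append({
            "denaturant_M": s.meta.get("denaturant_M", float("nan")),
            "csm_cm1": center_of_spectral_mass(s),
            "ratio_355_335": intensity_ratio(s),
        })
    path = outdir / "csm.tsv"
    with path.open("w") as fh:
        fh.write("denaturant_M\tcsm_cm1\tratio_355_335\n")
        for r in rows:
            fh.write(f"{r['denaturant_M']}\t{r['csm_cm1']:.4f}\t{r['ratio_355_335']:.6f}\n")
    return {"path": str(path), "n": len(rows)}


def _stage_s20w(opts: dict, seed: int, outdir: Path, artifacts: dict) -> dict:
    cond = SolventConditions(**opts.get("conditions", {}))
    vbar25 = float(opts.get("vbar25", VBAR_25))
    logger.info("s20w: using vbar25 = %.4f mL/g", vbar25)
    values = {str(s): s20w(float(s), cond, vbar25) for s in opts["s_obs"]}
    path = outdir / "s20w.tsv"
    with path.open("w") as fh:
        fh.write("s_obs_S\ts20w_S\n")
        for k, v in values.items():
            fh.write(f"{k}\t{v:.4f}\n")
    return {"path": str(path), "s20w": values, "vbar25": vbar25}


def _stage_cs_integrate(opts: dict, seed: int, outdir: Path, artifacts: dict) -> dict:
    if "path" in opts and opts["path"] != "simulated":
        dist = read_cs_distribution(opts["path"])
    elif "cs" in artifacts:
        dist = artifacts["cs"]
    else:
        raise ValueError("cs_integrate: no c(s) distribution given or simulated")
    bounds = opts.get("boundaries")
    if bounds is not None:
        bounds = {k: (float(v[0]), float(v[1])) for k, v in bounds.items()}
    pct = integrate_species(dist, bounds)
    path = outdir / "species.tsv"
    with path.open("w") as fh:
        fh.write("class\tpercent\n")
        for k, v in pct.items():
            fh.write(f"{k}\t{v:.3f}\n")
    return {"path": str(path), "percent": pct}


def _resolve_traj(opts: dict, artifacts: dict):
    if "path" in opts and opts["path"] != "simulated":
        return read_trajectory(opts["path"], float(opts.get("frame_interval_ps", 4.0)))
    if "trajectory" in artifacts:
        return artifacts["trajectory"]
    raise ValueError("no trajectory given or simulated")


def _stage_traj_rmsf(opts: dict, seed: int, outdir: Path, artifacts: dict) -> dict:
    traj = _resolve_traj(opts, artifacts)
    prof = rmsf_windowed(traj, window_ns=float(opts.get("window_ns", 10.0)))
    path = outdir / "rmsf.tsv"
    with path.open("w") as fh:
        fh.write("chain\tresnum\trmsf_A\n")
        for (ch, rn), v in zip(prof.residues, prof.mean):
            fh.write(f"{ch}\t{rn}\t{v:.4f}\n")
    return {"path": str(path), "n_windows": int(prof.per_window.shape[0])}


def _stage_traj_contacts(opts: dict, seed: int, outdir: Path, artifacts: dict) -> dict:
    traj = _resolve_traj(opts, artifacts)
    records = contact_persistence(
        traj,
        cutoff=float(opts.get("cutoff", 4.5)),
        min_seq_sep=int(opts.get("min_seq_sep", 2)),
    )
    path = outdir / "contacts.tsv"
    with path.open("w") as fh:
        fh.write("i_chain\ti_res\tj_chain\tj_res\tpersistence\n")
        for r in records:
            fh.write(
                f"{r.residue_i[0]}\t{r.residue_i[1]}\t"
                f"{r.residue_j[0]}\t{r.residue_j[1]}\t{r.persistence:.6f}\n"
            )
    return {"path": str(path), "n_contacts": len(records)}


def _stage_struct_rmsd(opts: dict, seed: int, outdir: Path, artifacts: dict) -> dict:
    mobile = read_structure(opts["mobile"])
    reference = read_structure(opts["reference"])
    res = superpose(mobile, reference, selection=opts.get("selection", "CA"))
    return {
        "rmsd_A": res.rmsd,
        "n_matched": res.n_matched,
        "n_skipped": len(res.skipped),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "csm": _stage_csm,
    "fit_denat": _stage_fit_denat,
    "s20w": _stage_s20w,
    "cs_integrate": _stage_cs_integrate,
    "traj_rmsf": _stage_traj_rmsf,
    "traj_contacts": _stage_traj_contacts,
    "struct_rmsd": _stage_struct_rmsd,
}
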