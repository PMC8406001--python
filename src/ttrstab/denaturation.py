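"""Linked tetramer-dissociation / monomer-unfolding denaturation model.

Urea denaturation of transthyretin (TTR) is biphasic.  The model treats the
protein as two coexisting tetramer populations:

* a **non-stabilized** population that equilibrates on the experimental
  timescale: tetramer T4 dissociates to partially folded monomers
  (dissociation constant ``K_D = [M]^4/[T4]``, M^3), which then unfold in a
  two-state step (``K_U``).  Both free energies depend linearly on
  denaturant concentration D (linear extrapolation model,
  ``dG(D) = dG(0) - m*D``).
* a **stabilized** population (fraction ``alpha_stab``) whose dissociation
  is kinetically frozen; its late, *apparent* transition is modelled as an
  empirical two-state sigmoid with apparent parameters ``dG2_app, m2_app``
  — not as an equilibrium tetramer model, because it does not reach
  equilibrium.

Mass action for the dissociating population, in protomer units
(``C`` = protomer concentration, ``[T4] = C*fT/4``, ``[M] = C*fM``):

    K_D = 4 C^3 fM^4 / fT,   fT + fM = 1

which has a unique root fM in (0, 1).  The observable (355/335 ratio, CSM,
or resveratrol F394) is a population-weighted sum of linear baselines for
the folded tetramer, intermediate monomer and unfolded monomer states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterable, Sequence

import lmfit
import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .config import RT, BOOTSTRAP_REPLICATES, logger

__all__ = [
    "StabilityModelParams",
    "DenaturationCurve",
    "FitResult",
    "params_from_midpoints",
    "tetramer_fraction",
    "population_fractions",
    "tetramer_population_fraction",
    "predict_signal",
    "fit_curve",
    "transition_midpoints",
    "read_curve_csv",
    "write_curve_csv",
]

# Parameter names in canonical order (used by the fitter).
_PARAM_NAMES = (
    "dG_diss", "m_diss", "dG_unf", "m_unf",
    "alpha_stab", "dG2_app", "m2_app",
    "s_T0", "s_T1", "s_M0", "s_M1", "s_U0", "s_U1",
)


@dataclass(frozen=True)
class StabilityModelParams:
    """Parameters of the two-population dissociation/unfolding model.

    Free energies in kcal/mol (aqueous, 25 degC), m-values in kcal/mol/M.
    ``s_X0 + s_X1 * D`` are the linear signal baselines of the folded
    tetramer (T), intermediate/partially folded monomer (M) and unfolded
    monomer (U) states.
    """

    dG_diss: float        # tetramer -> 4 monomers, houses K_D
    m_diss: float
    dG_unf: float         # monomer unfolding, houses K_U
    m_unf: float
    alpha_stab: float = 0.0   # fraction of kinetically stabilized tetramers
    dG2_app: float = 30.0     # apparent two-state step of the stabilized population
    m2_app: float = 4.0
    s_T0: float = 1.0
    s_T1: float = 0.0
    s_M0: float = 1.5
    s_M1: float = 0.0
    s_U0: float = 2.0
    s_U1: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_diss", "m_unf", "m2_app"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.alpha_stab <= 1.0:
            raise ValueError("alpha_stab must lie in [0, 1]")

    # -- linked equilibrium constants -------------------------------------
    def K_D(self, D) -> np.ndarray | float:
        """Tetramer dissociation constant at denaturant concentration D, M^3."""
        return np.exp(-(self.dG_diss - self.m_diss * np.asarray(D, float)) / RT)

    def K_U(self, D) -> np.ndarray | float:
        """Monomer unfolding constant at D (dimensionless)."""
        return np.exp(-(self.dG_unf - self.m_unf * np.asarray(D, float)) / RT)

    def K2_app(self, D) -> np.ndarray | float:
        """Apparent constant of the stabilized-population sigmoid at D."""
        return np.exp(-(self.dG2_app - self.m2_app * np.asarray(D, float)) / RT)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DenaturationCurve:
    """Ordered (denaturant, observable) pairs at a stated protomer concentration."""

    denaturant: np.ndarray          # mol/L grid, ascending
    signal: np.ndarray
    protomer_conc: float            # mol/L (4 x tetramer concentration)
    denaturant_type: str = "urea"   # urea | gdmhcl
    observable: str = "ratio"       # ratio | csm | F394

    def __post_init__(self) -> None:
        d = np.asarray(self.denaturant, float)
        s = np.asarray(self.signal, float)
        object.__setattr__(self, "denaturant", d)
        object.__setattr__(self, "signal", s)
        if d.size != s.size:
            raise ValueError("denaturant and signal grids differ in length")
        if d.size and not np.all(np.diff(d) >= 0):
            raise ValueError("denaturant grid must be ascending")
        if self.protomer_conc <= 0:
            raise ValueError("protomer_conc must be positive")


def params_from_midpoints(
    protomer_conc: float,
    cm1: float,
    m_diss: float = 2.0,
    cm_unf: float = 15.0,
    m_unf: float = 2.0,
    alpha_stab: float = 0.0,
    cm2: float = 6.5,
    m2_app: float = 4.0,
    **baselines: float,
) -> StabilityModelParams:
    """Build model parameters from transition midpoints.

    ``cm1`` is the denaturant concentration at which the non-stabilized
    tetramer fraction is 0.5 at the given protomer concentration
    (``dG_diss = m_diss * cm1 - RT ln(0.5 C^3)``); ``cm_unf`` and ``cm2``
    are the two-state midpoints of monomer unfolding and of the stabilized
    population's apparent transition.  Baseline keywords (``s_T0`` ...)
    pass through unchanged.
    """
    L = RT * np.log(0.5 * protomer_conc**3)
    return StabilityModelParams(
        dG_diss=m_diss * cm1 - L,
        m_diss=m_diss,
        dG_unf=m_unf * cm_unf,
        m_unf=m_unf,
        alpha_stab=alpha_stab,
        dG2_app=m2_app * cm2,
        m2_app=m2_app,
        **baselines,
    )


# ---------------------------------------------------------------------------
# Mass-action closure
# ---------------------------------------------------------------------------

def tetramer_fraction(protomer_conc: float, K_D: float) -> tuple[float, float]:
    """Fractions (fT, fM) of protomers in tetramer vs free monomer.

    Solves ``K_D = 4 C^3 fM^4 / fT`` with ``fT + fM = 1`` for the unique
    root fM in (0, 1).  ``K_D = 0`` gives (1, 0); K_D -> inf gives (0, 1).
    """
    if protomer_conc <= 0:
        raise ValueError("protomer_conc must be positive")
    if K_D < 0:
        raise ValueError("K_D must be non-negative")
    if K_D == 0.0:
        return 1.0, 0.0
    if not np.isfinite(K_D):
        return 0.0, 1.0
    c3 = 4.0 * protomer_conc ** 3

    # g is strictly increasing on [0,1]; g(0) = -K_D < 0, g(1) = c3 > 0.
    def g(fM: float) -> float:
        return c3 * fM ** 4 - K_D * (1.0 - fM)

    fM = brentq(g, 0.0, 1.0, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    fM = min(max(fM, 0.0), 1.0)
    return 1.0 - fM, fM


def _tetramer_fraction_vec(protomer_conc: float, K_D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K_D = np.atleast_1d(np.asarray(K_D, float))
    fT = np.empty_like(K_D)
    fM = np.empty_like(K_D)
    for i, kd in enumerate(K_D):
        fT[i], fM[i] = tetramer_fraction(protomer_conc, float(kd))
    return fT, fM


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

def population_fractions(D, params: StabilityModelParams, protomer_conc: float) -> dict:
    """Species fractions of the full two-population model at denaturant D.

    Returns a dict of arrays: ``fT_ns``/``fM_ns`` (within the
    non-stabilized population), ``fU_m`` (unfolded fraction of free
    monomer), ``f2`` (progress of the stabilized population's apparent
    transition), and overall protomer fractions ``folded``,
    ``intermediate``, ``unfolded`` which sum to 1.
    """
    D = np.atleast_1d(np.asarray(D, float))
    a = params.alpha_stab
    with np.errstate(over="ignore"):
        fT_ns, fM_ns = _tetramer_fraction_vec(protomer_conc, params.K_D(D))
    # two-state fractions K/(1+K) in overflow-safe logistic form
    fU_m = expit((params.m_unf * D - params.dG_unf) / RT)
    f2 = expit((params.m2_app * D - params.dG2_app) / RT)
    folded = (1.0 - a) * fT_ns + a * (1.0 - f2)
    unfolded = (1.0 - a) * fM_ns * fU_m + a * f2
    intermediate = (1.0 - a) * fM_ns * (1.0 - fU_m)
    return {
        "fT_ns": fT_ns, "fM_ns": fM_ns, "fU_m": fU_m, "f2": f2,
        "folded": folded, "intermediate": intermediate, "unfolded": unfolded,
    }


def tetramer_population_fraction(D, params: StabilityModelParams, protomer_conc: float):
    """Fraction of protomers that are tetrameric (both populations) at D."""
    f = population_fractions(D, params, protomer_conc)
    return (1.0 - params.alpha_stab) * f["fT_ns"] + params.alpha_stab * (1.0 - f["f2"])


def predict_signal(D, params: StabilityModelParams, protomer_conc: float):
    """Model observable at denaturant concentration(s) D.

    Non-stabilized population: ``fT*S_T + fM*(fU_m*S_U + (1-fU_m)*S_M)``.
    Stabilized population: a two-state sigmoid between S_T and S_U driven
    by ``dG2_app - m2_app*D``.  All baselines are linear in D.
    """
    D_arr = np.atleast_1d(np.asarray(D, float))
    f = population_fractions(D_arr, params, protomer_conc)
    S_T = params.s_T0 + params.s_T1 * D_arr
    S_M = params.s_M0 + params.s_M1 * D_arr
    S_U = params.s_U0 + params.s_U1 * D_arr
    nonstab = f["fT_ns"] * S_T + f["fM_ns"] * (f["fU_m"] * S_U + (1.0 - f["fU_m"]) * S_M)
    stab = S_T + f["f2"] * (S_U - S_T)
    out = (1.0 - params.alpha_stab) * nonstab + params.alpha_stab * stab
    return out if np.ndim(D) else float(out[0])


# ---------------------------------------------------------------------------
# Transition midpoints
# ---------------------------------------------------------------------------

def transition_midpoints(
    params: StabilityModelParams, protomer_conc: float
) -> tuple[float | None, float | None]:
    """(Cm1, Cm2) transition midpoints in M of denaturant.

    Cm1 is the denaturant concentration where the non-stabilized tetramer
    fraction fT = 0.5 (root-found on the mass-action closure); Cm2 where
    the stabilized-population sigmoid reaches 0.5.  A midpoint whose
    population is absent (alpha_stab = 0 or 1) is None.
    """
    Cm1 = Cm2 = None
    if params.alpha_stab < 1.0:
        # At fT = 0.5 the closure fixes K_D = 0.5 C^3, giving an exact
        # linear-in-D equation; use it as the bracket centre and root-find
        # on fT(D) - 0.5 for fidelity to the full model.
        target = (params.dG_diss + RT * np.log(0.5 * protomer_conc ** 3)) / params.m_diss

        def h(D: float) -> float:
            fT, _ = tetramer_fraction(protomer_conc, float(params.K_D(D)))
            return fT - 0.5

        Cm1 = float(brentq(h, target - 1.0, target + 1.0, xtol=1e-12))
    if params.alpha_stab > 0.0:
        Cm2 = params.dG2_app / params.m2_app
    return Cm1, Cm2


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Converged parameters plus uncertainty and diagnostics."""

    params: StabilityModelParams
    stderr: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)          # name -> (lo, hi), bootstrap 95%
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    cost: float = np.inf                            # residual sum of squares
    success: bool = False
    n_points: int = 0
    midpoints: tuple[float | None, float | None] = (None, None)
    message: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "params": self.params.as_dict(),
            "stderr": self.stderr,
            "ci95": {k: list(v) for k, v in self.ci.items()},
            "residuals": self.residuals.tolist(),
            "cost": self.cost,
            "success": self.success,
            "n_points": self.n_points,
            "Cm1": self.midpoints[0],
            "Cm2": self.midpoints[1],
            "message": self.message,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# The optimizer works in a midpoint parametrization (cm1, m_diss, cm_unf,
# m_unf, alpha_stab, cm2, m2_app, baselines): free energies of
# intermolecular steps carry a large concentration offset
# (RT ln(0.5 C^3) ~ -22 kcal/mol at micromolar C), which makes the raw
# (dG, m) space badly conditioned — small relative dG errors move the
# transition out of the data window entirely.  Midpoints are what the data
# constrain directly.

_INTERNAL_NAMES = (
    "cm1", "m_diss", "cm_unf", "m_unf",
    "alpha_stab", "cm2", "m2_app",
    "s_T0", "s_T1", "s_M0", "s_M1", "s_U0", "s_U1",
)

_INTERNAL_BOUNDS: dict[str, tuple[float, float]] = {
    "cm1": (-10.0, 30.0), "m_diss": (1e-2, 20.0),
    "cm_unf": (-10.0, 40.0), "m_unf": (1e-2, 20.0),
    "alpha_stab": (0.0, 1.0), "cm2": (-10.0, 40.0), "m2_app": (1e-2, 20.0),
    "s_T0": (-np.inf, np.inf), "s_T1": (-np.inf, np.inf),
    "s_M0": (-np.inf, np.inf), "s_M1": (-np.inf, np.inf),
    "s_U0": (-np.inf, np.inf), "s_U1": (-np.inf, np.inf),
}

#: external (free-energy) parameter name -> internal (midpoint) name
_FIXED_NAME_MAP = {
    "dG_diss": "cm1", "dG_unf": "cm_unf", "dG2_app": "cm2",
    **{k: k for k in _INTERNAL_NAMES},
}


def _conc_offset(protomer_conc: float) -> float:
    # RT ln(0.5 C^3): dG_diss = m_diss * Cm1 - offset
    return RT * np.log(0.5 * protomer_conc**3)


def _to_internal(params: StabilityModelParams, protomer_conc: float) -> dict:
    L = _conc_offset(protomer_conc)
    d = params.as_dict()
    out = {k: d[k] for k in _INTERNAL_NAMES if k in d}
    out["cm1"] = (d["dG_diss"] + L) / d["m_diss"]
    out["cm_unf"] = d["dG_unf"] / d["m_unf"]
    out["cm2"] = d["dG2_app"] / d["m2_app"]
    return out


def _from_internal(values: dict, protomer_conc: float) -> StabilityModelParams:
    L = _conc_offset(protomer_conc)
    v = {k: float(values[k]) for k in _INTERNAL_NAMES}
    return StabilityModelParams(
        dG_diss=v["m_diss"] * v["cm1"] - L,
        m_diss=v["m_diss"],
        dG_unf=v["m_unf"] * v["cm_unf"],
        m_unf=v["m_unf"],
        alpha_stab=v["alpha_stab"],
        dG2_app=v["m2_app"] * v["cm2"],
        m2_app=v["m2_app"],
        **{k: v[k] for k in _INTERNAL_NAMES if k.startswith("s_")},
    )


def _make_lmfit_params(
    init: StabilityModelParams, fixed: Iterable[str], model: str, protomer_conc: float
) -> lmfit.Parameters:
    fixed_internal = set()
    for name in fixed:
        if name not in _FIXED_NAME_MAP:
            raise ValueError(f"unknown parameter name in fixed: {name!r}")
        fixed_internal.add(_FIXED_NAME_MAP[name])
    if model == "one_population":
        fixed_internal |= {"alpha_stab", "cm2", "m2_app"}
    p = lmfit.Parameters()
    init_d = _to_internal(init, protomer_conc)
    for name in _INTERNAL_NAMES:
        lo, hi = _INTERNAL_BOUNDS[name]
        val = float(np.clip(init_d[name], lo, hi))
        if model == "one_population" and name == "alpha_stab":
            val = 0.0
        p.add(name, value=val, min=lo, max=hi, vary=name not in fixed_internal)
    return p


def fit_curve(
    curve: DenaturationCurve,
    model: str = "two_population",
    init: StabilityModelParams | None = None,
    fixed: Iterable[str] = (),
    n_boot: int = BOOTSTRAP_REPLICATES,
    n_starts: int = 5,
    seed: int | None = None,
    max_restarts: int = 3,
) -> FitResult:
    """Nonlinear least-squares fit of the denaturation model to a curve.

    Parameters listed in ``fixed`` are clamped at their ``init`` values;
    free-energy names (dG_diss, dG_unf, dG2_app) clamp the corresponding
    midpoint.  ``model='one_population'`` additionally clamps
    ``alpha_stab = 0``.  The optimizer works in a transition-midpoint
    parametrization (``cm1, cm_unf, cm2`` plus m-values and baselines) and
    reported standard errors / bootstrap CIs are keyed by those internal
    names.  Multiple perturbed starts are tried (lowest residual norm
    wins; ties go to the start whose solution moved least from ``init``);
    ``n_boot=0`` skips the bootstrap.
    """
    if model not in ("one_population", "two_population"):
        raise ValueError(f"unknown model {model!r}")
    if init is None:
        raise ValueError("an initial StabilityModelParams is required")
    D, y, C = curve.denaturant, curve.signal, curve.protomer_conc
    lm_init = _make_lmfit_params(init, fixed, model, C)
    n_free = sum(1 for q in lm_init.values() if q.vary)
    if D.size < 3 * n_free:
        logger.warning(
            "only %d points for %d free parameters (< 3 per parameter)", D.size, n_free
        )

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return predict_signal(D, _from_internal(p.valuesdict(), C), C) - y

    rng = np.random.default_rng(seed)

    def perturb(p0: lmfit.Parameters) -> None:
        # restarts scatter free midpoints across the sampled denaturant
        # window (local minima of sigmoid fits live in midpoint space) and
        # jitter the remaining free parameters
        for q in p0.values():
            if not q.vary:
                continue
            if q.name.startswith("cm"):
                q.value = float(rng.uniform(D.min(), D.max()))
            elif q.name == "alpha_stab":
                q.value = float(np.clip(q.value + rng.uniform(-0.1, 0.1), 0.0, 1.0))
            else:
                scale = abs(q.value) if q.value != 0 else 0.1
                q.value = float(
                    np.clip(q.value + scale * rng.uniform(-0.15, 0.15), q.min, q.max)
                )

    best = None
    best_cost = np.inf
    best_shift = np.inf
    init_vec = np.array([lm_init[k].value for k in _INTERNAL_NAMES])
    attempts = 0
    for start in range(max(1, n_starts)):
        p0 = lm_init.copy()
        if start > 0:
            perturb(p0)
        try:
            res = lmfit.minimize(residual, p0, method="least_squares")
            attempts += 1
        except Exception as exc:  # pragma: no cover - lmfit failures are rare
            logger.warning("fit start %d raised %s", start, exc)
            continue
        cost = float(np.sum(np.asarray(res.residual) ** 2))
        vec = np.array([res.params[k].value for k in _INTERNAL_NAMES])
        shift = float(np.linalg.norm(vec - init_vec))
        if cost < best_cost - 1e-14 or (abs(cost - best_cost) <= 1e-14 and shift < best_shift):
            best, best_cost, best_shift = res, cost, shift
        if attempts >= max(1, n_starts) + max_restarts:
            break

    if best is None:
        return FitResult(
            params=init, success=False, n_points=int(D.size),
            message="no fit attempt converged",
        )

    fitted = _from_internal(best.params.valuesdict(), C)
    stderr = {
        k: (float(best.params[k].stderr) if best.params[k].stderr is not None else float("nan"))
        for k in _INTERNAL_NAMES
        if best.params[k].vary
    }
    residuals = np.asarray(best.residual)
    ci: dict = {}
    if n_boot > 0:
        yhat = predict_signal(D, fitted, C)
        samples: dict[str, list[float]] = {k: [] for k in stderr}
        p_start = best.params.copy()
        for _ in range(n_boot):
            y_star = yhat + rng.choice(residuals, size=residuals.size, replace=True)

            def residual_b(p: lmfit.Parameters, y_b=y_star) -> np.ndarray:
                return predict_signal(D, _from_internal(p.valuesdict(), C), C) - y_b

            try:
                res_b = lmfit.minimize(residual_b, p_start.copy(), method="least_squares")
            except Exception:  # pragma: no cover
                continue
            for k in samples:
                samples[k].append(float(res_b.params[k].value))
        ci = {
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in samples.items()
            if v
        }

    return FitResult(
        params=fitted,
        stderr=stderr,
        ci=ci,
        residuals=residuals,
        cost=best_cost,
        success=True,
        n_points=int(D.size),
        midpoints=transition_midpoints(fitted, C),
        message="converged",
    )


# ---------------------------------------------------------------------------
# CSV I/O: denaturant_M,signal with "# key=value" metadata header
# ---------------------------------------------------------------------------

def write_curve_csv(curve: DenaturationCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# protomer_conc={curve.protomer_conc!r}",
        f"# denaturant_type={curve.denaturant_type}",
        f"# observable={curve.observable}",
        "denaturant_M,signal",
    ]
    lines += [f"{d:.10g},{s:.10g}" for d, s in zip(curve.denaturant, curve.signal)]
    path.write_text("\n".join(lines) + "\n")


def read_curve_csv(path: str | Path) -> DenaturationCurve:
    path = Path(path)
    meta: dict = {}
    D: list[float] = []
    y: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.lower().startswith("denaturant"):
            continue
        a, b = line.split(",")
        D.append(float(a))
        y.append(float(b))
    return DenaturationCurve(
        np.array(D),
        np.array(y),
        protomer_conc=float(meta.get("protomer_conc", "nan")),
        denaturant_type=meta.get("denaturant_type", "urea"),
        observable=meta.get("observable", "ratio"),
    )
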