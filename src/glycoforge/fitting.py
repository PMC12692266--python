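"""Objective functions and enzyme-concentration estimation.

Personalization fits six total enzyme concentrations (GnT I, GnT II, GnT III,
GalT, FucT, SiaT; Man II stays at its common value) to one subject's 22
experimental glycan-peak percentages by minimizing the weighted least-squares
objective

    phi(GP) = sum_i w_i (GP_i − GP_i^exp)^2,   w_i = min_j(GP_j^exp) / GP_i^exp,

so every peak contributes on a comparable scale (the smallest peak has weight
one).  A penalty enforces the observed chromatogram coverage: with GP_peaks
the summed concentration of peak-member glycans and GP_all the total modelled
glycan,

    g = 0.965 − GP_peaks/GP_all,   psi = max(0, g)^2,

reflecting that measured peaks account for at least 96.5% of total glycan in
the study populations.  The search minimizes phi + lambda*psi with a seeded
population-based evolutionary optimizer (differential evolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .model import FITTED_ENZYMES, GolgiModel
from .simulate import CompiledModel, SteadyStateError, simulate_sequential

__all__ = [
    "peak_weights",
    "objective",
    "penalty",
    "mean_relative_deviation",
    "FitResult",
    "personalize",
    "calibrate_common",
    "COVERAGE_THRESHOLD",
]

COVERAGE_THRESHOLD = 0.965
FAILURE_OBJECTIVE = 1e6  # assigned when the simulator fails during a search


def peak_weights(gp_exp: np.ndarray) -> np.ndarray:
    """Weights w_i = min_j(GP_j^exp)/GP_i^exp; the minimal peak gets weight 1."""
    gp_exp = np.asarray(gp_exp, dtype=float)
    if (gp_exp <= 0).any():
        raise ValueError("experimental peaks must be positive to define weights")
    return gp_exp.min() / gp_exp


def objective(gp_sim: np.ndarray, gp_exp: np.ndarray,
              weights: np.ndarray) -> float:
    """Weighted sum of squared peak deviations (dimensionless)."""
    gp_sim = np.asarray(gp_sim, dtype=float)
    gp_exp = np.asarray(gp_exp, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (gp_sim.shape == gp_exp.shape == weights.shape):
        raise ValueError("gp_sim, gp_exp and weights must have equal length")
    return float(np.sum(weights * (gp_sim - gp_exp) ** 2))


def penalty(gp_peaks_conc: float, gp_all_conc: float,
            threshold: float = COVERAGE_THRESHOLD) -> float:
    """Quadratic penalty when peak coverage falls below the threshold."""
    if gp_all_conc <= 0:
        raise ValueError("total glycan concentration must be positive")
    g = threshold - gp_peaks_conc / gp_all_conc
    return max(0.0, g) ** 2


def mean_relative_deviation(gp_sim_cohort: np.ndarray,
                            gp_exp_cohort: np.ndarray) -> float:
    """Cohort mean of |GP_sim − GP_exp| / GP_exp, in percent.

    Implemented with absolute deviations so subject- and peak-level errors
    cannot cancel.
    """
    sim = np.asarray(gp_sim_cohort, dtype=float)
    exp = np.asarray(gp_exp_cohort, dtype=float)
    if sim.shape != exp.shape:
        raise ValueError("cohort arrays must have matching shapes")
    if (exp <= 0).any():
        raise ValueError("experimental peaks must be positive")
    return float(np.mean(np.abs(sim - exp) / exp) * 100.0)


@dataclass
class FitResult:
    """Outcome of one per-subject enzyme-concentration fit."""

    totals: Dict[str, float]        # fitted enzyme totals, uM
    objective: float                # phi at the optimum
    penalty: float                  # psi at the optimum
    combined: float                 # phi + lambda*psi actually minimized
    n_evaluations: int
    n_iterations: int
    converged: bool
    seed: Optional[int]
    n_failures: int = 0             # simulator failures during the search
    message: str = ""


class _PersonalObjective:
    """phi + lambda*psi as a function of the six fitted totals."""

    def __init__(self, compiled: CompiledModel, gp_exp: np.ndarray,
                 weights: np.ndarray, lam: float, sim_tol: float):
        self.compiled = compiled
        self.gp_exp = gp_exp
        self.weights = weights
        self.lam = lam
        self.sim_tol = sim_tol
        self.n_failures = 0

    def parts(self, x: np.ndarray) -> Tuple[float, float]:
        totals = dict(zip(FITTED_ENZYMES, np.clip(x, 0.0, None)))
        try:
            res = simulate_sequential(self.compiled, totals, tol=self.sim_tol)
        except SteadyStateError:
            self.n_failures += 1
            return FAILURE_OBJECTIVE, 0.0
        phi = objective(res.gp, self.gp_exp, self.weights)
        psi = penalty(res.gp_peaks, res.gp_all)
        return phi, psi

    def __call__(self, x: np.ndarray) -> float:
        phi, psi = self.parts(x)
        return phi + self.lam * psi


def personalize(
    gp_exp: np.ndarray,
    model: GolgiModel,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    lam: float = 1.0,
    seed: Optional[int] = None,
    popsize: int = 8,
    maxiter: int = 30,
    tol: float = 1e-10,
    sim_tol: float = 1e-8,
    polish: bool = True,
    compiled: Optional[CompiledModel] = None,
    init: str = "sobol",
    method: str = "de",
    x0: Optional[Mapping[str, float]] = None,
) -> FitResult:
    """Fit the six individual enzyme totals to one subject's peak vector.

    Parameters
    ----------
    gp_exp:
        22 experimental peak percentages (all positive), ordered as the
        model's peak table.
    bounds:
        Per-enzyme search ranges (uM); defaults to the model's bounds.
    lam:
        Weight of the coverage penalty psi (the penalty shares phi's
        dimensionless scale).
    seed:
        Seeds the evolutionary search; fixed seed gives a deterministic fit.
    method:
        ``"de"`` — seeded differential evolution (global, default);
        ``"local"`` — bounded local refinement (L-BFGS-B) warm-started at
        *x0* (default: the model's median totals).  The local mode is
        deterministic and much cheaper; appropriate for cohort-scale fitting
        when subjects are moderate perturbations of the population medians.
    """
    gp_exp = np.asarray(gp_exp, dtype=float)
    if gp_exp.shape != (model.peaks.n_peaks,):
        raise ValueError(f"expected {model.peaks.n_peaks} peaks, got {gp_exp.shape}")
    weights = peak_weights(gp_exp)
    bnds = dict(model.bounds)
    if bounds:
        bnds.update(bounds)
    box = [bnds[e] for e in FITTED_ENZYMES]
    compiled = compiled or CompiledModel(model)
    fun = _PersonalObjective(compiled, gp_exp, weights, lam, sim_tol)

    if method == "local":
        from scipy.optimize import minimize
        start = np.array([(x0 or model.totals)[e] for e in FITTED_ENZYMES])
        start = np.clip(start, [b[0] for b in box], [b[1] for b in box])
        result = minimize(fun, start, method="L-BFGS-B", bounds=box,
                          options={"maxiter": 300, "ftol": 1e-14})
        nit = int(result.nit)
    elif method == "de":
        result = differential_evolution(
            fun, bounds=box, seed=seed, popsize=popsize, maxiter=maxiter,
            tol=tol, init=init, polish=polish, updating="deferred",
        )
        nit = int(result.nit)
    else:
        raise ValueError(f"unknown method {method!r}")
    if fun.n_failures > 0 and not np.isfinite(result.fun):
        raise SteadyStateError("simulator failed for every candidate parameter set")
    phi, psi = fun.parts(result.x)
    return FitResult(
        totals=dict(zip(FITTED_ENZYMES, (float(v) for v in result.x))),
        objective=phi, penalty=psi, combined=float(result.fun),
        n_evaluations=int(result.nfev), n_iterations=nit,
        converged=bool(result.success), seed=seed,
        n_failures=fun.n_failures, message=str(result.message),
    )


# ---------------------------------------------------------------------------
# Two-stage common-parameter calibration
# ---------------------------------------------------------------------------

@dataclass
class CommonParameters:
    """Outcome of the two-stage common-parameter calibration."""

    factors: Dict[str, float]               # stage-1 median correction factors
    distribution: Dict[str, tuple]          # stage-2 distribution fractions
    manii_total: float                      # fixed common Man II total (uM)
    per_subject_stage1: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_subject_stage2: pd.DataFrame = field(default_factory=pd.DataFrame)


#: distribution coefficients re-fitted in stage 2 (enzyme, compartment index);
#: the remaining 23 keep their literature values
STAGE2_FREE_FRACTIONS: Tuple[Tuple[str, int], ...] = (
    ("FucT", 0), ("FucT", 1), ("FucT", 2),
    ("GnTI", 0), ("GnTI", 1),
)


def _fit_subject_factors(
    model: GolgiModel, gp_exp: np.ndarray, groups: Sequence[str],
    factor_bounds: Tuple[float, float], lam: float, seed: int,
    popsize: int, maxiter: int, sim_tol: float,
) -> Dict[str, float]:
    """Stage-1 inner fit: log-correction-factors + seven totals for one subject.

    Man II is included here so its per-subject estimates can be medianed and
    fixed as a common value afterwards.
    """
    weights = peak_weights(gp_exp)
    fitted = list(FITTED_ENZYMES) + ["ManII"]
    box = [tuple(np.log(factor_bounds))] * len(groups)
    box += [model.bounds.get(e, (0.0, 1.1)) for e in fitted]
    base_factors = dict(model.kinetics.factors)

    def fun(x: np.ndarray) -> float:
        factors = dict(base_factors)
        factors.update({g: float(np.exp(v)) for g, v in zip(groups, x)})
        m = model.with_factors(factors)
        compiled = CompiledModel(m)
        totals = dict(zip(fitted, x[len(groups):]))
        try:
            res = simulate_sequential(compiled, totals, tol=sim_tol)
        except SteadyStateError:
            return FAILURE_OBJECTIVE
        return (objective(res.gp, gp_exp, weights)
                + lam * penalty(res.gp_peaks, res.gp_all))

    result = differential_evolution(
        fun, bounds=box, seed=seed, popsize=popsize, maxiter=maxiter,
        tol=1e-10, init="sobol", polish=False, updating="deferred",
    )
    out = {g: float(np.exp(v)) for g, v in zip(groups, result.x)}
    out["_objective"] = float(result.fun)
    for e, v in zip(fitted, result.x[len(groups):]):
        out[f"_total_{e}"] = float(v)
    return out


def calibrate_common(
    cohort: pd.DataFrame,
    model: GolgiModel,
    free_factor_groups: Optional[Sequence[str]] = None,
    factor_bounds: Tuple[float, float] = (0.1, 10.0),
    lam: float = 1.0,
    seed: int = 0,
    popsize: int = 8,
    maxiter: int = 25,
    sim_tol: float = 1e-7,
    max_subjects: Optional[int] = None,
) -> CommonParameters:
    """Two-stage calibration of the common (population-level) parameters.

    Stage 1 fits kf correction factors together with the six enzyme totals
    for each subject, then fixes the factors at their population medians.
    Stage 2 re-fits, per subject, the five non-literature distribution
    coefficients plus the totals, replaces the coefficients with their
    medians (renormalized per enzyme), and fixes the common Man II total at
    the median of the per-subject Man II estimates from stage 1.

    The search runs at a configurable, reduced population size; *cohort*
    needs at least two subjects with columns GP1..GP24 (excl. GP3, GP20).
    """
    from .io import peak_columns

    if len(cohort) < 2:
        raise ValueError("calibration needs a cohort with at least 2 subjects")
    gp_cols = peak_columns(cohort)
    rows = cohort.head(max_subjects) if max_subjects else cohort
    groups = list(free_factor_groups
                  if free_factor_groups is not None
                  else model.kinetics.factors)

    # ----- stage 1: correction factors -----
    stage1 = []
    for i, (_, row) in enumerate(rows.iterrows()):
        gp_exp = row[gp_cols].to_numpy(dtype=float)
        fit = _fit_subject_factors(
            model, gp_exp, groups, factor_bounds, lam,
            seed=seed + 1000 + i, popsize=popsize, maxiter=maxiter,
            sim_tol=sim_tol)
        stage1.append(fit)
    stage1_df = pd.DataFrame(stage1)
    median_factors = {g: float(stage1_df[g].median()) for g in groups}
    model_f = model.with_factors(median_factors)

    # ----- stage 2: distribution coefficients + Man II total -----
    free = STAGE2_FREE_FRACTIONS
    base = model_f.distribution.as_dict()
    stage2 = []
    for i, (_, row) in enumerate(rows.iterrows()):
        gp_exp = row[gp_cols].to_numpy(dtype=float)
        weights = peak_weights(gp_exp)
        box = [(0.0, 1.0)] * len(free) + [model_f.bounds[e] for e in FITTED_ENZYMES]

        def fun(x: np.ndarray) -> float:
            frac = {e: list(v) for e, v in base.items()}
            for (e, k), v in zip(free, x):
                frac[e][k] = float(v)
            from .model import EnzymeDistribution
            from dataclasses import replace as _replace
            try:
                dist = EnzymeDistribution({e: tuple(v) for e, v in frac.items()})
            except ValueError:
                return FAILURE_OBJECTIVE
            m = _replace(model_f, distribution=dist)
            totals = dict(zip(FITTED_ENZYMES, x[len(free):]))
            try:
                res = simulate_sequential(CompiledModel(m), totals, tol=sim_tol)
            except SteadyStateError:
                return FAILURE_OBJECTIVE
            return (objective(res.gp, gp_exp, weights)
                    + lam * penalty(res.gp_peaks, res.gp_all))

        result = differential_evolution(
            fun, bounds=box, seed=seed + 2000 + i, popsize=popsize,
            maxiter=maxiter, tol=1e-10, init="sobol", polish=False,
            updating="deferred")
        rec = {f"{e}_{k}": float(v) for (e, k), v in zip(free, result.x)}
        rec["_objective"] = float(result.fun)
        stage2.append(rec)
    stage2_df = pd.DataFrame(stage2)

    fractions = {e: list(v) for e, v in base.items()}
    for e, k in free:
        fractions[e][k] = float(stage2_df[f"{e}_{k}"].median())
    # renormalize per enzyme so each row sums to one again
    for e in fractions:
        s = sum(fractions[e])
        fractions[e] = tuple(v / s for v in fractions[e])

    manii = float(stage1_df["_total_ManII"].median())

    return CommonParameters(
        factors=median_factors,
        distribution=fractions,
        manii_total=manii,
        per_subject_stage1=stage1_df,
        per_subject_stage2=stage2_df,
    )
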