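"""Practical identifiability of fitted enzyme totals by objective profiling.

One fitted parameter at a time is fixed on a multiplicative grid around its
estimate and removed from optimization; the remaining parameters are re-fit
at every grid point.  The resulting objective profile classifies the
parameter: *identifiable* if the objective rises significantly on both sides
of the optimum, *partially identifiable* if it rises on only one side (e.g.
a parameter pushed against its search bound, or one whose further increase
no longer improves the fit), and *unidentifiable* if it stays flat.

"Significant" is a relative objective increase above a configurable
threshold (default 5%) anywhere on the profiled side; because noise-free
fits can reach near-zero objectives, the relative increase uses a small
absolute floor in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .fitting import FitResult, _PersonalObjective, peak_weights
from .model import FITTED_ENZYMES, GolgiModel
from .simulate import CompiledModel

__all__ = [
    "ProfilePoint",
    "IdentifiabilityLabel",
    "profile_parameter",
    "classify_identifiability",
    "identifiability_report",
]

LABELS = ("identifiable", "partially_identifiable", "unidentifiable")


@dataclass(frozen=True)
class ProfilePoint:
    """One profiled value of a parameter with its re-optimized objective."""

    value: float            # fixed parameter value (uM)
    objective: float        # phi + lambda*psi after refitting the others
    refit_ok: bool = True


@dataclass(frozen=True)
class IdentifiabilityLabel:
    label: str                              # one of LABELS
    flat_direction: Optional[str] = None    # "up" / "down" when partial
    increase_down: float = np.nan           # max relative rise below optimum
    increase_up: float = np.nan             # max relative rise above optimum

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _profile_grid(center: float, bounds: Tuple[float, float],
                  span: float, steps_per_side: int) -> List[float]:
    """Log-spaced multiplicative grid around *center*, clipped at bounds."""
    lo, hi = bounds
    factors = np.exp(np.linspace(np.log(1.0 / span), np.log(span),
                                 2 * steps_per_side + 1))
    eps = 1e-9
    values = np.clip(center * factors, lo + eps, hi)
    return sorted(set(float(v) for v in values))


def profile_parameter(
    fit: FitResult,
    param_id: str,
    gp_exp: np.ndarray,
    model: GolgiModel,
    span: float = 2.0,
    steps_per_side: int = 5,
    lam: float = 1.0,
    sim_tol: float = 1e-8,
    compiled: Optional[CompiledModel] = None,
) -> List[ProfilePoint]:
    """Objective profile of one fitted enzyme total.

    At each grid value the parameter is held fixed and the remaining five
    totals are re-optimized locally, warm-started from the original optimum
    (adequate for profiling around a converged fit).  Refit failures are
    recorded per point, not raised.
    """
    if param_id not in FITTED_ENZYMES:
        raise ValueError(f"unknown fitted parameter {param_id!r}")
    gp_exp = np.asarray(gp_exp, dtype=float)
    compiled = compiled or CompiledModel(model)
    weights = peak_weights(gp_exp)
    fun = _PersonalObjective(compiled, gp_exp, weights, lam, sim_tol)

    idx = FITTED_ENZYMES.index(param_id)
    others = [e for e in FITTED_ENZYMES if e != param_id]
    x_best = np.array([fit.totals[e] for e in FITTED_ENZYMES])
    other_bounds = [model.bounds[e] for e in others]

    points: List[ProfilePoint] = []
    for value in _profile_grid(x_best[idx], model.bounds[param_id],
                               span, steps_per_side):
        def restricted(y: np.ndarray) -> float:
            x = np.empty(len(FITTED_ENZYMES))
            x[idx] = value
            x[[FITTED_ENZYMES.index(e) for e in others]] = y
            return fun(x)

        y0 = np.array([fit.totals[e] for e in others])
        res = minimize(restricted, y0, method="L-BFGS-B", bounds=other_bounds,
                       options={"maxiter": 200, "ftol": 1e-12})
        points.append(ProfilePoint(value=float(value),
                                   objective=float(res.fun),
                                   refit_ok=bool(res.success)))
    return points


def classify_identifiability(
    profile: Sequence[ProfilePoint],
    center: float,
    rel_increase_threshold: float = 0.05,
    objective_floor: float = 1e-4,
) -> IdentifiabilityLabel:
    """Label a parameter from its objective profile.

    The relative increase on each side is (phi* − phi0)/max(phi0, floor)
    where phi0 is the profile minimum; a side whose maximum increase exceeds
    the threshold counts as "rising".  Both sides rising → identifiable;
    exactly one → partially identifiable; neither → unidentifiable.  A
    profile clipped at a search bound is treated as one-sided.
    """
    if len(profile) < 2:
        raise ValueError("profile needs at least 2 points")
    values = np.array([p.value for p in profile])
    objs = np.array([p.objective for p in profile])
    phi0 = objs.min()
    denom = max(phi0, objective_floor)
    rel = (objs - phi0) / denom

    below = values < center * (1 - 1e-9)
    above = values > center * (1 + 1e-9)
    inc_down = float(rel[below].max()) if below.any() else np.nan
    inc_up = float(rel[above].max()) if above.any() else np.nan

    rises_down = bool(below.any() and inc_down >= rel_increase_threshold)
    rises_up = bool(above.any() and inc_up >= rel_increase_threshold)

    if rises_down and rises_up:
        return IdentifiabilityLabel("identifiable",
                                    increase_down=inc_down, increase_up=inc_up)
    if rises_down != rises_up:
        flat = "up" if rises_down else "down"
        return IdentifiabilityLabel("partially_identifiable", flat_direction=flat,
                                    increase_down=inc_down, increase_up=inc_up)
    return IdentifiabilityLabel("unidentifiable",
                                increase_down=inc_down, increase_up=inc_up)


def identifiability_report(
    fit: FitResult,
    gp_exp: np.ndarray,
    model: GolgiModel,
    params: Optional[Sequence[str]] = None,
    span: float = 2.0,
    steps_per_side: int = 5,
    rel_increase_threshold: float = 0.05,
    lam: float = 1.0,
    compiled: Optional[CompiledModel] = None,
) -> Dict[str, dict]:
    """Profile and classify every fitted parameter of one subject's fit."""
    compiled = compiled or CompiledModel(model)
    out: Dict[str, dict] = {}
    for p in (params or FITTED_ENZYMES):
        prof = profile_parameter(fit, p, gp_exp, model, span=span,
                                 steps_per_side=steps_per_side, lam=lam,
                                 compiled=compiled)
        label = classify_identifiability(prof, fit.totals[p],
                                         rel_increase_threshold)
        out[p] = {
            "label": label.label,
            "flat_direction": label.flat_direction,
            "increase_down": label.increase_down,
            "increase_up": label.increase_up,
            "profile": [(pt.value, pt.objective, pt.refit_ok) for pt in prof],
        }
    return out
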