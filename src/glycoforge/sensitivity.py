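"""Global (Sobol) and local sensitivity of glycan peaks to enzyme totals.

The Sobol design uses two independent uniform sample matrices A and B of
size N x k plus the k "swap" matrices AB_j (A with column j replaced from
B).  With model outputs Y_A, Y_B and Y_AB_j the estimators are

    first-order (Saltelli 2010):  S_j  = mean(Y_B * (Y_AB_j − Y_A)) / Var(Y)
    total effect (Jansen):        ST_j = mean((Y_A − Y_AB_j)^2) / (2 Var(Y))

for a cost of (2 + k) N model evaluations.  Inputs are varied uniformly
within +/-50% of their reference (median) totals by default.  Outputs whose
variance is negligible are excluded to avoid numerical instability.

Local relative sensitivity uses the forward finite difference

    SS = (C(a + da) − C(a)) / da * a / C(a),

which equals the local log-log slope (exactly 1 for a linear map).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .model import FITTED_ENZYMES, GolgiModel
from .simulate import CompiledModel, SteadyStateError, simulate_sequential

__all__ = [
    "SobolDesign",
    "sobol_sample",
    "sobol_indices",
    "SensitivityReport",
    "enzyme_sensitivity",
    "local_sensitivity",
    "local_enzyme_sensitivity",
]

VARIANCE_FLOOR = 1e-12


@dataclass
class SobolDesign:
    """Sample matrices for the Saltelli scheme."""

    names: Tuple[str, ...]
    ranges: Dict[str, Tuple[float, float]]
    A: np.ndarray                 # N x k
    B: np.ndarray                 # N x k
    AB: np.ndarray                # k x N x k (column j of A swapped from B)
    seed: Optional[int] = None
    excluded: Tuple[str, ...] = ()

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    @property
    def n_evaluations(self) -> int:
        return (2 + len(self.names)) * self.n_samples


def sobol_sample(
    ranges: Mapping[str, Tuple[float, float]],
    n_samples: int,
    seed: Optional[int] = None,
    sampler: str = "uniform",
) -> SobolDesign:
    """Draw the A/B/AB_j matrices with independent uniform columns.

    ``sampler="uniform"`` (default) draws plain pseudo-random uniforms;
    ``sampler="qmc"`` draws a scrambled low-discrepancy sequence over the
    joint (A, B) space, which shrinks estimator error by roughly an order
    of magnitude at equal N.  Degenerate inputs (lower == upper) are
    excluded from the design with a warning and recorded in
    ``design.excluded``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    import warnings

    active, excluded = [], []
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if hi == lo:
            excluded.append(name)
            warnings.warn(f"input {name!r} has a degenerate range; excluded")
        else:
            active.append(name)
    if not active:
        raise ValueError("no non-degenerate inputs")

    k = len(active)
    lows = np.array([ranges[n][0] for n in active])
    highs = np.array([ranges[n][1] for n in active])
    if sampler == "uniform":
        rng = np.random.default_rng(seed)
        A = rng.uniform(lows, highs, size=(n_samples, k))
        B = rng.uniform(lows, highs, size=(n_samples, k))
    elif sampler == "qmc":
        from scipy.stats import qmc

        eng = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
        with warnings.catch_warnings():
            # balance is immaterial here; any N is allowed
            warnings.filterwarnings("ignore", message=".*balance properties.*")
            u = eng.random(n_samples)  # joint (A, B) space
        A = lows + (highs - lows) * u[:, :k]
        B = lows + (highs - lows) * u[:, k:]
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    AB = np.repeat(A[None, :, :], k, axis=0)
    for j in range(k):
        AB[j, :, j] = B[:, j]
    return SobolDesign(names=tuple(active),
                       ranges={n: tuple(ranges[n]) for n in active},
                       A=A, B=B, AB=AB, seed=seed,
                       excluded=tuple(excluded))


def sobol_indices(
    y_a: np.ndarray, y_b: np.ndarray, y_ab: np.ndarray,
    variance_floor: float = VARIANCE_FLOOR,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order and total-effect indices from evaluated sample matrices.

    Parameters
    ----------
    y_a, y_b:
        Outputs on A and B, shape (N,) or (N, p) for p outputs.
    y_ab:
        Outputs on the swap matrices, shape (k, N) or (k, N, p).

    Returns
    -------
    (S, ST, valid):
        Index arrays of shape (k, p) and a boolean mask of outputs whose
        variance exceeds the floor (indices for excluded outputs are NaN).
    """
    y_a = np.atleast_2d(np.asarray(y_a, dtype=float).T).T  # (N, p)
    y_b = np.atleast_2d(np.asarray(y_b, dtype=float).T).T
    y_ab = np.asarray(y_ab, dtype=float)
    if y_ab.ndim == 2:
        y_ab = y_ab[:, :, None]
    k, n, p = y_ab.shape
    if y_a.shape != (n, p) or y_b.shape != (n, p):
        raise ValueError("inconsistent evaluation shapes")

    y_all = np.concatenate([y_a, y_b], axis=0)
    var = y_all.var(axis=0, ddof=1)
    valid = var > variance_floor

    S = np.full((k, p), np.nan)
    ST = np.full((k, p), np.nan)
    for j in range(k):
        S[j, valid] = (np.mean(y_b[:, valid] * (y_ab[j][:, valid] - y_a[:, valid]),
                               axis=0) / var[valid])
        ST[j, valid] = (0.5 * np.mean((y_a[:, valid] - y_ab[j][:, valid]) ** 2,
                                      axis=0) / var[valid])
    return S, ST, valid


@dataclass
class SensitivityReport:
    """Sobol indices of every peak with respect to every enzyme total."""

    first_order: pd.DataFrame     # peaks x enzymes
    total_effect: pd.DataFrame    # peaks x enzymes
    excluded_outputs: Tuple[str, ...]
    n_samples: int
    seed: Optional[int]
    n_failures: int = 0

    def dominant_enzyme(self, peak: str) -> str:
        """Enzyme with the largest total-effect index for *peak*."""
        return str(self.total_effect.loc[peak].idxmax())

    def to_long(self) -> pd.DataFrame:
        rows = []
        for peak in self.first_order.index:
            for enz in self.first_order.columns:
                rows.append({"peak": peak, "enzyme": enz,
                             "S": self.first_order.loc[peak, enz],
                             "ST": self.total_effect.loc[peak, enz]})
        return pd.DataFrame(rows)


def enzyme_sensitivity(
    model: GolgiModel,
    n_samples: int = 10_000,
    seed: Optional[int] = None,
    rel_range: float = 0.5,
    medians: Optional[Mapping[str, float]] = None,
    sim_tol: float = 1e-8,
    compiled: Optional[CompiledModel] = None,
) -> SensitivityReport:
    """Sobol sensitivity of the 22 peaks to the six fitted enzyme totals.

    Each total varies uniformly within ``+/- rel_range`` (default 50%) of
    its median value.  Failed simulations are excluded sample-wise from the
    estimators (their count is reported).
    """
    compiled = compiled or CompiledModel(model)
    med = {e: (medians or model.totals)[e] for e in FITTED_ENZYMES}
    ranges = {e: ((1 - rel_range) * med[e], (1 + rel_range) * med[e])
              for e in FITTED_ENZYMES}
    design = sobol_sample(ranges, n_samples, seed=seed)

    n_failures = 0

    def evaluate(x: np.ndarray) -> np.ndarray:
        nonlocal n_failures
        totals = dict(zip(design.names, x))
        try:
            return simulate_sequential(compiled, totals, tol=sim_tol).gp
        except SteadyStateError:
            n_failures += 1
            return np.full(model.peaks.n_peaks, np.nan)

    y_a = np.array([evaluate(x) for x in design.A])
    y_b = np.array([evaluate(x) for x in design.B])
    y_ab = np.array([[evaluate(x) for x in design.AB[j]]
                     for j in range(len(design.names))])

    ok = (np.isfinite(y_a).all(axis=1) & np.isfinite(y_b).all(axis=1)
          & np.isfinite(y_ab).all(axis=(0, 2)))
    if not ok.all():
        y_a, y_b, y_ab = y_a[ok], y_b[ok], y_ab[:, ok, :]
    if y_a.shape[0] < 2:
        raise SteadyStateError("too few successful evaluations for Sobol analysis")

    S, ST, valid = sobol_indices(y_a, y_b, y_ab)
    peak_ids = list(model.peaks.peak_ids)
    excluded = tuple(p for p, v in zip(peak_ids, valid) if not v)
    return SensitivityReport(
        first_order=pd.DataFrame(S.T, index=peak_ids, columns=list(design.names)),
        total_effect=pd.DataFrame(ST.T, index=peak_ids, columns=list(design.names)),
        excluded_outputs=excluded,
        n_samples=y_a.shape[0], seed=seed, n_failures=n_failures,
    )


def local_sensitivity(
    func: Callable[[float], float],
    alpha: float,
    delta_rel: float = 0.01,
) -> float:
    """Relative sensitivity coefficient SS of ``func`` at ``alpha``.

    ``SS = (C(a+da) − C(a))/da * a/C(a)`` with ``da = delta_rel * a``.
    Raises for a zero parameter; a zero baseline output is undefined and
    reported as NaN.
    """
    if alpha == 0:
        raise ValueError("local sensitivity requires a nonzero parameter value")
    da = delta_rel * alpha
    c0 = func(alpha)
    if c0 == 0:
        return float("nan")
    c1 = func(alpha + da)
    return (c1 - c0) / da * alpha / c0


def local_enzyme_sensitivity(
    model: GolgiModel,
    delta_rel: float = 0.01,
    totals: Optional[Mapping[str, float]] = None,
    sim_tol: float = 1e-8,
    compiled: Optional[CompiledModel] = None,
) -> pd.DataFrame:
    """Local relative sensitivities of all peaks to each enzyme total.

    Returns a peaks x enzymes DataFrame; peaks with zero baseline are NaN.
    """
    compiled = compiled or CompiledModel(model)
    base_totals = {e: (totals or model.totals)[e] for e in FITTED_ENZYMES}
    base = simulate_sequential(compiled, base_totals, tol=sim_tol).gp
    out = {}
    for e in FITTED_ENZYMES:
        a = base_totals[e]
        pert = dict(base_totals)
        pert[e] = a + delta_rel * a
        gp = simulate_sequential(compiled, pert, tol=sim_tol).gp
        with np.errstate(divide="ignore", invalid="ignore"):
            ss = (gp - base) / (delta_rel * a) * a / base
        ss[base == 0] = np.nan
        out[e] = ss
    return pd.DataFrame(out, index=list(model.peaks.peak_ids))
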