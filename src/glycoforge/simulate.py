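"""Reaction kinetics and sequential steady-state simulation of the Golgi.

Each reaction obeys competitive Michaelis--Menten kinetics: for substrate
concentration C, enzyme concentration U and constants kf, Km,

    v = kf * U * (C / Km) / (1 + sum_l C_l / Km_l),

where the sum runs over the substrates of *all* reactions catalysed by the
same enzyme, including the substrate itself — so with a single substrate the
rate reduces to the textbook kf*U*C/(Km+C).

Within one compartment the species dynamics are

    dC/dt = N @ v(C, U_k) + (C_inflow − C)/tau,

with N the species-by-reactions stoichiometric matrix and tau the residence
time.  Because every reaction converts one glycan into one glycan, the column
sums of N vanish and total glycan concentration at steady state equals the
inflow total in every compartment.

Steady states are found by damped Newton iteration on the algebraic system
(analytic Jacobian), with a long-time stiff integration fallback; the four
compartments are solved sequentially, each receiving the previous steady
state as inflow.  The trans-Golgi-network (compartment IV) steady state
yields the simulated chromatographic peak vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .model import GolgiModel
from .network import PeakTable
from .rules import ENZYMES

__all__ = [
    "reaction_rate",
    "CompiledModel",
    "SimulationResult",
    "SteadyStateError",
    "compartment_rhs",
    "solve_compartment_steady_state",
    "simulate_sequential",
    "simulate_timecourse",
    "compute_peaks",
]

DEFAULT_TOL = 1e-8  # residual infinity-norm, uM/min


class SteadyStateError(RuntimeError):
    """Steady-state solve failed to converge within the iteration budget."""


def reaction_rate(substrate_conc: float, enzyme_conc: float, kf: float,
                  km: float,
                  competitors: Sequence[Tuple[float, float]]) -> float:
    """Competitive Michaelis--Menten rate of one reaction (uM/min).

    Parameters
    ----------
    substrate_conc, enzyme_conc:
        Concentrations C and U (uM).
    kf:
        Effective turnover constant (correction factor included), 1/min.
    km:
        Michaelis constant of this reaction, uM.
    competitors:
        ``(C_l, Km_l)`` pairs for every substrate of every reaction catalysed
        by the same enzyme — the substrate itself included.
    """
    if km <= 0:
        raise ValueError(f"Km must be positive, got {km}")
    if substrate_conc < 0 or enzyme_conc < 0:
        raise ValueError("concentrations must be non-negative")
    denom = 1.0
    for c_l, km_l in competitors:
        if km_l <= 0:
            raise ValueError(f"competitor Km must be positive, got {km_l}")
        denom += c_l / km_l
    return kf * enzyme_conc * (substrate_conc / km) / denom


class CompiledModel:
    """Vectorized view of a :class:`GolgiModel` for fast evaluation.

    Precomputes index arrays and the per-enzyme competition matrix so that
    rate vectors, right-hand sides and Jacobians are single numpy expressions.
    """

    def __init__(self, model: GolgiModel):
        self.model = model
        net = model.network
        self.m = net.n_species
        self.n = net.n_reactions
        self.N = model.stoichiometry.astype(float)
        self.tau = model.tau

        kin = model.kinetics
        self.sub = np.array([r.substrate for r in net.reactions])
        self.prod = np.array([r.product for r in net.reactions])
        enz_index = {e: i for i, e in enumerate(ENZYMES)}
        self.enz = np.array([enz_index[r.enzyme_id] for r in net.reactions])
        self.kf_eff = np.array([
            kin.kf[r.activity] * kin.factors[r.factor_group]
            for r in net.reactions
        ])
        self.km = np.array([kin.km_of_activity(r.activity) for r in net.reactions])
        # competition matrix W[e, s] = 1/Km_e for each unique substrate s of e
        self.W = np.zeros((len(ENZYMES), self.m))
        for r in net.reactions:
            e = enz_index[r.enzyme_id]
            self.W[e, r.substrate] = 1.0 / kin.km_of_activity(r.activity)
        self._eye = np.eye(self.m)

    def compartment_enzymes(self, totals: Optional[Mapping[str, float]] = None
                            ) -> np.ndarray:
        """Enzyme concentrations per compartment (7 x 4, uM)."""
        t = dict(self.model.totals)
        if totals:
            t.update(totals)
        return self.model.distribution.compartment_concentrations(t)

    def rates(self, c: np.ndarray, u7: np.ndarray) -> np.ndarray:
        """Reaction-rate vector v (n,) for state *c* and enzyme vector *u7*."""
        denom = 1.0 + self.W @ c
        return (self.kf_eff * u7[self.enz] * c[self.sub] / self.km
                / denom[self.enz])

    def rhs(self, c: np.ndarray, u7: np.ndarray, inflow: np.ndarray) -> np.ndarray:
        return self.N @ self.rates(c, u7) + (inflow - c) / self.tau

    def jacobian(self, c: np.ndarray, u7: np.ndarray) -> np.ndarray:
        """d(rhs)/dC (m x m), analytic."""
        denom = 1.0 + self.W @ c
        a = self.kf_eff * u7[self.enz] / self.km / denom[self.enz]
        jv = np.zeros((self.n, self.m))
        jv[np.arange(self.n), self.sub] = a
        jv -= (a * c[self.sub] / denom[self.enz])[:, None] * self.W[self.enz, :]
        return self.N @ jv - self._eye / self.tau


def compartment_rhs(model: CompiledModel, state: np.ndarray, u7: np.ndarray,
                    inflow: np.ndarray) -> np.ndarray:
    """Time derivative dC/dt (uM/min) of one compartment."""
    state = np.asarray(state, dtype=float)
    inflow = np.asarray(inflow, dtype=float)
    if state.shape != (model.m,) or inflow.shape != (model.m,):
        raise ValueError(
            f"state/inflow must have length {model.m}, got "
            f"{state.shape} and {inflow.shape}")
    return model.rhs(state, u7, inflow)


def solve_compartment_steady_state(
    model: CompiledModel, inflow: np.ndarray, u7: np.ndarray,
    tol: float = DEFAULT_TOL, max_newton: int = 60,
) -> np.ndarray:
    """Steady state of one compartment: N v(C) + (inflow − C)/tau = 0.

    Damped Newton iteration from the inflow profile with an analytic
    Jacobian; if Newton stalls, a stiff long-time integration re-seeds it.
    Returns a non-negative state with residual infinity-norm below *tol*.
    """
    inflow = np.asarray(inflow, dtype=float)
    if (inflow < 0).any():
        raise ValueError("inflow concentrations must be non-negative")

    def newton(c0: np.ndarray) -> Tuple[np.ndarray, float]:
        # Iterates may swing transiently negative (the algebraic system
        # extends smoothly there); only the converged state must be
        # non-negative.  The line search keeps competition denominators
        # well away from zero.
        c = c0.copy()
        f = model.rhs(c, u7, inflow)
        res = np.abs(f).max()
        for _ in range(max_newton):
            if res < tol:
                break
            J = model.jacobian(c, u7)
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            for _ in range(40):
                c_new = c + lam * step
                if (1.0 + model.W @ c_new).min() > 0.05:
                    f_new = model.rhs(c_new, u7, inflow)
                    res_new = np.abs(f_new).max()
                    if res_new < res:
                        c, f, res = c_new, f_new, res_new
                        break
                lam *= 0.5
            else:
                break  # line search failed
        return c, res

    c, res = newton(inflow)
    if res < tol and c.min() < -1e-9 * max(1.0, inflow.sum()):
        res = np.inf  # converged to an unphysical root; force the fallback
    if res >= tol:
        # fallback: integrate towards the attractor, then polish
        sol = solve_ivp(
            lambda t, y: model.rhs(np.clip(y, 0.0, None), u7, inflow),
            (0.0, 400.0 * model.tau), inflow, method="BDF",
            jac=lambda t, y: model.jacobian(np.clip(y, 0.0, None), u7),
            rtol=1e-10, atol=1e-12,
        )
        c, res = newton(np.clip(sol.y[:, -1], 0.0, None))
        if res >= tol:
            raise SteadyStateError(
                f"steady state not reached: residual {res:.3e} >= tol {tol:.1e}")
    # converged: scrub numerical negatives (at most O(tol*tau) in size)
    return np.clip(c, 0.0, None)


@dataclass
class SimulationResult:
    """Chained steady states of the four compartments plus the peak vector."""

    compartments: np.ndarray        # 4 x m steady states (uM)
    gp: np.ndarray                  # 22 peak percentages
    gp_peaks: float                 # summed concentration of peak members (uM)
    gp_all: float                   # summed concentration of all species (uM)
    peak_ids: Tuple[str, ...]

    @property
    def c4(self) -> np.ndarray:
        return self.compartments[3]

    def gp_series(self):
        import pandas as pd
        return pd.Series(self.gp, index=list(self.peak_ids))


def compute_peaks(c4: np.ndarray, peaks: PeakTable) -> Tuple[np.ndarray, float, float]:
    """Peak percentages from the trans-Golgi-network steady state.

    GP_i = 100 * (summed member concentrations) / (total modelled glycan), so
    the 22 peaks sum to 100 * GP_peaks / GP_all.
    Returns ``(gp, gp_peaks, gp_all)`` with concentrations in uM.
    """
    c4 = np.asarray(c4, dtype=float)
    if (c4 < 0).any():
        raise ValueError("concentrations must be non-negative")
    gp_all = float(c4.sum())
    if gp_all <= 0:
        raise ValueError("all-zero state: peak normalization undefined")
    member_conc = peaks.indicator @ c4
    gp_peaks = float(member_conc.sum())
    return 100.0 * member_conc / gp_all, gp_peaks, gp_all


def simulate_sequential(
    model: CompiledModel,
    totals: Optional[Mapping[str, float]] = None,
    tol: float = DEFAULT_TOL,
) -> SimulationResult:
    """Solve the four compartments in sequence and compute the peak vector.

    *totals* overrides total enzyme concentrations (uM) of the model; the
    initial condition is the model's M5-only inflow.
    """
    u = model.compartment_enzymes(totals)
    inflow = model.model.initial_condition()
    states = np.empty((4, model.m))
    for k in range(4):
        try:
            inflow = solve_compartment_steady_state(model, inflow, u[:, k], tol=tol)
        except SteadyStateError as exc:
            raise SteadyStateError(f"compartment {k + 1}: {exc}") from exc
        states[k] = inflow
    gp, gp_peaks, gp_all = compute_peaks(states[3], model.model.peaks)
    return SimulationResult(
        compartments=states, gp=gp, gp_peaks=gp_peaks, gp_all=gp_all,
        peak_ids=model.model.peaks.peak_ids,
    )


def simulate_timecourse(
    model: CompiledModel,
    totals: Optional[Mapping[str, float]] = None,
    phase_length: float = 100.0,
    n_points: int = 101,
    rtol: float = 1e-9,
    atol: float = 1e-10,
) -> Dict[str, np.ndarray]:
    """Four-phase switching time-course equivalent of the sequential solve.

    The glycan pool spends *phase_length* minutes in each compartment; at
    each switch the enzyme concentrations jump to the next compartment's
    values and the transport inflow is clamped to the end state of the
    previous phase.  Returns times, the state trajectory, the four phase-end
    states and the per-phase inflows.
    """
    u = model.compartment_enzymes(totals)
    inflow = model.model.initial_condition()
    # the glycan pool starts as the M5 bolus already inside compartment I;
    # at each switch the state carries over (the pool matures in place)
    state = inflow.copy()
    times, traj, ends = [], [], []
    for k in range(4):
        u7 = u[:, k]
        t_eval = np.linspace(0.0, phase_length, n_points)
        sol = solve_ivp(
            lambda t, y: model.rhs(y, u7, inflow),
            (0.0, phase_length), state, method="BDF",
            jac=lambda t, y: model.jacobian(y, u7),
            t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SteadyStateError(
                f"stiff integration failed in phase {k + 1}: {sol.message}")
        times.append(sol.t + k * phase_length)
        traj.append(sol.y)
        state = sol.y[:, -1].copy()
        ends.append(state.copy())
        inflow = state.copy()
    return {
        "t": np.concatenate(times),
        "c": np.concatenate(traj, axis=1),
        "phase_ends": np.array(ends),
    }
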