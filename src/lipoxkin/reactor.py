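"""Closed homogeneous isothermal constant-volume batch reactor.

The reactor is perfectly mixed with no inflow or outflow.  Initial molar
concentrations follow from the mechanism's initial mole fractions through the
ideal gas law, c_i = x_i * P0 / (R_u * T); the coupled mass-action ODE system

    dc/dt = S @ q(c),   q_j = k_j(T) * prod over reactants of c^nu

(S the signed stoichiometry matrix) is integrated with a stiff implicit
method.  Temperature is held constant, so rate constants are evaluated once;
pressure is a diagnostic that may drift as total moles change (about 0.2% at
90 degC over 12 h in the bundled mechanism).

Default solver settings (rtol 1e-10, atol 1e-24 mol/cm^3) are tight because
trace radicals sit some ten orders of magnitude below the bulk species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, MechanismError
from .mechanism import Mechanism

#: Universal gas constant in reactor units, cm^3 atm / (mol K).
R_GAS_CM3_ATM = 82.057


def default_sample_times(t_end: float, dt: float = 600.0) -> np.ndarray:
    """Regular grid every ``dt`` seconds plus the 4 h and 12 h marks (if inside)."""
    grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    grid = grid[grid <= t_end]
    extra = [t for t in (14_400.0, 43_200.0, t_end) if 0.0 < t <= t_end]
    return np.unique(np.concatenate([grid, np.asarray(extra)]))


@dataclass(frozen=True)
class ReactorConditions:
    """Operating point of the isothermal batch reactor.

    Parameters
    ----------
    T : float
        Temperature, K.
    P0 : float
        Initial pressure, atm.
    V : float
        Reactor volume, cm^3 (bookkeeping only; concentrations are intensive).
    t_end : float
        Duration, s.
    sample_times : sequence of float, optional
        Strictly increasing output times within [0, t_end]; defaults to a
        600 s grid plus the 4 h / 12 h marks.
    """

    T: float
    P0: float = 1.0
    V: float = 100.0
    t_end: float = 43_200.0
    sample_times: tuple[float, ...] | None = None

    def __post_init__(self):
        if not (self.T > 0 and self.P0 > 0 and self.V > 0):
            raise ValueError("T, P0 and V must be positive")
        if self.t_end < 0:
            raise ValueError("t_end must be nonnegative")
        if self.sample_times is not None:
            ts = tuple(float(t) for t in self.sample_times)
            if any(t < 0 or t > self.t_end for t in ts):
                raise ValueError("sample times must lie in [0, t_end]")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("sample times must be strictly increasing")
            object.__setattr__(self, "sample_times", ts)

    @classmethod
    def from_celsius(cls, T_celsius: float, **kwargs) -> "ReactorConditions":
        return cls(T=T_celsius + 273.15, **kwargs)

    def resolved_sample_times(self) -> np.ndarray:
        if self.t_end == 0:
            return np.array([0.0])
        if self.sample_times is None:
            return default_sample_times(self.t_end)
        ts = np.asarray(self.sample_times, dtype=float)
        if ts.size == 0 or ts[0] != 0.0:
            ts = np.concatenate([[0.0], ts])
        return ts


@dataclass
class Trajectory:
    """Simulated time series: concentrations, mole fractions, rates of progress.

    ``concentrations`` is (n_times, n_species) in mol/cm^3; ``mole_fractions``
    is concentrations normalized by the instantaneous total at each sample;
    ``rates_of_progress`` is (n_times, n_reactions) in mol/(cm^3 s).
    """

    mechanism: Mechanism
    conditions: ReactorConditions
    times: np.ndarray
    concentrations: np.ndarray
    mole_fractions: np.ndarray = field(init=False)
    rates_of_progress: np.ndarray = field(init=False)

    def __post_init__(self):
        totals = self.concentrations.sum(axis=1, keepdims=True)
        self.mole_fractions = self.concentrations / totals
        k = self.mechanism.rate_constants(self.conditions.T)
        self.rates_of_progress = np.stack(
            [
                _rates_of_progress(self.mechanism, k, c)
                for c in np.clip(self.concentrations, 0.0, None)
            ]
        )

    # -- accessors -------------------------------------------------------

    def species_fraction(self, name: str, t: float | None = None):
        """Mole-fraction series of ``name``; a scalar at sample time ``t``."""
        col = self.mole_fractions[:, self.mechanism.species_index(name)]
        if t is None:
            return col
        return float(np.interp(t, self.times, col))

    def pressure(self) -> np.ndarray:
        """Diagnostic pressure series, atm (ideal gas at constant T, V)."""
        return self.concentrations.sum(axis=1) * R_GAS_CM3_ATM * self.conditions.T

    def to_frame(self):
        """Wide pandas DataFrame: time, mole fractions, concentrations, rates."""
        import pandas as pd

        names = self.mechanism.species_names
        data = {"time_s": self.times}
        for i, n in enumerate(names):
            data[f"x_{n}"] = self.mole_fractions[:, i]
        for i, n in enumerate(names):
            data[f"c_{n}"] = self.concentrations[:, i]
        for j, rx in enumerate(self.mechanism.reactions):
            data[f"q_{j + 1}"] = self.rates_of_progress[:, j]
        return pd.DataFrame(data)

    def write(self, path, sidecar_path=None) -> None:
        """Write the trajectory as TSV plus a YAML metadata sidecar."""
        import yaml

        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10e")
        if sidecar_path is not None:
            meta = {
                "mechanism_hash": self.mechanism.content_hash(),
                "conditions": {
                    "T_K": self.conditions.T,
                    "P0_atm": self.conditions.P0,
                    "V_cm3": self.conditions.V,
                    "t_end_s": self.conditions.t_end,
                },
                "n_samples": int(self.times.size),
            }
            with open(sidecar_path, "w") as fh:
                yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Right-hand side


def initial_state(mech: Mechanism, cond: ReactorConditions) -> np.ndarray:
    """Initial concentrations, mol/cm^3, from mole fractions via the ideal gas law."""
    try:
        mech.validate_initial_composition()
    except MechanismError as exc:
        raise MechanismError(f"cannot build initial state: {exc}") from exc
    c_total = cond.P0 / (R_GAS_CM3_ATM * cond.T)
    return mech.initial_mole_fractions * c_total


def _reactant_indices(mech: Mechanism) -> list[list[int]]:
    idx = {n: i for i, n in enumerate(mech.species_names)}
    out = []
    for rx in mech.reactions:
        ids: list[int] = []
        for name, nu in rx.reactants.items():
            ids.extend([idx[name]] * nu)
        out.append(ids)
    return out


def _rates_of_progress(mech: Mechanism, k: np.ndarray, c: np.ndarray) -> np.ndarray:
    q = np.empty(len(mech.reactions))
    for j, ids in enumerate(_reactant_indices(mech)):
        q[j] = k[j] * np.prod(c[ids])
    return q


def species_rates(mech: Mechanism, concentrations: np.ndarray, T: float) -> np.ndarray:
    """dc/dt in mol/(cm^3 s) from mass-action kinetics at temperature ``T``."""
    k = mech.rate_constants(T)
    q = _rates_of_progress(mech, k, np.asarray(concentrations, dtype=float))
    return mech.stoich_matrix @ q


# ---------------------------------------------------------------------------
# Integration


def simulate(
    mech: Mechanism,
    cond: ReactorConditions,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-24,
    method: str = "BDF",
    negative_floor: float | None = None,
) -> Trajectory:
    """Integrate the batch-reactor ODE system and sample at the output grid.

    Raises :class:`IntegrationError` when the stiff solver fails or when any
    concentration undershoots below ``-negative_floor`` (default: the larger
    of ``atol`` and 1e-12 times the total concentration).
    """
    c0 = initial_state(mech, cond)
    t_eval = cond.resolved_sample_times()
    if cond.t_end == 0:
        conc = c0[None, :].copy()
        return Trajectory(mech, cond, np.array([0.0]), conc)

    S = mech.stoich_matrix.astype(float)
    k = mech.rate_constants(cond.T)
    reac_ids = _reactant_indices(mech)
    n_rx = len(mech.reactions)

    def rhs(t, c):
        cp = np.clip(c, 0.0, None)
        q = np.empty(n_rx)
        for j, ids in enumerate(reac_ids):
            q[j] = k[j] * np.prod(cp[ids])
        return S @ q

    def jac(t, c):
        cp = np.clip(c, 0.0, None)
        dq = np.zeros((n_rx, c.size))
        for j, ids in enumerate(reac_ids):
            for pos, i in enumerate(ids):
                others = ids[:pos] + ids[pos + 1 :]
                dq[j, i] += k[j] * np.prod(cp[others])
        return S @ dq

    try:
        sol = solve_ivp(
            rhs,
            (0.0, cond.t_end),
            c0,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            jac=jac,
        )
    except (ValueError, OverflowError) as exc:
        # solve_ivp surfaces non-finite states as ValueError mid-integration
        raise IntegrationError(f"stiff integration failed: {exc}") from exc
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"stiff integration failed: {sol.message}", t_fail)

    conc = sol.y.T
    floor = negative_floor if negative_floor is not None else max(atol, 1e-12 * c0.sum())
    worst = conc.min()
    if worst < -floor:
        i_t, _ = np.unravel_index(np.argmin(conc), conc.shape)
        raise IntegrationError(
            f"negative concentration {worst:.3e} beyond tolerance {floor:.3e}",
            float(sol.t[i_t]),
        )
    return Trajectory(mech, cond, sol.t.copy(), np.clip(conc, 0.0, None))


def rate_of_progress_ranking(traj: Trajectory) -> list[tuple[int, str, float]]:
    """Reactions ordered by time-averaged rate of progress, fastest first.

    Returns (reaction index, label or equation, time-averaged q_j) triples;
    the average is trapezoidal over the sample grid (plain mean for a
    single-sample trajectory).
    """
    q = traj.rates_of_progress
    if traj.times.size > 1:
        avg = np.trapezoid(q, traj.times, axis=0) / (traj.times[-1] - traj.times[0])
    else:
        avg = q.mean(axis=0)
    order = np.argsort(avg)[::-1]
    return [
        (int(j), traj.mechanism.reactions[j].label or traj.mechanism.reactions[j].equation,
         float(avg[j]))
        for j in order
    ]


def simulate_celsius_set(
    mech: Mechanism,
    temps_celsius: Sequence[float],
    *,
    t_end: float = 43_200.0,
    sample_times: Sequence[float] | None = None,
    **solver_opts,
) -> dict[float, Trajectory]:
    """Run one simulation per Celsius temperature; keys are the Celsius values."""
    out = {}
    for tc in temps_celsius:
        cond = ReactorConditions.from_celsius(
            tc, t_end=t_end,
            sample_times=tuple(sample_times) if sample_times is not None else None,
        )
        out[float(tc)] = simulate(mech, cond, **solver_opts)
    return out
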