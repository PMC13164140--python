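"""Synthetic replicate generation, parameter perturbation and calibration.

The generator emulates the study design behind the experimental fixtures:
three temperatures (50/70/90 degC), two sampling times (4 h, 12 h), three
replicates per condition, with the published means and standard deviations as
the default truth.  Noise is independent Gaussian per replicate, truncated at
zero (marker values are nonnegative by construction); every draw is governed
by an explicit seed.

Calibration is SD-weighted least squares on the marker summaries: the
objective re-runs the batch reactor at every trial point, so it is exactly
the forward model being fitted.  Over the narrow 323-363 K span, A and Ea of
the same reaction are nearly collinear (d ln k spans only ~1/323 - 1/363 in
1/T), so joint (A, Ea) fits report their correlation rather than pretending
both are identified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import analysis
from .errors import LipoxkinError
from .mechanism import ArrheniusParams, Mechanism
from .reactor import IntegrationError, ReactorConditions, simulate
from .validation import (
    MeasurementRecord,
    MeasurementSet,
    experimental_fixtures,
)

_H = 3600.0
_DEFAULT_CONDITIONS = tuple(
    (tc + 273.15, th * _H) for th in (4, 12) for tc in (50, 70, 90)
)


@dataclass(frozen=True)
class SyntheticDesign:
    """Truth means/SDs per marker and condition, replicate count, seed.

    ``truth`` and ``sd`` map marker -> {(T, t): value}; the defaults are the
    published experimental tables.
    """

    truth: Mapping[str, Mapping[tuple[float, float], float]] | None = None
    sd: Mapping[str, Mapping[tuple[float, float], float]] | None = None
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.truth is None or self.sd is None:
            fx = experimental_fixtures()
            truth = self.truth or {
                m: {(r.T, r.t): r.mean for r in s.records} for m, s in fx.items()
            }
            sd = self.sd or {
                m: {(r.T, r.t): r.sd for r in s.records} for m, s in fx.items()
            }
            object.__setattr__(self, "truth", truth)
            object.__setattr__(self, "sd", sd)
        for marker, conds in self.sd.items():
            if any(v < 0 for v in conds.values()):
                raise ValueError(f"negative sd in marker {marker}")


def generate_measurements(design: SyntheticDesign) -> dict[str, MeasurementSet]:
    """Draw replicate sets per marker/condition; deterministic given the seed.

    Each replicate is Normal(mean, sd) truncated below at zero (redrawn while
    negative); records carry the replicate values plus their recomputed
    mean and sample SD.
    """
    rng = np.random.default_rng(design.seed)
    out: dict[str, MeasurementSet] = {}
    for marker in sorted(design.truth):
        records = []
        for (T, t) in sorted(design.truth[marker]):
            mean = design.truth[marker][(T, t)]
            sd = design.sd[marker].get((T, t), 0.0)
            reps = []
            for _ in range(design.n_replicates):
                draw = rng.normal(mean, sd) if sd > 0 else mean
                while draw < 0:
                    draw = rng.normal(mean, sd)
                reps.append(float(draw))
            reps_arr = np.asarray(reps)
            records.append(
                MeasurementRecord(
                    T=T,
                    t=t,
                    mean=float(reps_arr.mean()),
                    sd=float(reps_arr.std(ddof=1)) if len(reps) > 1 else 0.0,
                    n_replicates=design.n_replicates,
                    replicates=tuple(reps),
                )
            )
        out[marker] = MeasurementSet(marker, tuple(records))
    return out


# ---------------------------------------------------------------------------
# Parameter perturbation


@dataclass(frozen=True)
class PerturbationRecord:
    reaction_index: int
    parameter: str          # "log10_A" or "Ea"
    old_value: float
    new_value: float


def perturb_parameters(
    mech: Mechanism,
    spec: Sequence[tuple[int, str, float]] | None = None,
    *,
    random_log10_A_jitter: float = 0.0,
    seed: int = 0,
) -> tuple[Mechanism, list[PerturbationRecord]]:
    """Return a modified mechanism copy plus the perturbation record.

    ``spec`` lists deterministic shifts (reaction index, "log10_A" | "Ea",
    additive delta).  ``random_log10_A_jitter`` additionally applies a
    uniform(+/- jitter) shift in log10 A to every reaction, seed-governed.
    The input mechanism is never modified.
    """
    records: list[PerturbationRecord] = []
    new = Mechanism(species=list(mech.species), reactions=list(mech.reactions))
    for j, param, delta in spec or []:
        kin = new.reactions[j].kinetics
        if param == "log10_A":
            old = math.log10(kin.A)
            kin2 = replace(kin, A=10.0 ** (old + delta))
            records.append(PerturbationRecord(j, param, old, old + delta))
        elif param == "Ea":
            old = kin.Ea
            if old + delta < 0:
                raise LipoxkinError(
                    f"perturbation drives Ea of reaction {j} negative"
                )
            kin2 = replace(kin, Ea=old + delta)
            records.append(PerturbationRecord(j, param, old, old + delta))
        else:
            raise ValueError(f"unknown parameter {param!r}")
        new = new.replace_kinetics(j, kin2)
    if random_log10_A_jitter:
        rng = np.random.default_rng(seed)
        for j, rx in enumerate(new.reactions):
            old = math.log10(rx.kinetics.A)
            shift = rng.uniform(-random_log10_A_jitter, random_log10_A_jitter)
            new = new.replace_kinetics(j, replace(rx.kinetics, A=10.0 ** (old + shift)))
            records.append(PerturbationRecord(j, "log10_A", old, old + shift))
    return new, records


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class CalibrationSpec:
    """What to fit: free parameters with bounds, objective markers/conditions.

    ``free_parameters`` is a list of (reaction index, "log10_A" | "Ea");
    ``bounds`` pairs (lower, upper) per free parameter.  The objective pools
    the listed markers over the listed (T, t) conditions, weighting each
    residual by the measurement SD (floored at ``sd_floor``).
    """

    free_parameters: tuple[tuple[int, str], ...]
    bounds: tuple[tuple[float, float], ...]
    markers: tuple[str, ...] = ("linoleic_loss_pct", "lycopene_loss_pct")
    conditions: tuple[tuple[float, float], ...] = _DEFAULT_CONDITIONS
    sd_floor: float = 1e-6
    max_iterations: int = 100
    tolerance: float = 1e-10
    multistart: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.free_parameters:
            raise ValueError("need at least one free parameter")
        if len(self.bounds) != len(self.free_parameters):
            raise ValueError("one (lower, upper) bound pair per free parameter")
        for lo, hi in self.bounds:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds ({lo}, {hi})")


@dataclass
class CalibrationResult:
    parameters: dict[tuple[int, str], float]
    objective: float
    converged: bool
    n_evaluations: int
    trace: list[tuple[float, ...]] = field(default_factory=list)  # (params..., objective)
    mechanism: Mechanism | None = None
    parameter_correlation: np.ndarray | None = None
    message: str = ""


def _apply_parameters(mech: Mechanism, spec: CalibrationSpec, theta) -> Mechanism:
    new = mech
    for (j, param), value in zip(spec.free_parameters, theta):
        kin = new.reactions[j].kinetics
        if param == "log10_A":
            kin = replace(kin, A=10.0 ** value)
        elif param == "Ea":
            kin = replace(kin, Ea=float(value))
        else:
            raise ValueError(f"unknown parameter {param!r}")
        new = new.replace_kinetics(j, kin)
    return new


def _marker_value(traj, marker: str, t: float) -> float:
    if marker == "linoleic_loss_pct":
        return analysis.loss_percent(traj, "LINOLEIC", t)
    if marker == "lycopene_loss_pct":
        return analysis.loss_percent(traj, "LYCOPENE", t)
    raise ValueError(f"marker {marker!r} not supported in calibration objective")


def calibrate(
    mech: Mechanism,
    spec: CalibrationSpec,
    data: Mapping[str, MeasurementSet],
    *,
    x0: Sequence[float] | None = None,
    solver_opts: Mapping | None = None,
) -> CalibrationResult:
    """Fit the free Arrhenius parameters to marker data by bounded least squares.

    Each objective evaluation integrates the reactor at every distinct
    temperature in ``spec.conditions`` and compares the requested markers with
    the measurement means, weighted by 1/max(sd, sd_floor).  A trial point
    where the ODE fails contributes a large penalty residual instead of
    raising.  Non-convergence is reported through ``converged``/``message``,
    never as an exception.
    """
    solver_opts = dict(solver_opts or {})
    solver_opts.setdefault("rtol", 1e-8)
    solver_opts.setdefault("atol", 1e-22)
    temps = sorted({T for T, _ in spec.conditions})
    t_max = max(t for _, t in spec.conditions)
    sample_ts = tuple(sorted({t for _, t in spec.conditions}))

    targets = []  # (marker, T, t, mean, weight)
    for marker in spec.markers:
        mset = data[marker]
        for (T, t) in spec.conditions:
            rec = mset.lookup(T, t)
            targets.append(
                (marker, T, t, rec.mean, 1.0 / max(rec.sd, spec.sd_floor))
            )

    n_eval = 0
    trace: list[tuple[float, ...]] = []

    def residuals(theta):
        nonlocal n_eval
        n_eval += 1
        trial = _apply_parameters(mech, spec, theta)
        trajs = {}
        penalty = None
        for T in temps:
            cond = ReactorConditions(
                T=T, t_end=t_max, sample_times=sample_ts
            )
            try:
                trajs[T] = simulate(trial, cond, **solver_opts)
            except IntegrationError:
                penalty = 1e6
                break
        if penalty is not None:
            res = np.full(len(targets), penalty)
        else:
            res = np.array(
                [
                    (_marker_value(trajs[T], marker, t) - mean) * w
                    for marker, T, t, mean, w in targets
                ]
            )
        trace.append((*[float(v) for v in theta], float(np.sum(res**2))))
        return res

    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    else:
        starts.append(
            np.array(
                [
                    math.log10(mech.reactions[j].kinetics.A)
                    if param == "log10_A"
                    else mech.reactions[j].kinetics.Ea
                    for j, param in spec.free_parameters
                ]
            )
        )
    if spec.multistart > 1:
        rng = np.random.default_rng(spec.seed)
        starts += [rng.uniform(lo, hi) for _ in range(spec.multistart - 1)]

    best = None
    message = ""
    for start in starts:
        start = np.clip(start, lo, hi)
        fit = least_squares(
            residuals,
            start,
            bounds=(lo, hi),
            method="trf",
            xtol=spec.tolerance,
            ftol=spec.tolerance,
            gtol=spec.tolerance,
            max_nfev=spec.max_iterations * (len(start) + 1) * 4,
            diff_step=1e-6,
        )
        if best is None or fit.cost < best.cost:
            best = fit
            message = fit.message

    corr = None
    if len(spec.free_parameters) > 1 and best.jac is not None:
        JtJ = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(JtJ)
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
        except np.linalg.LinAlgError:
            corr = None

    params = dict(zip(spec.free_parameters, (float(v) for v in best.x)))
    return CalibrationResult(
        parameters=params,
        objective=float(2.0 * best.cost),  # least_squares cost = 0.5 * sum(res^2)
        converged=bool(best.status > 0),
        n_evaluations=n_eval,
        trace=trace,
        mechanism=_apply_parameters(mech, spec, best.x),
        parameter_correlation=corr,
        message=message,
    )


def markers_from_mechanism(
    mech: Mechanism,
    conditions: Sequence[tuple[float, float]] = _DEFAULT_CONDITIONS,
    markers: Sequence[str] = ("linoleic_loss_pct", "lycopene_loss_pct"),
    **solver_opts,
) -> dict[str, dict[tuple[float, float], float]]:
    """Forward-simulate marker truth values per condition (for known-truth studies)."""
    temps = sorted({T for T, _ in conditions})
    t_max = max(t for _, t in conditions)
    sample_ts = tuple(sorted({t for _, t in conditions}))
    trajs = {
        T: simulate(
            mech, ReactorConditions(T=T, t_end=t_max, sample_times=sample_ts),
            **solver_opts,
        )
        for T in temps
    }
    return {
        marker: {
            (T, t): _marker_value(trajs[T], marker, t) for (T, t) in conditions
        }
        for marker in markers
    }
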