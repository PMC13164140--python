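"""Model-vs-experiment validation statistics.

Experimental marker tables for thermally treated tomato pomace (triplicate
mean +/- SD of linoleic-acid loss %, lycopene loss % and normalized hexanal at
50/70/90 degC after 4 h and 12 h) ship as fixtures; simulated summaries are
paired with them and scored with R^2, RMSE and mean percentage error.

Two R^2 conventions are reported because they genuinely differ on model-vs-
data pairings: the squared Pearson correlation (always in [0, 1]) and the
coefficient of determination 1 - SS_res/SS_tot (negative when the model does
worse than the experimental mean).  MPE is reported both as the mean absolute
percentage deviation relative to the experimental value and as the signed
mean (negative = model under-predicts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .analysis import OxidationSummary
from .errors import ValidationError

MARKERS = ("linoleic_loss_pct", "lycopene_loss_pct", "hexanal_normalized")


@dataclass(frozen=True)
class MeasurementRecord:
    """One experimental condition: temperature (K), time (s), mean +/- sd, n."""

    T: float
    t: float
    mean: float
    sd: float
    n_replicates: int = 3
    replicates: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("standard deviation must be nonnegative")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")


@dataclass(frozen=True)
class MeasurementSet:
    """All experimental records for one marker."""

    marker: str
    records: tuple[MeasurementRecord, ...]

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}")
        keys = [(r.T, r.t) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValidationError(f"duplicate (T, t) condition in {self.marker} records")

    def lookup(self, T: float, t: float) -> MeasurementRecord:
        for r in self.records:
            if abs(r.T - T) < 1e-6 and abs(r.t - t) < 1e-6:
                return r
        raise ValidationError(f"no {self.marker} record at T={T} K, t={t} s")


_H = 3600.0


def _records(rows: Iterable[tuple[float, float, float, float]]):
    return tuple(
        MeasurementRecord(T=tc + 273.15, t=th * _H, mean=m, sd=s, n_replicates=3)
        for tc, th, m, s in rows
    )


def experimental_fixtures() -> dict[str, MeasurementSet]:
    """Published triplicate means +/- SD per marker, 3 temperatures x 2 times.

    Normalized hexanal is a ratio of peak areas (each time point scaled by its
    90 degC value); no replicate SD accompanies those ratios, so their records
    carry sd = 0.
    """
    linoleic = _records([
        (50, 4, 0.32, 0.04), (70, 4, 0.92, 0.10), (90, 4, 7.59, 0.91),
        (50, 12, 0.28, 0.07), (70, 12, 2.96, 0.37), (90, 12, 20.46, 4.15),
    ])
    lycopene = _records([
        (50, 4, 0.05, 0.01), (70, 4, 0.28, 0.04), (90, 4, 1.85, 0.15),
        (50, 12, 0.12, 0.02), (70, 12, 0.85, 0.08), (90, 12, 5.10, 0.35),
    ])
    hexanal = _records([
        (50, 4, 0.0021, 0.0), (70, 4, 0.741, 0.0), (90, 4, 1.0, 0.0),
        (50, 12, 0.0031, 0.0), (70, 12, 0.725, 0.0), (90, 12, 1.0, 0.0),
    ])
    return {
        "linoleic_loss_pct": MeasurementSet("linoleic_loss_pct", linoleic),
        "lycopene_loss_pct": MeasurementSet("lycopene_loss_pct", lycopene),
        "hexanal_normalized": MeasurementSet("hexanal_normalized", hexanal),
    }


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class MetricResult:
    r_squared_pearson: float       # squared Pearson correlation, in [0, 1]
    r_squared_ss: float            # 1 - SS_res / SS_tot (can be negative)
    rmse: float
    mpe_abs_pct: float             # mean |sim-exp|/exp * 100
    mpe_signed_pct: float          # mean (sim-exp)/exp * 100
    n: int


def validation_metrics(sim: Sequence[float], exp: Sequence[float]) -> MetricResult:
    """Score simulated against experimental values.

    RMSE = sqrt(mean((sim-exp)^2)); pairings with exp == 0 are excluded from
    the percentage errors with a warning.  Requires at least two pairs.
    """
    s = np.asarray(sim, dtype=float)
    e = np.asarray(exp, dtype=float)
    if s.shape != e.shape:
        raise ValidationError(f"length mismatch: {s.shape} vs {e.shape}")
    if s.size < 2:
        raise ValidationError("need at least two paired values")

    resid = s - e
    rmse = float(np.sqrt(np.mean(resid**2)))

    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    if ss_res == 0.0:
        r2_ss = 1.0
        r2_pearson = 1.0
    else:
        r2_ss = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
        sd_s, sd_e = s.std(), e.std()
        if sd_s == 0 or sd_e == 0:
            r2_pearson = 0.0
        else:
            r2_pearson = float(np.corrcoef(s, e)[0, 1] ** 2)

    nz = e != 0
    if not np.all(nz):
        warnings.warn(
            "zero experimental value(s) excluded from percentage error",
            stacklevel=2,
        )
    if np.any(nz):
        pe = (s[nz] - e[nz]) / e[nz] * 100.0
        mpe_abs = float(np.mean(np.abs(pe)))
        mpe_signed = float(np.mean(pe))
    else:
        mpe_abs = mpe_signed = float("nan")
    return MetricResult(r2_pearson, r2_ss, rmse, mpe_abs, mpe_signed, int(s.size))


# ---------------------------------------------------------------------------
# Report


@dataclass(frozen=True)
class PairedPoint:
    T: float
    t: float
    simulated: float
    experimental_mean: float
    experimental_sd: float
    flagged: bool  # |sim - mean| > 2 sd (only evaluated when sd > 0)


@dataclass
class ValidationReport:
    """Per-marker paired points and metrics for one simulation run."""

    pairs: dict[str, list[PairedPoint]] = field(default_factory=dict)
    metrics: dict[str, MetricResult] = field(default_factory=dict)

    #: Published whole-study statistics, for side-by-side display only; the
    #: convention behind them is not documented, so they are never asserted.
    published_reference: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "linoleic_loss_pct": {"r_squared": 0.9761, "rmse": 0.5784, "mpe_pct": 23.52},
            "lycopene_loss_pct": {"r_squared": 0.9899, "rmse": 0.2205, "mpe_pct": 14.28},
            "hexanal_normalized": {"r_squared": 0.9982, "rmse": 0.0179, "mpe_pct": 10.03},
        }
    )

    def to_text(self) -> str:
        lines = []
        for marker in self.metrics:
            m = self.metrics[marker]
            lines.append(f"marker: {marker}  (n={m.n})")
            lines.append(
                f"  recomputed: R2(pearson)={m.r_squared_pearson:.6g} "
                f"R2(1-SSres/SStot)={m.r_squared_ss:.6g} RMSE={m.rmse:.6g} "
                f"MPE={m.mpe_abs_pct:.6g}% signed={m.mpe_signed_pct:.6g}%"
            )
            ref = self.published_reference.get(marker)
            if ref:
                lines.append(
                    f"  published : R2={ref['r_squared']:.4f} RMSE={ref['rmse']:.4f} "
                    f"MPE={ref['mpe_pct']:.2f}%  "
                    f"(|dR2|={abs(m.r_squared_pearson - ref['r_squared']):.4f}, "
                    f"|dRMSE|={abs(m.rmse - ref['rmse']):.4f}, "
                    f"|dMPE|={abs(m.mpe_abs_pct - ref['mpe_pct']):.2f}; convention "
                    "of the published statistics is undocumented — no agreement "
                    "is asserted)"
                )
            for p in self.pairs[marker]:
                flag = "  ** outside 2 SD" if p.flagged else ""
                lines.append(
                    f"    T={p.T - 273.15:.0f}C t={p.t / 3600:.0f}h "
                    f"sim={p.simulated:.6g} exp={p.experimental_mean:.6g}"
                    f"±{p.experimental_sd:.6g}{flag}"
                )
        return "\n".join(lines) + "\n"


def validation_report(
    summaries: Sequence[OxidationSummary],
    fixtures: Mapping[str, MeasurementSet],
    normalized_hexanal: Mapping[tuple[float, float], float] | None = None,
) -> ValidationReport:
    """Pair simulated summaries with experimental fixtures and score each marker.

    ``summaries`` must cover every fixture condition.  Normalized hexanal is a
    cross-condition quantity (each time point is scaled by its hottest value),
    so it cannot be derived from one summary alone; pass it precomputed as a
    ``{(T, t): value}`` map, or leave it None to score only the loss markers.
    """
    report = ValidationReport()
    for marker, mset in fixtures.items():
        pairs: list[PairedPoint] = []
        for rec in mset.records:
            if marker == "hexanal_normalized":
                if normalized_hexanal is None:
                    break
                key = min(
                    normalized_hexanal,
                    key=lambda k: abs(k[0] - rec.T) + abs(k[1] - rec.t),
                )
                if abs(key[0] - rec.T) > 1e-6 or abs(key[1] - rec.t) > 1e-6:
                    raise ValidationError(
                        f"no simulated normalized hexanal at T={rec.T}, t={rec.t}"
                    )
                sim_val = float(normalized_hexanal[key])
            else:
                match = [
                    s for s in summaries
                    if abs(s.T - rec.T) < 1e-6 and abs(s.t - rec.t) < 1e-6
                ]
                if not match:
                    raise ValidationError(
                        f"no simulated summary for {marker} at T={rec.T} K, t={rec.t} s"
                    )
                sim_val = float(getattr(match[0], marker))
            flagged = rec.sd > 0 and abs(sim_val - rec.mean) > 2 * rec.sd
            pairs.append(
                PairedPoint(rec.T, rec.t, sim_val, rec.mean, rec.sd, flagged)
            )
        if not pairs:
            continue
        report.pairs[marker] = pairs
        report.metrics[marker] = validation_metrics(
            [p.simulated for p in pairs], [p.experimental_mean for p in pairs]
        )
    return report
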