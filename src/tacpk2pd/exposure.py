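"""Exposure and calcineurin-activity metrics, and correlation analysis.

Noncompartmental-style quantities over one 12 h dosing interval: trough
(C0, the predose sample), peak (Cmax) and its time (Tmax), AUC0-12 by the
linear trapezoidal rule (on raw samples, or on a model-predicted dense
profile when one is supplied), apparent clearance CL/F = dose / AUC_WB,
and the blood-to-cell partitioning ("intracellular diffusion") ratio.

The diffusion ratio is reported as an intracellular-to-blood
*concentration* ratio: intracellular amounts per million cells are
converted to a concentration using a PBMC volume of 0.2 uL per million
cells (~200 fL per lymphocyte), i.e.

    ratio = (AUC_PBMC [pg.h/10^6 cells] / 0.2 [uL/10^6 cells]) / AUC_WB [ng.h/mL]

since 1 pg/uL = 1 ng/mL.  Without the volume conversion the raw
mixed-unit quotient is ~4.9x smaller than the conventional ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model_io import Subject
from .pk_model import SimulatedProfile

__all__ = [
    "PBMC_UL_PER_MILLION",
    "ExposureMetrics",
    "PDMetrics",
    "CorrelationResult",
    "trapezoid",
    "nca_metrics",
    "pd_metrics",
    "correlate",
    "diffusion_ratio",
]

#: intracellular volume used to convert pg per million cells to ng/mL
PBMC_UL_PER_MILLION = 0.2


@dataclass(frozen=True)
class ExposureMetrics:
    dose: float | None
    # whole blood (ng/mL, ng.h/mL)
    c0_wb: float | None
    cmax_wb: float | None
    tmax_wb: float | None
    auc_wb: float | None
    # PBMC (pg per million cells)
    c0_pbmc: float | None
    cmax_pbmc: float | None
    tmax_pbmc: float | None
    auc_pbmc: float | None
    cl_f: float | None  # L/h
    diffusion_ratio: float | None

    def dose_normalized(self, value: float | None) -> float | None:
        if value is None or self.dose is None:
            return None
        return value / self.dose


@dataclass(frozen=True)
class PDMetrics:
    aua: float  # pmol.h/min per million PBMC
    can_basal: float
    can_min: float
    can_moy: float
    max_inhibition_pct: float  # negative = inhibited below basal
    t_min: float


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    r2: float
    p: float
    n: int
    slope: float | None = None
    intercept: float | None = None


def trapezoid(times, values) -> float:
    """Linear trapezoidal area over [times[0], times[-1]]."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("trapezoid needs at least 2 points")
    if np.any(np.diff(times) <= 0.0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(values, times))


def diffusion_ratio(auc_pbmc: float, auc_wb: float) -> float:
    """AUC_PBMC/AUC_WB as a concentration ratio (cell-volume converted)."""
    if auc_wb <= 0.0:
        raise ValueError("AUC_WB must be > 0")
    return (auc_pbmc / PBMC_UL_PER_MILLION) / auc_wb


def _series_metrics(times, values):
    """(C0, Cmax, Tmax) from raw samples; C0 is the t=0 (predose) value,
    Tmax tie-break takes the earliest time."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        return None, None, None
    c0 = float(values[times == 0.0][0]) if np.any(times == 0.0) else None
    i = int(np.argmax(values))  # argmax returns the first maximum
    return c0, float(values[i]), float(times[i])


def nca_metrics(
    subject: Subject,
    profile: SimulatedProfile | None = None,
) -> tuple[ExposureMetrics, list[str]]:
    """Per-subject exposure metrics.

    C0/Cmax/Tmax always come from the raw samples.  AUCs come from the
    trapezoidal rule on the raw samples, or on the model-predicted dense
    ``profile`` when one is given.  Returns the metrics and a list of
    findings (e.g. a missing predose sample).
    """
    findings: list[str] = []
    dose = subject.dose_amount
    c0_wb, cmax_wb, tmax_wb = _series_metrics(subject.wb.times, subject.wb.values)
    c0_pb, cmax_pb, tmax_pb = _series_metrics(subject.pbmc.times, subject.pbmc.values)
    if subject.wb.times and c0_wb is None:
        findings.append("no t=0 whole-blood sample; C0_WB not reported")
    if subject.pbmc.times and c0_pb is None:
        findings.append("no t=0 PBMC sample; C0_PBMC not reported")

    if profile is not None:
        t = np.asarray(profile.times, dtype=float)
        auc_wb = trapezoid(t, profile.c_wb)
        auc_pb = trapezoid(t, profile.c_pbmc)
    else:
        auc_wb = (
            trapezoid(subject.wb.times, subject.wb.values)
            if len(subject.wb) >= 2 else None
        )
        auc_pb = (
            trapezoid(subject.pbmc.times, subject.pbmc.values)
            if len(subject.pbmc) >= 2 else None
        )

    cl_f = None
    if auc_wb and dose and auc_wb > 0.0:
        # mg -> ng (1e6), then mL/h -> L/h (1e-3)
        cl_f = dose * 1e6 / auc_wb / 1e3
    ratio = None
    if auc_wb and auc_pb and auc_wb > 0.0:
        ratio = diffusion_ratio(auc_pb, auc_wb)

    return (
        ExposureMetrics(
            dose=dose,
            c0_wb=c0_wb, cmax_wb=cmax_wb, tmax_wb=tmax_wb, auc_wb=auc_wb,
            c0_pbmc=c0_pb, cmax_pbmc=cmax_pb, tmax_pbmc=tmax_pb, auc_pbmc=auc_pb,
            cl_f=cl_f, diffusion_ratio=ratio,
        ),
        findings,
    )


def pd_metrics(can) -> PDMetrics:
    """Calcineurin-activity metrics over the interval.

    Maximal inhibition is relative to the pre-treatment basal activity:
    100 * (min activity - basal) / basal, negative when activity drops
    below basal (the usual case), positive when it stays above.
    """
    if can is None or can.basal is None:
        raise ValueError("basal calcineurin activity is required")
    if not can.basal > 0.0:
        raise ValueError("basal activity must be > 0")
    if len(can) == 0:
        raise ValueError("calcineurin series is empty")
    times = np.asarray(can.times, dtype=float)
    act = np.asarray(can.activity, dtype=float)
    i = int(np.argmin(act))  # earliest minimum
    aua = trapezoid(times, act) if times.size >= 2 else float("nan")
    span = times[-1] - times[0]
    return PDMetrics(
        aua=aua,
        can_basal=float(can.basal),
        can_min=float(act[i]),
        can_moy=float(aua / span) if span > 0 else float(act.mean()),
        max_inhibition_pct=float(100.0 * (act[i] - can.basal) / can.basal),
        t_min=float(times[i]),
    )


def correlate(x, y, log_x: bool = False, alpha: float = 0.05) -> CorrelationResult:
    """Correlation with a Shapiro normality gate.

    Both variables normal at level ``alpha`` -> Pearson (with the linear
    regression slope/intercept and r^2 = r^2); otherwise Spearman rank
    correlation (r^2 reported from the rank coefficient).  ``log_x``
    log-transforms x before testing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlate needs two equal-length vectors, n >= 3")
    if log_x:
        if np.any(x <= 0.0):
            raise ValueError("log_x requires strictly positive x")
        x = np.log(x)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined: zero variance")

    normal = (
        stats.shapiro(x).pvalue >= alpha and stats.shapiro(y).pvalue >= alpha
    )
    if normal:
        reg = stats.linregress(x, y)
        return CorrelationResult(
            method="pearson", r=float(reg.rvalue), r2=float(reg.rvalue**2),
            p=float(reg.pvalue), n=int(x.size),
            slope=float(reg.slope), intercept=float(reg.intercept),
        )
    rho, p = stats.spearmanr(x, y)
    ties = (len(np.unique(x)) < x.size) or (len(np.unique(y)) < y.size)
    if x.size <= 8 and not ties:
        p = _spearman_exact_p(x, y)
    return CorrelationResult(
        method="spearman", r=float(rho), r2=float(rho**2), p=float(p), n=int(x.size),
    )


def _spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p for the rank correlation (small n,
    no ties): full enumeration of rank permutations."""
    from itertools import permutations as _perms

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    total = hits = 0
    for perm in _perms(ry):
        total += 1
        hits += abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12
    return hits / total
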