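"""Concentration-effect model for calcineurin inhibition by tacrolimus.

The maximal inhibition of calcineurin activity over a dosing interval
(expressed in % of the pre-treatment basal activity, negative = inhibited)
is related to the peak tacrolimus concentration by a hyperbolic inhibitory
Emax curve with unit Hill coefficient:

    E(c) = I_min + (I_max - I_min) / (1 + c / IC50)

where I_max is the *lowest* inhibitory effect (the value at c = 0,
typically ~0 %), I_min the *highest* (most negative) inhibitory effect
reached at high concentration, and IC50 the concentration giving the
midpoint effect.  The curve is monotone non-increasing; inversion for a
target effect (e.g. IC50 as the concentration of -50 % inhibition
relative to basal, or IC37 for the cohort-median -37 %) is closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "InhibitionModel",
    "InhibitionFit",
    "UnidentifiableError",
    "predict_inhibition",
    "fit_inhibition",
    "invert_inhibition",
]


class UnidentifiableError(RuntimeError):
    """The data carry no usable concentration-effect relationship."""


@dataclass(frozen=True)
class InhibitionModel:
    """I_min < I_max in %, IC50 > 0 in the concentration unit of its matrix
    (ng/mL for whole blood, pg per million cells for PBMC)."""

    i_min: float
    i_max: float
    ic50: float
    matrix: str = "PBMC"

    def __post_init__(self) -> None:
        if not self.i_min < self.i_max:
            raise ValueError(f"require I_min < I_max, got {self.i_min} >= {self.i_max}")
        if not self.ic50 > 0.0:
            raise ValueError(f"IC50 must be > 0, got {self.ic50}")
        if self.matrix not in ("WB", "PBMC"):
            raise ValueError(f"matrix must be WB or PBMC, got {self.matrix!r}")


@dataclass(frozen=True)
class InhibitionFit:
    i_min: float
    i_max: float
    ic50: float
    matrix: str
    rss: float
    boundary_flag: bool  # IC50 pinned to the search boundary or flat fit

    @property
    def model(self) -> InhibitionModel:
        return InhibitionModel(self.i_min, self.i_max, self.ic50, self.matrix)


def predict_inhibition(model: InhibitionModel, c):
    """Inhibitory effect (%) at concentration(s) c >= 0."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0.0):
        raise ValueError("concentration must be >= 0")
    out = model.i_min + (model.i_max - model.i_min) / (1.0 + c / model.ic50)
    return out if out.shape else float(out)


def invert_inhibition(model: InhibitionModel, target_effect: float) -> float:
    """Concentration producing ``target_effect`` % inhibition (ICx).

    Exact inverse of :func:`predict_inhibition`; the target must lie in
    (I_min, I_max] — effects at or below I_min are unreachable.
    """
    if not model.i_min < target_effect <= model.i_max:
        raise ValueError(
            f"target effect {target_effect} outside reachable range "
            f"({model.i_min}, {model.i_max}]"
        )
    return float(
        model.ic50 * (model.i_max - target_effect) / (target_effect - model.i_min)
    )


def fit_inhibition(
    cmax,
    effects,
    matrix: str = "PBMC",
    n_starts: int = 5,
) -> InhibitionFit:
    """Nonlinear least squares of the inhibition curve on (Cmax, effect) pairs.

    Fits (I_min, I_max, log IC50) with multiple IC50 starting values
    spread over the observed concentration range.  Requires >= 4 pairs
    with concentration spread (max/min >= 3).  Raises
    :class:`UnidentifiableError` for a flat response; sets
    ``boundary_flag`` when the optimum pins IC50 to the search boundary
    or collapses I_min onto I_max (no usable relationship).
    """
    c = np.asarray(cmax, dtype=float)
    e = np.asarray(effects, dtype=float)
    if c.size != e.size or c.size < 4:
        raise ValueError("need >= 4 (Cmax, effect) pairs")
    if np.any(c <= 0.0):
        raise ValueError("concentrations must be > 0")
    if c.max() / c.min() < 3.0:
        raise ValueError("insufficient concentration spread (max/min < 3)")
    scale = max(np.std(e), 1e-12)
    if np.std(e) < 1e-10 * max(1.0, np.abs(e).max()):
        raise UnidentifiableError("effect variance ~ 0: inhibition curve unidentifiable")

    lo_log, hi_log = np.log(c.min()) - np.log(50.0), np.log(c.max()) + np.log(50.0)
    e_span = e.max() - e.min()

    def resid(p):
        i_min, i_max, log_ic50 = p
        return i_min + (i_max - i_min) / (1.0 + c / np.exp(log_ic50)) - e

    best = None
    for log0 in np.linspace(np.log(c.min()), np.log(c.max()), n_starts):
        sol = least_squares(
            resid,
            x0=[e.min() - 0.25 * e_span, e.max(), log0],
            bounds=([-np.inf, -np.inf, lo_log], [np.inf, np.inf, hi_log]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    i_min, i_max, log_ic50 = best.x
    ic50 = np.exp(log_ic50)
    # signal-to-noise gate: the fitted curve must move by at least twice
    # the residual SD across the observed concentration range, otherwise
    # there is no usable relationship
    resid_sd = np.sqrt(2.0 * best.cost / max(c.size - 3, 1))
    span = abs(
        (i_min + (i_max - i_min) / (1.0 + c.min() / ic50))
        - (i_min + (i_max - i_min) / (1.0 + c.max() / ic50))
    )
    at_boundary = (
        log_ic50 - lo_log < 1e-3 or hi_log - log_ic50 < 1e-3
        or abs(i_max - i_min) < 1e-6 * scale
        or span < 2.0 * resid_sd
    )
    return InhibitionFit(
        i_min=float(i_min),
        i_max=float(i_max),
        ic50=float(np.exp(log_ic50)),
        matrix=matrix,
        rss=float(2.0 * best.cost),
        boundary_flag=bool(at_boundary),
    )
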