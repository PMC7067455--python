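"""Nonparametric population PK estimation by expectation-maximization.

The population distribution of the structural parameters is represented
as a discrete set of support points with probability weights (the
nonparametric maximum-likelihood estimator of a mixing distribution).
Starting from a scrambled low-discrepancy grid inside a parameter box,
weights are updated by the multiplicative EM rule

    w_j  <-  w_j * (1/n) * sum_i P_ij / sum_k w_k P_ik

where ``P_ij`` is subject i's marginal likelihood under support point j
(Gaussian residuals with the data-fixed SD sigma(y_obs) = assay_sd(y_obs)
+ lambda).  The log marginal likelihood is non-decreasing under this
update.  After convergence, near-zero-weight points are condensed away
and one local-perturbation refinement cycle is run (a reduced form of
adaptive-grid refinement; each surviving point may move +-10 % in the
transformed space if that improves the likelihood).

Estimation operates in a transformed space — log for positive
parameters, logit for the absorption fraction r — so the box bounds are
scale-free.  Individual ("posterior") parameters are the Bayes-weighted
means over support points in that transformed space, back-transformed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .data_model_io import Cohort, Subject
from .pk_model import (
    DEFAULT_N_PRIOR_DOSES,
    PARAM_NAMES,
    ErrorModel,
    PKParameterVector,
    concentrations,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "NPModel",
    "SupportPoint",
    "FitDiagnostics",
    "VPCResult",
    "CovariateScreenResult",
    "subject_loglik",
    "npem_fit",
    "posterior_params",
    "model_aic",
    "gof_diagnostics",
    "vpc",
    "covariate_screen",
    "save_model",
    "load_model",
]

#: default estimation box; wide enough to contain the synthetic
#: population and deliberately not informative
DEFAULT_BOUNDS = {
    "r": (0.05, 0.95),
    "a1": (0.5, 10.0),
    "b1": (0.5, 10.0),
    "a2": (0.02, 0.8),
    "b2": (0.4, 6.0),
    "V": (5.0, 80.0),
    "ke": (0.1, 3.0),
    "k12": (0.005, 0.4),
    "k21": (0.3, 8.0),
    "S": (2000.0, 80000.0),
}

_N_PARAMS = len(PARAM_NAMES)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class SupportPoint:
    theta: PKParameterVector
    weight: float


@dataclass(frozen=True)
class NPModel:
    points: np.ndarray  # (K, 10) natural scale
    weights: np.ndarray  # (K,)
    bounds: dict
    error: ErrorModel
    loglik: float
    n_iter: int
    seed: int
    n_prior_doses: int = DEFAULT_N_PRIOR_DOSES

    @property
    def support(self) -> tuple:
        return tuple(
            SupportPoint(PKParameterVector.from_array(p), float(w))
            for p, w in zip(self.points, self.weights)
        )

    @property
    def n_support(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class FitDiagnostics:
    table: "object"  # pandas DataFrame: one row per observation
    posterior_means: np.ndarray  # (n_subjects, 10)
    posterior_weights: tuple  # per subject (K,) arrays
    trough_wb: np.ndarray  # model-estimated C01 per subject
    trough_pbmc: np.ndarray  # model-estimated C02 per subject
    subject_ids: tuple


@dataclass(frozen=True)
class VPCResult:
    bin_times: np.ndarray
    p5: dict  # matrix -> (lo95, median, hi95) arrays per bin
    p50: dict
    p95: dict
    coverage: dict  # matrix -> fraction of observations inside the 90% PI
    n_sim: int


@dataclass(frozen=True)
class CovariateScreenResult:
    records: tuple  # dicts: parameter, covariate, test, p, flagged
    findings: tuple = ()


# ---------------------------------------------------------------------------
# transforms


def _to_transformed(x, eps=1e-12):
    x = np.asarray(x, dtype=float)
    z = np.log(np.clip(x, eps, None))
    ir = PARAM_NAMES.index("r")
    r = np.clip(x[..., ir], eps, 1.0 - eps)
    z[..., ir] = np.log(r / (1.0 - r))
    return z


def _from_transformed(z):
    z = np.asarray(z, dtype=float)
    x = np.exp(z)
    ir = PARAM_NAMES.index("r")
    x[..., ir] = 1.0 / (1.0 + np.exp(-z[..., ir]))
    return x


def _bounds_arrays(bounds: dict):
    lo = np.array([bounds[n][0] for n in PARAM_NAMES], dtype=float)
    hi = np.array([bounds[n][1] for n in PARAM_NAMES], dtype=float)
    return lo, hi


# ---------------------------------------------------------------------------
# likelihood machinery


def _subject_obs(subject: Subject):
    """Stack a subject's WB and PBMC observations with their sigmas."""
    times, values, matrices = [], [], []
    for series, m in ((subject.wb, "WB"), (subject.pbmc, "PBMC")):
        times.extend(series.times)
        values.extend(series.values)
        matrices.extend([m] * len(series))
    return np.asarray(times), np.asarray(values), np.asarray(matrices)


def subject_loglik(
    subject: Subject,
    theta: PKParameterVector,
    error: ErrorModel | None = None,
    n_prior_doses: int = DEFAULT_N_PRIOR_DOSES,
) -> float:
    """Gaussian log likelihood of one subject's concentration data.

    sigma is evaluated at the *observed* concentration (data-fixed), so
    the log-likelihood is a plain weighted least-squares criterion in the
    model prediction.
    """
    err = error if error is not None else ErrorModel()
    times, values, matrices = _subject_obs(subject)
    if times.size == 0:
        raise ValueError(f"subject {subject.id} has no observations")
    dose = subject.dose_amount
    if dose is None:
        raise ValueError(f"subject {subject.id} has no dose event")
    c_wb, c_pbmc = concentrations(theta.as_array(), dose, times, n_prior_doses)
    pred = np.where(matrices == "WB", c_wb, c_pbmc)
    sigma = np.array([err.sigma(v, m) for v, m in zip(values, matrices)])
    z = (values - pred) / sigma
    return float(-0.5 * np.sum(z * z + np.log(2.0 * np.pi * sigma * sigma)))


class _LikelihoodTable:
    """Per-subject log-likelihoods against a bank of parameter vectors.

    Predictions for all points are computed once on the union of observed
    times at unit dose and rescaled per subject (the model is linear in
    dose), so the cost is one vectorized simulation per bank.
    """

    def __init__(self, cohort: Cohort, error: ErrorModel, n_prior_doses: int):
        cohort.require_nonempty("nonparametric estimation")
        self.error = error
        self.n_prior_doses = n_prior_doses
        self.subjects = cohort.subjects
        all_times = sorted({
            t for s in self.subjects
            for series in (s.wb, s.pbmc)
            for t in series.times
        })
        if not all_times:
            raise ValueError("cohort has no concentration observations")
        self.union_times = np.asarray(all_times)
        index = {t: i for i, t in enumerate(all_times)}

        self._obs = []
        for s in self.subjects:
            times, values, matrices = _subject_obs(s)
            if times.size == 0:
                raise ValueError(f"subject {s.id} has no observations")
            sigma = np.array(
                [error.sigma(v, m) for v, m in zip(values, matrices)]
            )
            cols = np.array([index[t] for t in times])
            is_wb = matrices == "WB"
            dose = s.dose_amount
            if dose is None:
                raise ValueError(f"subject {s.id} has no dose event")
            self._obs.append((cols, is_wb, values, sigma, dose))

    def loglik_matrix(self, points: np.ndarray) -> np.ndarray:
        """(n_subjects, K) log-likelihood matrix."""
        u_wb, u_pb = concentrations(
            points, 1.0, self.union_times, self.n_prior_doses
        )
        n, K = len(self._obs), points.shape[0]
        ll = np.empty((n, K))
        for i, (cols, is_wb, values, sigma, dose) in enumerate(self._obs):
            pred = np.where(is_wb[None, :], u_wb[:, cols], u_pb[:, cols]) * dose
            z = (values[None, :] - pred) / sigma[None, :]
            ll[i] = -0.5 * np.sum(
                z * z + np.log(2.0 * np.pi * sigma * sigma)[None, :], axis=1
            )
        return ll


def _em_weights(ll: np.ndarray, w0: np.ndarray, tol: float, max_iter: int):
    """Multiplicative EM on the weights; returns (w, loglik trace)."""
    row_max = ll.max(axis=1, keepdims=True)
    L = np.exp(ll - row_max)  # (n, K), rows scaled to max 1
    n = L.shape[0]
    w = w0.copy()
    trace = []
    for _ in range(max_iter):
        mix = L @ w  # (n,)
        if np.any(mix <= 0.0):
            bad = int(np.argmax(mix <= 0.0))
            raise FitError(
                f"subject index {bad} has zero likelihood under every "
                "support point; widen the bounds or check the data"
            )
        loglik = float(np.sum(np.log(mix)) + row_max.sum())
        if trace and loglik < trace[-1] - 1e-9:
            raise FitError("EM log-likelihood decreased (numerical failure)")
        if trace and loglik - trace[-1] < tol:
            trace.append(loglik)
            break
        trace.append(loglik)
        w = w * (L.T @ (1.0 / mix)) / n
        w = w / w.sum()
    return w, trace


def npem_fit(
    cohort: Cohort,
    bounds: dict | None = None,
    n_grid: int = 8192,
    tol: float = 1e-4,
    seed: int = 0,
    error: ErrorModel | None = None,
    max_iter: int = 500,
    n_prior_doses: int = DEFAULT_N_PRIOR_DOSES,
    refine: bool = True,
    subject_candidates: bool = True,
) -> NPModel:
    """Fit the nonparametric population distribution.

    Support is initialized at ``n_grid`` scrambled-Sobol points in the
    transformed box, augmented (``subject_candidates``) with one
    bounded weighted-least-squares candidate per subject — the usual
    adaptive-grid device that lets each subject's posterior reach its own
    likelihood mode.  EM weight updates run until the log-likelihood gain
    drops below ``tol``; points with weight < 1e-6 of the maximum are
    condensed away; shrinking local-perturbation cycles then let the
    surviving points move if the likelihood improves.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    err = error if error is not None else ErrorModel()
    table = _LikelihoodTable(cohort, err, n_prior_doses)

    lo, hi = _bounds_arrays(bounds)
    zlo, zhi = _to_transformed(lo), _to_transformed(hi)
    sampler = qmc.Sobol(d=_N_PARAMS, scramble=True, rng=np.random.default_rng(seed))
    unit = sampler.random(n_grid)
    z = zlo + unit * (zhi - zlo)
    points = _from_transformed(z)

    ll = table.loglik_matrix(points)
    if subject_candidates:
        cand = _subject_candidate_points(table, points, ll, zlo, zhi)
        points = np.vstack([points, cand])
        ll = np.hstack([ll, table.loglik_matrix(cand)])
    w0 = np.full(points.shape[0], 1.0 / points.shape[0])
    w, trace = _em_weights(ll, w0, tol, max_iter)
    n_iter = len(trace)

    # condensation
    keep = w >= 1e-6 * w.max()
    points, w, ll = points[keep], w[keep], ll[:, keep]
    w = w / w.sum()

    if refine and points.shape[0] > 0:
        rng = np.random.default_rng(seed + 1)
        span = zhi - zlo
        # shrinking local-perturbation cycles: each surviving point may
        # move if that improves the mixture likelihood at fixed weights,
        # then the weights are re-optimized
        for scale in (0.1, 0.05, 0.025):
            z = _to_transformed(points)
            z_prop = z + rng.uniform(-scale, scale, size=z.shape) * span
            z_prop = np.clip(z_prop, zlo, zhi)
            cand = _from_transformed(z_prop)
            ll_cand = table.loglik_matrix(cand)
            base = _mix_loglik(ll, w)
            for j in range(points.shape[0]):
                ll_try = ll.copy()
                ll_try[:, j] = ll_cand[:, j]
                new = _mix_loglik(ll_try, w)
                if new > base:
                    ll = ll_try
                    points[j] = cand[j]
                    base = new
            w, trace2 = _em_weights(ll, w, tol, max_iter)
            n_iter += len(trace2)
            keep = w >= 1e-6 * w.max()
            points, w = points[keep], w[keep]
            w = w / w.sum()
            ll = ll[:, keep]

    return NPModel(
        points=points,
        weights=w,
        bounds=bounds,
        error=err,
        loglik=_mix_loglik(ll, w),
        n_iter=n_iter,
        seed=seed,
        n_prior_doses=n_prior_doses,
    )


def _subject_candidate_points(
    table, points, ll, zlo, zhi, n_rounds=80, seed=0
):
    """One likelihood-optimized parameter vector per subject.

    Starts from each subject's best grid point and improves it by an
    annealed random local search in the transformed space; every round
    evaluates one proposal per subject in a single vectorized simulation,
    so the cost is ~2 * n_rounds batched profile evaluations total.
    """
    rng = np.random.default_rng(seed)
    n = len(table._obs)
    z = _to_transformed(points[np.argmax(ll, axis=1)])
    z = np.clip(z, zlo, zhi)
    span = zhi - zlo

    def batch_loglik(zmat):
        x = _from_transformed(zmat)
        u_wb, u_pb = concentrations(x, 1.0, table.union_times, table.n_prior_doses)
        out = np.empty(n)
        for i, (cols, is_wb, values, sigma, dose) in enumerate(table._obs):
            pred = np.where(is_wb, u_wb[i, cols], u_pb[i, cols]) * dose
            r = (values - pred) / sigma
            out[i] = -0.5 * np.sum(r * r)
        return out

    best = batch_loglik(z)
    for it in range(n_rounds):
        scale = 0.15 * 0.96**it
        prop = np.clip(z + rng.standard_normal(z.shape) * scale * span, zlo, zhi)
        cand = batch_loglik(prop)
        better = cand > best
        z[better] = prop[better]
        best[better] = cand[better]
    return _from_transformed(z)


def _mix_loglik(ll: np.ndarray, w: np.ndarray) -> float:
    row_max = ll.max(axis=1, keepdims=True)
    mix = np.exp(ll - row_max) @ w
    return float(np.sum(np.log(mix)) + row_max.sum())


def _posterior_matrix(model: NPModel, cohort: Cohort) -> np.ndarray:
    """(n_subjects, K) posterior weights over support points."""
    table = _LikelihoodTable(cohort, model.error, model.n_prior_doses)
    ll = table.loglik_matrix(model.points)
    logw = ll + np.log(model.weights)[None, :]
    logw -= logw.max(axis=1, keepdims=True)
    post = np.exp(logw)
    post /= post.sum(axis=1, keepdims=True)
    return post


def posterior_params(subject: Subject, model: NPModel):
    """Posterior mean parameter vector and posterior weights for a subject."""
    post = _posterior_matrix(model, Cohort(subjects=(subject,)))[0]
    z = _to_transformed(model.points)
    z_mean = post @ z
    return PKParameterVector.from_array(_from_transformed(z_mean)), post


def model_aic(model: NPModel, cohort: Cohort | None = None) -> float:
    """AIC = -2 loglik + 2 P with P = K (d + 1) - 1.

    Each of the K support points contributes d coordinates plus a weight,
    with one simplex constraint.  The count is a convention for relative
    comparisons between fits to the same data.
    """
    K = model.n_support
    P = K * (_N_PARAMS + 1) - 1
    return float(-2.0 * model.loglik + 2.0 * P)


def gof_diagnostics(model: NPModel, cohort: Cohort) -> FitDiagnostics:
    """Population/individual predictions and weighted residuals.

    Population predictions are the weight-averaged predictions over the
    support; individual predictions average with each subject's posterior
    weights.  Weighted residual = (obs - individual pred) / sigma(obs).
    """
    import pandas as pd

    table = _LikelihoodTable(cohort, model.error, model.n_prior_doses)
    post = _posterior_matrix(model, cohort)
    u_wb, u_pb = concentrations(
        model.points, 1.0, table.union_times, model.n_prior_doses
    )
    t12 = np.searchsorted(table.union_times, 12.0)
    has12 = t12 < table.union_times.size and table.union_times[t12] == 12.0
    if not has12:
        u_wb12, u_pb12 = concentrations(
            model.points, 1.0, np.array([12.0]), model.n_prior_doses
        )

    z_points = _to_transformed(model.points)
    rows = []
    post_means = np.empty((len(cohort.subjects), _N_PARAMS))
    troughs_wb = np.empty(len(cohort.subjects))
    troughs_pb = np.empty(len(cohort.subjects))
    for i, s in enumerate(cohort.subjects):
        cols, is_wb, values, sigma, dose = table._obs[i]
        pred_bank = np.where(is_wb[None, :], u_wb[:, cols], u_pb[:, cols]) * dose
        pop = model.weights @ pred_bank
        ind = post[i] @ pred_bank
        wres = (values - ind) / sigma
        times = table.union_times[cols]
        for k in range(values.size):
            rows.append({
                "ID": s.id,
                "TIME_H": float(times[k]),
                "MATRIX": "WB" if is_wb[k] else "PBMC",
                "DV": float(values[k]),
                "PRED_POP": float(pop[k]),
                "PRED_IND": float(ind[k]),
                "WRES": float(wres[k]),
            })
        post_means[i] = _from_transformed(post[i] @ z_points)
        if has12:
            bank_wb, bank_pb = u_wb[:, t12], u_pb[:, t12]
        else:
            bank_wb, bank_pb = u_wb12[:, 0], u_pb12[:, 0]
        troughs_wb[i] = float(post[i] @ bank_wb * dose)
        troughs_pb[i] = float(post[i] @ bank_pb * dose)

    return FitDiagnostics(
        table=pd.DataFrame(rows),
        posterior_means=post_means,
        posterior_weights=tuple(post),
        trough_wb=troughs_wb,
        trough_pbmc=troughs_pb,
        subject_ids=tuple(s.id for s in cohort.subjects),
    )


def vpc(model: NPModel, cohort: Cohort, n_sim: int = 200, seed: int = 0) -> VPCResult:
    """Visual predictive check by replicate simulation at the observed design.

    Each replicate redraws every subject's parameters from the discrete
    population distribution, simulates at that subject's design (same
    dose, same times) and adds residual noise with SD sigma(c_pred).
    Per nominal time bin the 5th/50th/95th percentiles are summarized
    across replicates (median and 95% envelope); ``coverage`` is the
    fraction of observed values inside the median 90% prediction band.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    table = _LikelihoodTable(cohort, model.error, model.n_prior_doses)
    u_wb, u_pb = concentrations(
        model.points, 1.0, table.union_times, model.n_prior_doses
    )
    n = len(cohort.subjects)

    obs_by_bin = {"WB": {}, "PBMC": {}}
    for i, s in enumerate(cohort.subjects):
        cols, is_wb, values, sigma, dose = table._obs[i]
        for k in range(values.size):
            m = "WB" if is_wb[k] else "PBMC"
            obs_by_bin[m].setdefault(cols[k], []).append(values[k])

    bins = sorted({c for m in obs_by_bin.values() for c in m})
    bin_times = table.union_times[bins]
    perc = {m: {q: [] for q in (5, 50, 95)} for m in ("WB", "PBMC")}
    for _ in range(n_sim):
        draw = rng.choice(model.n_support, size=n, p=model.weights)
        sim_by_bin = {"WB": {}, "PBMC": {}}
        for i, s in enumerate(cohort.subjects):
            cols, is_wb, values, sigma, dose = table._obs[i]
            pred = np.where(is_wb, u_wb[draw[i], cols], u_pb[draw[i], cols]) * dose
            sd = np.array([
                model.error.sigma(c, "WB" if b else "PBMC")
                for c, b in zip(pred, is_wb)
            ])
            sim = np.maximum(pred + sd * rng.standard_normal(pred.size), 0.0)
            for k in range(sim.size):
                m = "WB" if is_wb[k] else "PBMC"
                sim_by_bin[m].setdefault(cols[k], []).append(sim[k])
        for m in ("WB", "PBMC"):
            for q in (5, 50, 95):
                perc[m][q].append([
                    np.percentile(sim_by_bin[m][c], q) if c in sim_by_bin[m] else np.nan
                    for c in bins
                ])

    def summarize(m, q):
        arr = np.asarray(perc[m][q])  # (n_sim, n_bins)
        return (
            np.nanpercentile(arr, 2.5, axis=0),
            np.nanpercentile(arr, 50, axis=0),
            np.nanpercentile(arr, 97.5, axis=0),
        )

    p5 = {m: summarize(m, 5) for m in ("WB", "PBMC")}
    p50 = {m: summarize(m, 50) for m in ("WB", "PBMC")}
    p95 = {m: summarize(m, 95) for m in ("WB", "PBMC")}

    coverage = {}
    for m in ("WB", "PBMC"):
        inside = total = 0
        for j, c in enumerate(bins):
            if c not in obs_by_bin[m]:
                continue
            lo_band, hi_band = p5[m][1][j], p95[m][1][j]
            for v in obs_by_bin[m][c]:
                total += 1
                inside += lo_band <= v <= hi_band
        coverage[m] = inside / total if total else float("nan")

    return VPCResult(
        bin_times=bin_times, p5=p5, p50=p50, p95=p95,
        coverage=coverage, n_sim=n_sim,
    )


_CONTINUOUS_COVS = ("age", "weight", "albumin", "hematocrit", "pbmc_count")


def covariate_screen(
    diagnostics: FitDiagnostics,
    cohort: Cohort,
    alpha: float = 0.01,
    extra_parameters: dict | None = None,
) -> CovariateScreenResult:
    """Screen individual posterior parameters against covariates.

    Continuous covariates -> univariate linear regression p-value;
    categorical covariates (sex, each genotype) -> Mann-Whitney for two
    groups, Kruskal-Wallis for three or more.  Pairs with p < ``alpha``
    (0.01 by default) are flagged.  ``extra_parameters`` may add derived
    per-subject quantities (e.g. model troughs) as name -> vector.
    """
    subs = {s.id: s for s in cohort.subjects}
    ordered = [subs[sid] for sid in diagnostics.subject_ids]

    param_vectors = {
        name: diagnostics.posterior_means[:, j]
        for j, name in enumerate(PARAM_NAMES)
    }
    param_vectors["CL"] = (
        param_vectors["ke"] * param_vectors["V"]
    )
    param_vectors["C01"] = diagnostics.trough_wb
    param_vectors["C02"] = diagnostics.trough_pbmc
    if extra_parameters:
        param_vectors.update(extra_parameters)

    covariate_vectors: dict = {
        name: np.array([getattr(s.covariates, name) for s in ordered])
        for name in _CONTINUOUS_COVS
        if all(s.covariates is not None for s in ordered)
    }
    categorical: dict = {}
    if all(s.covariates is not None for s in ordered):
        categorical["sex"] = np.array([s.covariates.sex for s in ordered])
    genotype_keys = sorted({
        (g.origin, g.snp) for s in ordered for g in s.genotypes
    })
    for origin, snp in genotype_keys:
        calls = [s.genotype(origin, snp) for s in ordered]
        if all(c is not None for c in calls):
            categorical[f"{origin[0].upper()}_{snp}"] = np.array(calls)

    records, findings = [], []
    for pname, pvec in param_vectors.items():
        for cname, cvec in covariate_vectors.items():
            if np.ptp(cvec) == 0.0:
                findings.append(f"covariate {cname} constant; skipped")
                continue
            reg = stats.linregress(cvec, pvec)
            p = float(reg.pvalue)
            records.append({
                "parameter": pname, "covariate": cname,
                "test": "linear-regression", "p": p, "flagged": p < alpha,
            })
        for cname, cvec in categorical.items():
            levels = sorted(set(cvec))
            if len(levels) < 2:
                findings.append(f"covariate {cname} constant; skipped")
                continue
            groups = [pvec[cvec == lv] for lv in levels]
            if len(levels) == 2:
                joint = np.concatenate(groups)
                if np.ptp(joint) == 0.0:
                    p = 1.0
                else:
                    ties = len(np.unique(joint)) < joint.size
                    method = "exact" if (joint.size <= 20 and not ties) else "asymptotic"
                    p = float(stats.mannwhitneyu(
                        groups[0], groups[1], alternative="two-sided", method=method
                    ).pvalue)
                test = "mann-whitney"
            else:
                p = float(stats.kruskal(*groups).pvalue)
                test = "kruskal-wallis"
            records.append({
                "parameter": pname, "covariate": cname,
                "test": test, "p": p, "flagged": p < alpha,
            })
    return CovariateScreenResult(records=tuple(records), findings=tuple(findings))


# ---------------------------------------------------------------------------
# model (de)serialization


def save_model(model: NPModel, path) -> None:
    payload = {
        "points": model.points.tolist(),
        "weights": model.weights.tolist(),
        "bounds": {k: list(v) for k, v in model.bounds.items()},
        "error": {
            "wb_add": model.error.wb_add, "wb_prop": model.error.wb_prop,
            "pbmc_add": model.error.pbmc_add, "pbmc_prop": model.error.pbmc_prop,
            "lam": model.error.lam,
        },
        "loglik": model.loglik,
        "n_iter": model.n_iter,
        "seed": model.seed,
        "n_prior_doses": model.n_prior_doses,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> NPModel:
    with open(path) as fh:
        payload = json.load(fh)
    return NPModel(
        points=np.asarray(payload["points"], dtype=float),
        weights=np.asarray(payload["weights"], dtype=float),
        bounds={k: tuple(v) for k, v in payload["bounds"].items()},
        error=ErrorModel(**payload["error"]),
        loglik=float(payload["loglik"]),
        n_iter=int(payload["n_iter"]),
        seed=int(payload["seed"]),
        n_prior_doses=int(payload["n_prior_doses"]),
    )
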