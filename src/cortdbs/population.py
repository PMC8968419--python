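"""Population layer: variability, likelihood, estimation, SIR and VPC.

Interindividual variability is log-normal on the structural parameters
(param_i = typical * allometric scaling * exp(eta), eta ~ N(0, omega^2));
the age-group covariate selects the apparent RBC volume V_delta.  Residual
error is additive on the log scale (exponential), shared across plasma and
DBS observations and across populations.

The marginal likelihood is approximated by the Laplace method around the
per-subject empirical-Bayes modes: the inner optimization over eta is a
Gauss-Newton least-squares problem on log-scale residuals, and the Hessian
of the joint negative log-density is approximated by J'J/sigma^2 + Omega^-1
from the inner Jacobian.  Parameter uncertainty comes from sampling
importance resampling (SIR) with a multivariate-normal proposal on the
log-parameters; model adequacy from simulation-based visual predictive
checks (VPCs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _fastsim as fs
from .binding import BindingParams, BloodGeometry, default_binding_params
from .io import DVID_DBS, DVID_PLASMA, StudyDataset
from .params import (
    ALLOMETRIC_EXP_CL,
    ALLOMETRIC_EXP_V,
    AgeGroup,
    PopulationParams,
    REF_WEIGHT,
    StructuralParams,
)

__all__ = [
    "Covariates", "Individual", "draw_individual", "apply_residual",
    "filter_blq", "neg2ll", "fit", "FitResult", "sir", "SirResult",
    "vpc", "simulate_from_design", "DEFAULT_ETA_NAMES", "DEFAULT_FREE",
]

#: Structural parameters carrying a random effect in the default fit model.
DEFAULT_ETA_NAMES = ("cl", "vmax", "f", "v_delta")

#: Free parameters of the default estimation problem (10 parameters).
DEFAULT_FREE = (
    "cl", "v_c", "vmax", "v_delta_children_infants", "v_delta_neonate",
    "omega_cl", "omega_vmax", "omega_f", "omega_v_delta", "sigma",
)

_PENALTY = 1e10


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Covariates:
    weight: float
    age_group: AgeGroup


@dataclass(frozen=True)
class Individual:
    """One subject's realized parameters (after allometry and random effects)."""

    structural: StructuralParams
    geometry: BloodGeometry
    binding: BindingParams
    etas: dict


def _resolve_binding(pop: PopulationParams) -> BindingParams:
    """Binding parameters with Bmax/KR falling back to the calibrated defaults."""
    base = default_binding_params()
    return BindingParams(
        kd=pop.kd,
        bmax=pop.bmax if pop.bmax is not None else base.bmax,
        ns_alb=pop.ns_alb,
        kr=pop.kr if pop.kr is not None else base.kr,
        ka_rbc_published=pop.ka_rbc_published,
    )


def _eta_names_for(cov: Covariates) -> list[str]:
    if cov.age_group is AgeGroup.ADULT:
        return ["cl", "km", "vmax", "f", "base_adult_pla"]
    return ["cl", "km", "vmax", "f", "v_delta", "base_child"]


def draw_individual(
    pop: PopulationParams,
    covariates: Covariates,
    rng,
) -> Individual:
    """Draw one individual: log-normal random effects around the weight-scaled
    typical values; the age group selects V_delta (perturbed by its own eta);
    pediatric plasma/DBS baselines share a single eta.  ``rng`` is a seed or
    a ``numpy.random.Generator``; the same seed gives identical draws."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cov = covariates
    if not isinstance(cov.age_group, AgeGroup):
        raise ValueError(f"unknown age group {cov.age_group!r}")

    etas = {}
    for name in _eta_names_for(cov):
        w = pop.omega.get(name if name != "base_adult_pla" else "base_adult_pla", 0.0)
        etas[name] = float(rng.normal(0.0, w)) if w > 0 else 0.0

    s = cov.weight / REF_WEIGHT
    th = pop.structural
    if cov.age_group is AgeGroup.ADULT:
        base_pla = pop.base_adult_pla * math.exp(etas["base_adult_pla"])
        base_dbs = 0.0
        v_delta = 0.0
        kr = 0.0
    else:
        base_pla = pop.base_child_pla * math.exp(etas["base_child"])
        base_dbs = pop.base_child_dbs * math.exp(etas["base_child"])
        v_delta = pop.v_delta[cov.age_group] * math.exp(etas["v_delta"])
        kr = None

    structural = replace(
        th,
        cl=th.cl * s**ALLOMETRIC_EXP_CL * math.exp(etas["cl"]),
        q=th.q * s**ALLOMETRIC_EXP_CL,
        v_c=th.v_c * s**ALLOMETRIC_EXP_V,
        v_p=th.v_p * s**ALLOMETRIC_EXP_V,
        km=th.km * math.exp(etas["km"]),
        vmax=th.vmax * math.exp(etas["vmax"]),
        f=th.f * math.exp(etas["f"]),
        base_pla=base_pla,
        base_dbs=base_dbs,
    )
    geometry = BloodGeometry(
        v_c=structural.v_c, v_delta=v_delta, weight=cov.weight,
        age_group=cov.age_group,
    )
    binding = _resolve_binding(pop)
    if kr == 0.0:
        binding = replace(binding, kr=0.0)
    return Individual(structural=structural, geometry=geometry,
                      binding=binding, etas=etas)


def _pvec(ind: Individual) -> np.ndarray:
    """Parameter vector for the compiled simulation kernel."""
    st, g, b = ind.structural, ind.geometry, ind.binding
    return np.array([
        st.cl, g.v_c, st.q, st.v_p, st.km, st.vmax,
        b.kd, b.bmax, b.ns_alb, b.kr, g.v_delta, st.f,
    ])


def apply_residual(pred, sigma_exp: float, rng):
    """Exponential residual error: observed = pred * exp(eps), eps~N(0, sigma^2)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pred = np.asarray(pred, dtype=float)
    if np.any(pred <= 0):
        raise ValueError("predictions must be positive for exponential error")
    eps = rng.normal(0.0, sigma_exp, size=pred.shape)
    out = pred * np.exp(eps)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# BLQ handling
# ---------------------------------------------------------------------------

def filter_blq(ds: StudyDataset):
    """Discard observations below their LLOQ (M1 method).

    Returns ``(filtered_dataset, counts)`` where counts maps
    ``'plasma'``/``'dbs'`` to the number of discarded records; subjects whose
    *pre-dose* observation was BLQ keep no anchor for their baseline and are
    handled by baseline estimation downstream.
    """
    df = ds.df.copy()
    obs = (df["EVID"] == 0) & (df["MDV"] == 0)
    blq = obs & (df["DV"] < df["LLOQ"])
    counts = {
        "plasma": int((blq & (df["DVID"] == DVID_PLASMA)).sum()),
        "dbs": int((blq & (df["DVID"] == DVID_DBS)).sum()),
    }
    return StudyDataset(df[~blq].reset_index(drop=True)), counts


# ---------------------------------------------------------------------------
# Laplace likelihood
# ---------------------------------------------------------------------------

@dataclass
class _Subject:
    sid: object
    cov: Covariates
    dose_nmol: float
    times: np.ndarray          # observation times (likelihood records only)
    dvid: np.ndarray
    logy: np.ndarray
    anchor_pla: Optional[float]   # pre-dose plasma value, if usable
    anchor_dbs: Optional[float]
    sim_times: np.ndarray
    sim_index: np.ndarray      # position of each obs in sim_times


def _prepare_subjects(ds: StudyDataset) -> list[_Subject]:
    subjects = []
    for sid, sub in ds.df.groupby("ID", sort=False):
        doses = sub[sub["EVID"] == 1]
        if len(doses) != 1 or doses["TIME"].iloc[0] != 0.0:
            raise ValueError(
                f"subject {sid}: estimation supports a single dose at t=0"
            )
        cov = Covariates(float(sub["WT"].iloc[0]), AgeGroup(sub["AGEGRP"].iloc[0]))
        obs = sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)].copy()

        anchor_pla = anchor_dbs = None
        if cov.age_group is not AgeGroup.ADULT:
            pre = obs[obs["TIME"] == 0.0]
            for dvid, attr in ((DVID_PLASMA, "anchor_pla"), (DVID_DBS, "anchor_dbs")):
                row = pre[pre["DVID"] == dvid]
                if len(row) and row["DV"].iloc[0] >= row["LLOQ"].iloc[0]:
                    if attr == "anchor_pla":
                        anchor_pla = float(row["DV"].iloc[0])
                    else:
                        anchor_dbs = float(row["DV"].iloc[0])
            # pre-dose observations used as baseline anchors leave the likelihood
            drop = (obs["TIME"] == 0.0) & (
                ((obs["DVID"] == DVID_PLASMA) & (anchor_pla is not None))
                | ((obs["DVID"] == DVID_DBS) & (anchor_dbs is not None))
            )
            obs = obs[~drop]
        if not len(obs):
            continue
        if (obs["DV"] <= 0).any():
            raise ValueError(f"subject {sid}: nonpositive DV in likelihood records")
        times = obs["TIME"].to_numpy(float)
        sim_times = np.unique(times)
        subjects.append(_Subject(
            sid=sid, cov=cov,
            dose_nmol=float(doses["AMT"].iloc[0]),
            times=times,
            dvid=obs["DVID"].to_numpy(int),
            logy=np.log(obs["DV"].to_numpy(float)),
            anchor_pla=anchor_pla, anchor_dbs=anchor_dbs,
            sim_times=sim_times,
            sim_index=np.searchsorted(sim_times, times),
        ))
    return subjects


def _subject_eta_spec(sub: _Subject, pop: PopulationParams,
                      eta_names: Sequence[str]):
    """Names and SDs of this subject's active random effects."""
    names = [n for n in eta_names
             if not (n == "v_delta" and sub.cov.age_group is AgeGroup.ADULT)]
    if sub.cov.age_group is AgeGroup.ADULT:
        names.append("base_adult_pla")
    elif sub.anchor_pla is None or sub.anchor_dbs is None:
        names.append("base_child")
    sds = np.array([pop.omega.get(n, 0.0) for n in names])
    keep = sds > 0
    return [n for n, k in zip(names, keep) if k], sds[keep]


def _subject_predictions(sub: _Subject, pop: PopulationParams,
                         binding: BindingParams, eta: Mapping[str, float],
                         rtol: float) -> np.ndarray:
    """Model predictions (nmol/L) at the subject's likelihood records."""
    th = pop.structural
    s = sub.cov.weight / REF_WEIGHT
    e = lambda n: math.exp(eta.get(n, 0.0))
    adult = sub.cov.age_group is AgeGroup.ADULT
    v_delta = 0.0 if adult else pop.v_delta[sub.cov.age_group] * e("v_delta")
    kr = 0.0 if adult else binding.kr
    p = np.array([
        th.cl * s**ALLOMETRIC_EXP_CL * e("cl"),
        th.v_c * s,
        th.q * s**ALLOMETRIC_EXP_CL,
        th.v_p * s,
        th.km * e("km"),
        th.vmax * e("vmax"),
        binding.kd, binding.bmax, binding.ns_alb, kr,
        v_delta,
        th.f * e("f"),
    ])
    c_pla, c_dbs = fs.simulate_observations(sub.sim_times, sub.dose_nmol, p,
                                            rtol=rtol, atol=rtol * 1e-2)
    if adult:
        base_pla = pop.base_adult_pla * e("base_adult_pla")
        base_dbs = 0.0
    else:
        base_pla = sub.anchor_pla if sub.anchor_pla is not None \
            else pop.base_child_pla * e("base_child")
        base_dbs = sub.anchor_dbs if sub.anchor_dbs is not None \
            else pop.base_child_dbs * e("base_child")
    pred_pla = c_pla[sub.sim_index] + base_pla
    pred_dbs = c_dbs[sub.sim_index] + base_dbs
    return np.where(sub.dvid == DVID_PLASMA, pred_pla, pred_dbs)


def _subject_neg2ll(sub: _Subject, pop: PopulationParams,
                    binding: BindingParams, eta_names: Sequence[str],
                    sigma: float, eta_cache: dict, rtol: float,
                    dual_start: bool = False) -> float:
    names, sds = _subject_eta_spec(sub, pop, eta_names)
    n_obs = sub.logy.size
    const = n_obs * math.log(2.0 * math.pi * sigma * sigma)

    def obs_resid(eta_vec):
        eta = dict(zip(names, eta_vec))
        pred = _subject_predictions(sub, pop, binding, eta, rtol)
        pred = np.maximum(pred, 1e-12)
        return (sub.logy - np.log(pred)) / sigma

    if not names:
        r = obs_resid(np.empty(0))
        if not np.all(np.isfinite(r)):
            warnings.warn(f"subject {sub.sid}: non-finite prediction, penalized")
            return _PENALTY
        return const + float(r @ r)

    d = len(names)

    def resid(eta_vec):
        r = np.concatenate([obs_resid(eta_vec), eta_vec / sds])
        if not np.all(np.isfinite(r)):
            return np.full(n_obs + d, 1e6)
        return r

    x0 = eta_cache.get(sub.sid)
    if x0 is None or x0.size != d:
        x0 = np.zeros(d)
    starts = [x0]
    if dual_start and np.any(x0):
        # the joint eta objective can be multimodal; a second start from the
        # prior mode guards against a stale warm start trapping the subject
        starts.append(np.zeros(d))
    res = None
    for s0 in starts:
        try:
            # diff_step must sit well above the integrator's relative noise
            # (~rtol), otherwise the finite-difference Jacobian is dominated
            # by solver jitter and the inner optimizer stalls on bad modes
            cand = optimize.least_squares(resid, s0, method="lm", diff_step=1e-4,
                                          xtol=1e-10, ftol=1e-10, max_nfev=80 * d)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"subject {sub.sid}: inner optimization failed ({exc})")
            continue
        if res is None or cand.cost < res.cost:
            res = cand
    if res is None:
        return _PENALTY
    eta_hat = res.x
    eta_cache[sub.sid] = eta_hat
    m_hat = 2.0 * res.cost
    if not math.isfinite(m_hat) or m_hat >= 1e12:
        warnings.warn(f"subject {sub.sid}: non-finite objective, penalized")
        return _PENALTY
    H = res.jac.T @ res.jac   # Gauss-Newton Hessian of m/2
    sign, logdet_h = np.linalg.slogdet(H)
    if sign <= 0:
        return _PENALTY
    logdet_omega = 2.0 * float(np.sum(np.log(sds)))
    return const + logdet_omega + m_hat + logdet_h


def neg2ll(pop: PopulationParams, ds: StudyDataset,
           eta_names: Sequence[str] = DEFAULT_ETA_NAMES,
           eta_cache: Optional[dict] = None,
           subjects: Optional[list] = None,
           rtol: float = 1e-6,
           dual_start: bool = False) -> float:
    """-2 log marginal likelihood (Laplace approximation).

    Deterministic given data and the warm-start cache; subjects with
    non-finite predictions contribute a large penalty instead of NaN.
    ``dual_start`` additionally restarts each inner optimization from the
    prior mode (slower, smoother; used for final values and curvature).
    """
    if subjects is None:
        subjects = _prepare_subjects(ds)
    if eta_cache is None:
        eta_cache = {}
    binding = _resolve_binding(pop)
    sigma = pop.sigma_exp
    return float(sum(
        _subject_neg2ll(s, pop, binding, eta_names, sigma, eta_cache, rtol,
                        dual_start)
        for s in subjects
    ))


# ---------------------------------------------------------------------------
# Parameter namespace (flat names <-> PopulationParams)
# ---------------------------------------------------------------------------

_STRUCTURAL = {"cl", "v_c", "q", "v_p", "km", "vmax", "f"}
_SCALARS = {"kd", "ns_alb", "bmax", "kr",
            "base_adult_pla", "base_child_pla", "base_child_dbs"}


def get_param(pop: PopulationParams, name: str) -> float:
    if name in _STRUCTURAL:
        return getattr(pop.structural, name)
    if name in _SCALARS:
        v = getattr(pop, name)
        if v is None:
            v = getattr(_resolve_binding(pop), name)
        return v
    if name.startswith("v_delta_"):
        return pop.v_delta[AgeGroup(name[len("v_delta_"):])]
    if name.startswith("omega_"):
        return pop.omega[name[len("omega_"):]]
    if name == "sigma":
        return pop.sigma_exp
    raise KeyError(name)


def set_params(pop: PopulationParams, values: Mapping[str, float]) -> PopulationParams:
    structural = dict()
    updates: dict = {}
    v_delta = dict(pop.v_delta)
    omega = dict(pop.omega)
    sigma = pop.sigma_exp
    for name, val in values.items():
        if name in _STRUCTURAL:
            structural[name] = val
        elif name in _SCALARS:
            updates[name] = val
        elif name.startswith("v_delta_"):
            v_delta[AgeGroup(name[len("v_delta_"):])] = val
        elif name.startswith("omega_"):
            omega[name[len("omega_"):]] = val
        elif name == "sigma":
            sigma = val
        else:
            raise KeyError(name)
    return replace(
        pop,
        structural=replace(pop.structural, **structural) if structural else pop.structural,
        v_delta=v_delta, omega=omega, sigma_exp=sigma, **updates,
    )


# ---------------------------------------------------------------------------
# Fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    pop: PopulationParams
    free: tuple
    estimates: dict
    neg2ll: float
    success: bool
    message: str
    nfev: int
    cov_log: Optional[np.ndarray] = None   # covariance on log-parameter scale
    se_log: Optional[dict] = None
    eta_names: tuple = DEFAULT_ETA_NAMES
    eta_modes: dict = field(default_factory=dict)

    def se(self, name: str) -> float:
        """Approximate SE on the natural scale (delta method)."""
        if self.se_log is None:
            raise ValueError("fit has no covariance")
        return self.estimates[name] * self.se_log[name]


def fit(ds: StudyDataset, init: PopulationParams,
        free: Sequence[str] = DEFAULT_FREE,
        frozen: Iterable[str] = (),
        eta_names: Sequence[str] = DEFAULT_ETA_NAMES,
        maxfev: int = 2000,
        compute_covariance: bool = True,
        rtol: float = 1e-6) -> FitResult:
    """Maximize the Laplace likelihood over the ``free`` parameters (log
    transformed); anything not in ``free`` (or listed in ``frozen``) stays
    at its ``init`` value.  Non-convergence is reported in
    ``FitResult.success/message``, never silently."""
    free = tuple(n for n in free if n not in set(frozen))
    if not free:
        raise ValueError("no free parameters")
    subjects = _prepare_subjects(ds)
    eta_cache: dict = {}
    x0 = np.log([get_param(init, n) for n in free])

    def objective(x, dual=False):
        pop = set_params(init, dict(zip(free, np.exp(x))))
        return neg2ll(pop, ds, eta_names, eta_cache, subjects, rtol,
                      dual_start=dual)

    res = optimize.minimize(objective, x0, method="Powell",
                            options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-5})
    # Powell tends to stall slightly above the valley floor on curved
    # ridges; a short Nelder-Mead polish descends the remaining ~0.5 units
    polish = optimize.minimize(
        objective, res.x, method="Nelder-Mead",
        options={"maxfev": max(40 * len(free), 300), "xatol": 2e-3, "fatol": 1e-3,
                 "initial_simplex": res.x + 0.05 * np.vstack([np.zeros(len(free)),
                                                              np.eye(len(free))])},
    )
    if polish.fun < res.fun:
        res = polish
    x_hat = res.x
    estimates = dict(zip(free, np.exp(x_hat)))
    pop_hat = set_params(init, estimates)
    cov = se = None
    if compute_covariance:
        cov = _numerical_covariance(lambda x: objective(x, dual=True), x_hat)
        if cov is not None:
            se = dict(zip(free, np.sqrt(np.diag(cov))))
    # final pass to refresh EB modes at the estimate
    final = neg2ll(pop_hat, ds, eta_names, eta_cache, subjects, rtol,
                   dual_start=True)
    return FitResult(
        pop=pop_hat, free=free, estimates=estimates, neg2ll=final,
        success=bool(res.success), message=str(res.message), nfev=int(res.nfev),
        cov_log=cov, se_log=se, eta_names=tuple(eta_names),
        eta_modes=dict(eta_cache),
    )


def _numerical_covariance(objective, x_hat, step: float = 0.1):
    """Asymptotic covariance on the log scale from a central-difference
    Hessian of the -2LL surface (cov = 2 * H^-1).

    The step is deliberately wide: the Laplace surface carries small-scale
    roughness from the inner optimizations, so curvature is measured on the
    scale of the SEs themselves.  Non-positive information eigenvalues are
    floored so no proposal direction exceeds SD 1 on the log scale."""
    d = x_hat.size
    H = np.empty((d, d))
    f0 = objective(x_hat)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        ei = np.zeros(d); ei[i] = step
        fp[i] = objective(x_hat + ei)
        fm[i] = objective(x_hat - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step**2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = step
            ej = np.zeros(d); ej[j] = step
            fpp = objective(x_hat + ei + ej)
            fmm = objective(x_hat - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * step**2)
    if not np.all(np.isfinite(H)):
        warnings.warn("non-finite Hessian; covariance unavailable")
        return None
    w, v = np.linalg.eigh(H / 2.0)   # information matrix of the log-likelihood
    if np.any(w <= 0):
        warnings.warn("information matrix not positive definite; "
                      "flooring weak directions at unit log-scale variance")
    w = np.maximum(w, 1.0)   # variance cap 1.0 on the log scale
    return (v / w) @ v.T


# ---------------------------------------------------------------------------
# SIR
# ---------------------------------------------------------------------------

@dataclass
class SirResult:
    table: pd.DataFrame          # index: parameter; median, ci_lo, ci_hi
    ess: float
    samples: np.ndarray          # resampled log-parameter draws
    names: tuple


def sir(fitted: FitResult, ds: StudyDataset, n_samples: int = 1000,
        n_resamples: int = 500, seed: int = 0, inflation: float = 1.0,
        rtol: float = 1e-6) -> SirResult:
    """Sampling importance resampling around a fit.

    Proposal: MVN on the log-parameters centered at the estimate with the
    fit covariance (times ``inflation``^2).  Importance weights combine the
    likelihood ratio exp(-0.5 * d(-2LL)) with the proposal density; the
    resample is drawn without replacement and the CI read off its
    2.5/97.5% quantiles.  A zero proposal covariance collapses the CI onto
    the point estimate.
    """
    if fitted.cov_log is None:
        raise ValueError("SIR needs a fit with a proposal covariance")
    rng = np.random.default_rng(seed)
    names = fitted.free
    x_hat = np.log([fitted.estimates[n] for n in names])
    cov = np.asarray(fitted.cov_log) * inflation**2

    if not np.any(cov):
        samples = np.tile(x_hat, (n_samples, 1))
        logw = np.zeros(n_samples)
    else:
        samples = rng.multivariate_normal(x_hat, cov, size=n_samples,
                                          method="cholesky" if _is_pd(cov) else "svd")
        subjects = _prepare_subjects(ds)
        eta_cache = dict(fitted.eta_modes)
        nll = np.empty(n_samples)
        for i, x in enumerate(samples):
            pop = set_params(fitted.pop, dict(zip(names, np.exp(x))))
            nll[i] = neg2ll(pop, ds, fitted.eta_names, eta_cache, subjects, rtol)
        logq = stats.multivariate_normal.logpdf(samples, mean=x_hat, cov=cov,
                                                allow_singular=True)
        logw = -0.5 * (nll - nll.min()) - logq

    idx, w, ess = _importance_resample(logw, min(n_resamples, n_samples), rng)
    resampled = samples[idx]
    q = np.exp(np.quantile(resampled, [0.5, 0.025, 0.975], axis=0))
    table = pd.DataFrame(
        {"median": q[0], "ci_lo": q[1], "ci_hi": q[2]}, index=list(names)
    )
    return SirResult(table=table, ess=ess, samples=resampled, names=names)


def _importance_resample(logw: np.ndarray, n_resamples: int, rng):
    """Normalize log importance weights and resample without replacement.

    Returns (indices, normalized weights, effective sample size); warns when
    the ESS drops below 5% of the sample count.
    """
    logw = logw - logw.max()
    w = np.exp(logw)
    w /= w.sum()
    n = w.size
    ess = float(1.0 / np.sum(w * w))
    if ess < 0.05 * n:
        warnings.warn(
            f"SIR effective sample size {ess:.1f} < 5% of {n}; "
            "importance weights are degenerate"
        )
    idx = rng.choice(n, size=min(n_resamples, n), replace=False, p=w)
    return idx, w, ess


def _is_pd(a: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(a)
        return True
    except np.linalg.LinAlgError:
        return False


# ---------------------------------------------------------------------------
# Simulation under a design, and VPC
# ---------------------------------------------------------------------------

def simulate_from_design(ds: StudyDataset, pop: PopulationParams, rng,
                         rtol: float = 1e-8):
    """Redraw every subject (same covariates, doses, sampling design) from
    the population model and return ``(dataset, individuals)``; DV values
    carry fresh random effects and residual error, BLQ flags are refreshed."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    df = ds.df.copy()
    individuals: dict = {}
    for sid, sub in df.groupby("ID", sort=False):
        cov = Covariates(float(sub["WT"].iloc[0]), AgeGroup(sub["AGEGRP"].iloc[0]))
        ind = draw_individual(pop, cov, rng)
        individuals[sid] = ind
        doses = sub[sub["EVID"] == 1]
        if len(doses) != 1 or doses["TIME"].iloc[0] != 0.0:
            raise ValueError(f"subject {sid}: design needs a single dose at t=0")
        obs_idx = sub.index[sub["EVID"] == 0]
        times = df.loc[obs_idx, "TIME"].to_numpy(float)
        dvid = df.loc[obs_idx, "DVID"].to_numpy(int)
        sim_times = np.unique(times)
        pos = np.searchsorted(sim_times, times)
        c_pla, c_dbs = fs.simulate_observations(
            sim_times, float(doses["AMT"].iloc[0]), _pvec(ind),
            rtol=rtol, atol=rtol * 1e-2,
        )
        pred = np.where(dvid == DVID_PLASMA,
                        c_pla[pos] + ind.structural.base_pla,
                        c_dbs[pos] + ind.structural.base_dbs)
        dv = apply_residual(np.maximum(pred, 1e-12), pop.sigma_exp, rng)
        df.loc[obs_idx, "DV"] = dv
        df.loc[obs_idx, "BLQ"] = (dv < df.loc[obs_idx, "LLOQ"]).astype(int)
    return StudyDataset(df), individuals


_PCTL = (5.0, 50.0, 95.0)


def vpc(ds: StudyDataset, pop: PopulationParams, n_sim: int = 1000,
        seed: int = 0, bins: Optional[Sequence[float]] = None,
        rtol: float = 1e-6) -> pd.DataFrame:
    """Visual predictive check: ``n_sim`` replicate datasets under the
    design of ``ds``, percentile bands (5/50/95) with 95% CIs per time bin,
    stratified by observation type and age group.

    Returns a tidy frame with one row per (stratum, bin, percentile):
    columns obs (observed percentile), sim_lo/sim_med/sim_hi (band CI).
    Bins with no observations are dropped with a warning.  Same seed,
    same bands.
    """
    rng = np.random.default_rng(seed)
    obs = ds.observations
    obs = obs[obs["MDV"] == 0]
    if bins is None:
        key_time = obs["TIME"].round(6)
    else:
        edges = np.asarray(bins, dtype=float)
        key_time = pd.Series(
            edges[np.clip(np.digitize(obs["TIME"], edges) - 1, 0, len(edges) - 2)],
            index=obs.index,
        )
    strata = pd.DataFrame({
        "DVID": obs["DVID"], "AGEGRP": obs["AGEGRP"], "BIN": key_time,
        "DV": obs["DV"], "BLQ": obs["BLQ"] if "BLQ" in obs else 0,
    })
    above = strata[strata["DV"] >= obs["LLOQ"].to_numpy()]
    groups = list(above.groupby(["DVID", "AGEGRP", "BIN"]).groups.items())
    if not groups:
        warnings.warn("VPC: no usable observations")
        return pd.DataFrame()
    dropped = len(strata.groupby(["DVID", "AGEGRP", "BIN"])) - len(groups)
    if dropped > 0:
        warnings.warn(f"VPC: dropped {dropped} empty bin(s)")

    sim_pct = np.empty((n_sim, len(groups), len(_PCTL)))
    lloq = ds.df["LLOQ"]
    for r in range(n_sim):
        sim_ds, _ = simulate_from_design(ds, pop, rng, rtol=rtol)
        dv = sim_ds.df["DV"]
        for gi, (key, idx) in enumerate(groups):
            vals = dv.loc[idx]
            vals = vals[vals >= lloq.loc[idx]]
            if len(vals):
                sim_pct[r, gi] = np.percentile(vals, _PCTL)
            else:
                sim_pct[r, gi] = np.nan

    rows = []
    for gi, (key, idx) in enumerate(groups):
        dvid, agegrp, b = key
        observed = np.percentile(above.loc[idx, "DV"], _PCTL)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            band = np.nanpercentile(sim_pct[:, gi, :], [2.5, 50.0, 97.5], axis=0)
        for pi, pct in enumerate(_PCTL):
            rows.append({
                "DVID": dvid, "AGEGRP": agegrp, "bin": b, "percentile": pct,
                "n_obs": len(idx), "obs": observed[pi],
                "sim_lo": band[0, pi], "sim_med": band[1, pi],
                "sim_hi": band[2, pi],
            })
    return pd.DataFrame(rows)
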