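"""Maximum-likelihood fitting of DFE models to paired folded spectra.

The likelihood is an independent-Poisson (Poisson random field style) model
over the folded synonymous and non-synonymous class counts, with a shared
per-site mutation rate theta and per-class nuisance multipliers r_i
(r_1 = 1) absorbing demography, structure and orientation distortions; the
r_i multiply both spectra, so the DFE is identified from the syn/nonsyn
contrast only.  Fractional observed counts enter the Poisson kernel as
c log(lambda) - lambda.

Given theta and the DFE parameters, the Poisson MLE of each free r_i is
available in closed form, so the r_i are profiled out analytically and only
theta plus the DFE parameters are optimized numerically (bounded
quasi-Newton with seeded multistarts).  This is exact, not an
approximation, and the profiled parameters still count toward AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .dfe import (
    FAMILY_CLASSES,
    DFEModel,
    GammaExpo,
    GammaZero,
    ScaledBeta,
    expected_folded_sfs,
)
from .sfs import PairedSFS, neutral_folded_expectation

_TINY = 1e-300


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_model` (deterministic given seed)."""

    n_starts: int = 10
    seed: int = 0
    maxiter: int = 400
    tol: float = 1e-8


@dataclass
class FitResult:
    """A fitted DFE with its nuisance vector and information criteria."""

    model: DFEModel
    theta_site: float
    r: np.ndarray
    logL: float
    k: int
    AIC: float
    family: str
    converged: bool = True

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)


def poisson_kernel(obs: np.ndarray, lam: np.ndarray) -> float:
    """Sum of c log(lambda) - lambda, dropping the data-only factorial term.

    Returns -inf when an expected count is (numerically) zero but the
    observation is not.
    """
    lam = np.asarray(lam, dtype=float)
    obs = np.asarray(obs, dtype=float)
    bad = (lam <= 0) & (obs > 0)
    if np.any(bad):
        return -np.inf
    lam = np.clip(lam, _TINY, None)
    terms = np.where(obs > 0, obs * np.log(lam), 0.0) - lam
    return float(terms.sum())


def loglik(data: PairedSFS, model: DFEModel, theta_site: float, r: np.ndarray) -> float:
    """Poisson log-likelihood of the paired spectra under (model, theta, r)."""
    n = data.sample_size
    lam_syn = expected_folded_sfs(None, theta_site, r, n, data.syn.n_sites, neutral=True)
    lam_non = expected_folded_sfs(model, theta_site, r, n, data.nonsyn.n_sites)
    return poisson_kernel(data.syn.counts, lam_syn) + poisson_kernel(
        data.nonsyn.counts, lam_non
    )


def _profile_r(data: PairedSFS, base_syn: np.ndarray, base_non: np.ndarray) -> np.ndarray:
    """Closed-form Poisson MLE of r_2..r_nc (r_1 fixed at 1)."""
    obs = data.syn.counts + data.nonsyn.counts
    base = base_syn + base_non
    r = np.ones_like(base)
    with np.errstate(divide="ignore", invalid="ignore"):
        r[1:] = np.where(base[1:] > 0, obs[1:] / base[1:], 1.0)
    return r


def _profiled_loglik(data: PairedSFS, model: DFEModel, theta: float):
    n = data.sample_size
    base_syn = data.syn.n_sites * theta * neutral_folded_expectation(n)
    base_non = data.nonsyn.n_sites * theta * model.folded_factors(n)
    r = _profile_r(data, base_syn, base_non)
    ll = poisson_kernel(data.syn.counts, r * base_syn) + poisson_kernel(
        data.nonsyn.counts, r * base_non
    )
    return ll, r


# --- per-family transformed parameterizations -------------------------------

def _make_model(family: str, x: np.ndarray) -> tuple[DFEModel, float]:
    theta = np.exp(x[0])
    if family == "GammaZero":
        return GammaZero(-np.exp(x[1]), np.exp(x[2])), theta
    if family == "GammaExpo":
        p = 1.0 / (1.0 + np.exp(-x[3]))
        return GammaExpo(-np.exp(x[1]), np.exp(x[2]), p, np.exp(x[4])), theta
    if family == "ScaledBeta":
        return ScaledBeta(np.exp(x[1]), np.exp(x[2])), theta
    raise ValueError(f"unknown family {family!r}")


_BOUNDS = {
    "GammaZero": [(-25.0, 2.0), (np.log(1e-3), np.log(1e7)), (np.log(0.02), np.log(5.0))],
    "GammaExpo": [
        (-25.0, 2.0),
        (np.log(1e-3), np.log(1e7)),
        (np.log(0.02), np.log(5.0)),
        (-16.0, 4.0),
        (np.log(1e-2), np.log(1e3)),
    ],
    "ScaledBeta": [(-25.0, 2.0), (np.log(0.02), np.log(50.0)), (np.log(0.02), np.log(50.0))],
}


def _theta_moment_estimate(data: PairedSFS) -> float:
    n = data.sample_size
    denom = data.syn.n_sites * neutral_folded_expectation(n).sum()
    return max(data.syn.total_snps / denom, 1e-8)


def _default_start(family: str, data: PairedSFS) -> np.ndarray:
    lt = np.log(_theta_moment_estimate(data))
    if family == "GammaZero":
        return np.array([lt, np.log(300.0), np.log(0.25)])
    if family == "GammaExpo":
        return np.array([lt, np.log(300.0), np.log(0.25), -4.0, np.log(10.0)])
    if family == "ScaledBeta":
        return np.array([lt, np.log(0.2), np.log(2.0)])
    raise ValueError(family)


def model_from_x(family: str, x: np.ndarray) -> tuple[DFEModel, float]:
    """Public hook mapping an optimizer vector to (model, theta)."""
    return _make_model(family, np.asarray(x, dtype=float))


def x_from_model(model: DFEModel, theta: float) -> np.ndarray:
    """Inverse of :func:`model_from_x`, used to warm-start bootstrap refits."""
    lt = np.log(theta)
    if isinstance(model, GammaZero):
        return np.array([lt, np.log(-model.mean_S), np.log(model.shape)])
    if isinstance(model, GammaExpo):
        p = np.clip(model.p_pos, 1e-7, 1 - 1e-7)
        return np.array(
            [lt, np.log(-model.mean_S), np.log(model.shape), np.log(p / (1 - p)),
             np.log(model.mean_S_pos)]
        )
    if isinstance(model, ScaledBeta):
        return np.array([lt, np.log(model.a), np.log(model.b)])
    raise TypeError(type(model))


def fit_model(
    data: PairedSFS,
    family: str,
    opts: FitOptions | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Fit one DFE family to a paired SFS by maximum likelihood.

    Deterministic given ``opts.seed``.  ``x0`` (transformed parameter
    vector) adds a user-supplied start to the multistart set, e.g. the
    parent optimum when refitting bootstrap replicates.
    """
    if family not in FAMILY_CLASSES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILY_CLASSES)}")
    opts = opts or FitOptions()
    bounds = _BOUNDS[family]
    rng = np.random.default_rng(opts.seed)

    def negll(x):
        model, theta = _make_model(family, x)
        ll, _ = _profiled_loglik(data, model, theta)
        return -ll if np.isfinite(ll) else 1e12

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    base = _default_start(family, data)
    if x0 is None or opts.n_starts > 1:
        starts.append(base)
    scale = np.array([0.3] + [1.5] * (len(base) - 1))
    while len(starts) < max(opts.n_starts, 1):
        starts.append(base + rng.normal(0.0, scale))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    any_converged = False
    for s in starts:
        s = np.clip(s, lo, hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                negll, s, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": opts.maxiter, "ftol": opts.tol},
            )
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    model, theta = _make_model(family, best.x)
    ll, r = _profiled_loglik(data, model, theta)
    r = np.clip(r, 1e-12, None)
    nc = data.sample_size // 2
    k = model.n_params + 1 + (nc - 1)
    result = FitResult(
        model=model, theta_site=theta, r=r, logL=ll, k=k, AIC=2.0 * k - 2.0 * ll,
        family=family, converged=bool(any_converged and np.isfinite(ll)),
    )
    if not result.converged:
        warnings.warn(f"{family} fit did not converge cleanly (logL={ll:.3f})")
    return result
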