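"""McDonald-Kreitman estimation of adaptive substitution rates.

Couples a fitted DFE (which predicts the non-adaptive dN/dS, omega_na) with
observed divergence counts: alpha = 1 - omega_na_pred / omega_obs,
omega_a = alpha * omega_obs, omega_na = (1 - alpha) * omega_obs.  Estimates
from the three DFE families are combined by Akaike-weight averaging, and
confidence intervals come from resampling the SFS (multinomial over
frequency classes) and the divergence counts (Poisson).

Two group-level estimators are provided: the pooled estimator (fit on the
equal-weight pooled SFS of the group against the whole-tree dN/dS) and the
averaged estimator (group dN/dS minus the arithmetic mean of species
omega_na).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dfe import predicted_omega_na
from .fit import FitOptions, FitResult, fit_model, x_from_model
from .sfs import FoldedSFS, PairedSFS, pool_sfs, project_paired

DEFAULT_FAMILIES = ("GammaZero", "GammaExpo", "ScaledBeta")


@dataclass(frozen=True)
class DivergenceCounts:
    """Non-synonymous / synonymous substitution counts with site sizes."""

    dN: float
    dS: float
    L_nonsyn_div: float
    L_syn_div: float
    scope: str = "species_branch"  # or "group_tree"
    subset: str = "all"

    def __post_init__(self):
        if self.dN < 0 or self.dS < 0:
            raise ValueError("substitution counts must be non-negative")
        if self.L_nonsyn_div <= 0 or self.L_syn_div <= 0:
            raise ValueError("site counts must be positive")
        if self.scope not in ("species_branch", "group_tree"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def omega_obs(self) -> float:
        if self.dS <= 0:
            raise ZeroDivisionError("dS must be positive to form dN/dS")
        return (self.dN / self.L_nonsyn_div) / (self.dS / self.L_syn_div)


@dataclass
class PerModelEstimate:
    alpha: float
    omega_a: float
    omega_na: float
    logL: float
    AIC: float
    aic_weight: float = float("nan")


@dataclass
class MKEstimate:
    """alpha / omega_a / omega_na, per model and AIC-averaged, with optional CIs."""

    alpha: float
    omega_a: float
    omega_na: float
    omega_obs: float
    per_model: dict[str, PerModelEstimate] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] | None = None


def aic_weights(aics) -> np.ndarray:
    """Akaike weights exp(-dAIC/2) / sum."""
    aics = np.asarray(aics, dtype=float)
    if not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite")
    d = aics - aics.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def estimate_mk(
    fit: FitResult, div: DivergenceCounts, include_positive: bool = False
) -> MKEstimate:
    """Single-model MK estimate from a fitted DFE and divergence counts."""
    omega_obs = div.omega_obs
    omega_na_pred = predicted_omega_na(fit.model, include_positive=include_positive)
    alpha = 1.0 - omega_na_pred / omega_obs
    omega_a = alpha * omega_obs
    omega_na = omega_na_pred
    pm = PerModelEstimate(alpha, omega_a, omega_na, fit.logL, fit.AIC, 1.0)
    return MKEstimate(alpha, omega_a, omega_na, omega_obs, per_model={fit.family: pm})


def model_average(fits_ests: list[tuple[FitResult, MKEstimate]]) -> MKEstimate:
    """Akaike-weight average of per-model alpha, omega_a and omega_na."""
    if not fits_ests:
        raise ValueError("no fits to average")
    aics = [f.AIC for f, _ in fits_ests]
    ws = aic_weights(aics)
    omega_obs = fits_ests[0][1].omega_obs
    per_model = {}
    alpha = omega_a = omega_na = 0.0
    for (f, e), w in zip(fits_ests, ws):
        pm = PerModelEstimate(e.alpha, e.omega_a, e.omega_na, f.logL, f.AIC, float(w))
        per_model[f.family] = pm
        alpha += w * e.alpha
        omega_a += w * e.omega_a
        omega_na += w * e.omega_na
    return MKEstimate(float(alpha), float(omega_a), float(omega_na), omega_obs, per_model)


def mk_analysis(
    data: PairedSFS,
    div: DivergenceCounts,
    families=DEFAULT_FAMILIES,
    opts: FitOptions | None = None,
    include_positive: bool = False,
    warm_starts: dict[str, np.ndarray] | None = None,
) -> tuple[MKEstimate, dict[str, FitResult]]:
    """Fit all requested families, model-average, and return both."""
    fits: dict[str, FitResult] = {}
    pairs = []
    for fam in families:
        x0 = warm_starts.get(fam) if warm_starts else None
        f = fit_model(data, fam, opts, x0=x0)
        fits[fam] = f
        pairs.append((f, estimate_mk(f, div, include_positive)))
    return model_average(pairs), fits


def _resample_pair(data: PairedSFS, rng: np.random.Generator,
                   scheme: str = "snps") -> PairedSFS:
    """Bootstrap the SNPs of a paired SFS.

    ``scheme='snps'`` (default) treats each SNP as carrying a mutation class
    and a frequency category and draws one multinomial over the concatenated
    syn+nonsyn cells with the grand total fixed; this keeps the binomial
    variance of the syn/nonsyn split, which drives omega_na.
    ``scheme='per_spectrum'`` fixes each spectrum's total separately and
    resamples only the frequency categories.
    """
    nc = data.sample_size // 2

    def draw(cells):
        total = int(round(cells.sum()))
        if total <= 0:
            return np.zeros_like(cells)
        return rng.multinomial(total, cells / cells.sum()).astype(float)

    if scheme == "snps":
        out = draw(np.concatenate([data.syn.counts, data.nonsyn.counts]))
        syn_counts, non_counts = out[:nc], out[nc:]
    elif scheme == "per_spectrum":
        syn_counts = draw(data.syn.counts)
        non_counts = draw(data.nonsyn.counts)
    else:
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    return PairedSFS(
        FoldedSFS(data.sample_size, syn_counts, data.syn.n_sites,
                  data.syn.mutation_class, data.syn.subset),
        FoldedSFS(data.sample_size, non_counts, data.nonsyn.n_sites,
                  data.nonsyn.mutation_class, data.nonsyn.subset),
        data.species_id, data.group_id,
    )


def bootstrap_ci(
    data: PairedSFS,
    div: DivergenceCounts,
    families=DEFAULT_FAMILIES,
    B: int = 200,
    seed: int = 0,
    opts: FitOptions | None = None,
    include_positive: bool = False,
    resample_divergence: bool = True,
    resample_scheme: str = "snps",
) -> tuple[MKEstimate, dict[str, np.ndarray]]:
    """Percentile bootstrap CIs for alpha, omega_a and omega_na.

    Each replicate resamples SNPs (one multinomial over all class x
    frequency cells, grand total fixed; see ``resample_scheme``) and the
    substitution counts Poisson-wise, then reruns the full fit -> average
    pipeline, warm-started from the point-estimate optimum (single start).
    Deterministic given ``seed``.
    Replicates whose fits all fail, or with zero resampled dS, are dropped;
    more than 20% drops flags a warning.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    opts = opts or FitOptions()
    point, fits = mk_analysis(data, div, families, opts, include_positive)
    warm = {fam: x_from_model(f.model, f.theta_site) for fam, f in fits.items()}
    rng = np.random.default_rng(seed)
    rep_opts = FitOptions(n_starts=1, seed=opts.seed, maxiter=opts.maxiter, tol=opts.tol)
    draws: dict[str, list[float]] = {"alpha": [], "omega_a": [], "omega_na": []}
    failures = 0
    for _ in range(B):
        rep = _resample_pair(data, rng, resample_scheme)
        if resample_divergence:
            dN = float(rng.poisson(div.dN))
            dS = float(rng.poisson(div.dS))
        else:
            dN, dS = div.dN, div.dS
        if dS <= 0:
            failures += 1
            continue
        rep_div = DivergenceCounts(dN, dS, div.L_nonsyn_div, div.L_syn_div,
                                   div.scope, div.subset)
        try:
            est, _ = mk_analysis(rep, rep_div, families, rep_opts,
                                 include_positive, warm_starts=warm)
        except Exception:
            failures += 1
            continue
        draws["alpha"].append(est.alpha)
        draws["omega_a"].append(est.omega_a)
        draws["omega_na"].append(est.omega_na)
    if failures > 0.2 * B:
        warnings.warn(f"{failures}/{B} bootstrap replicates failed")
    ci = {}
    arrays = {}
    for stat, vals in draws.items():
        arr = np.asarray(vals)
        arrays[stat] = arr
        if len(arr):
            ci[stat] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    point.ci = ci
    return point, arrays


def group_pooled_estimate(
    spectra: list[PairedSFS],
    group_div: DivergenceCounts,
    families=DEFAULT_FAMILIES,
    opts: FitOptions | None = None,
    include_positive: bool = False,
) -> tuple[MKEstimate, dict[str, FitResult]]:
    """Group-level omega_a[P]: pool species SFS, fit, average, contrast with
    the group-tree dN/dS."""
    if group_div.scope != "group_tree":
        raise ValueError("group_pooled_estimate needs group_tree divergence")
    sizes = {sp.sample_size for sp in spectra}
    if len(sizes) > 1:
        m = min(sizes)
        m -= m % 2
        spectra = [project_paired(sp, m) for sp in spectra]
    pooled = pool_sfs(spectra)
    return mk_analysis(pooled, group_div, families, opts, include_positive)


def group_averaged_estimate(
    species_mk: list[MKEstimate], group_div: DivergenceCounts
) -> float:
    """Group-level omega_a[A]: group dN/dS minus the mean species omega_na."""
    if not species_mk:
        raise ValueError("no species estimates")
    mean_na = float(np.mean([e.omega_na for e in species_mk]))
    return group_div.omega_obs - mean_na
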