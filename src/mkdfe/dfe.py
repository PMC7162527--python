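"""Distributions of fitness effects and expected folded site frequency spectra.

The population-genetic kernel is the Wright-Fisher diffusion sojourn density
of a mutation with scaled selection coefficient S = 4 Ne s,

    H(x; S) = (1 - exp(-S (1 - x))) / (x (1 - x) (1 - exp(-S))),

whose expected contribution to frequency class j of an n-sample,

    B(j; n, S) = C(n,j) * Integral_0^1 H(x;S) x^j (1-x)^(n-j) dx,

has the closed form n/(j(n-j)) * (M(j,n,S) - e^S)/(1 - e^S) with M the
confluent hypergeometric (Kummer) function.  Expected folded class counts
under a DFE phi(S) are E[c_i] = L theta r_i Integral phi(S)
[B(i;n,S) + B(n-i;n,S)] / (1 + delta_{i,n-i}) dS; the S-integral is carried
out on a fixed log-spaced grid with exact CDF-difference weights, so the
sojourn matrix depends only on n and is cached.

Three DFE families are provided: a reflected gamma of deleterious effects
(GammaZero), gamma plus an exponential tail of beneficial effects
(GammaExpo), and a Beta distribution rescaled to S in [-25, 25] covering
both weakly deleterious and weakly beneficial mutations (ScaledBeta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.special import betainc, gammainc, hyp1f1

# fixed discretization grids (node positions never depend on parameters)
NEG_GRID_SIZE = 256
NEG_GRID_RANGE = (1e-6, 1e5)  # |S| range of the deleterious grid
POS_GRID_SIZE = 128
POS_GRID_RANGE = (1e-6, 1e4)
BETA_GRID_SIZE = 400
BETA_BOUND = 25.0


def _log_edges(lo: float, hi: float, size: int) -> np.ndarray:
    return np.logspace(math.log10(lo), math.log10(hi), size + 1)


@lru_cache(maxsize=8)
def _neg_grid() -> tuple[np.ndarray, np.ndarray]:
    """(edges, nodes) of the deleterious |S| grid (geometric midpoints)."""
    edges = _log_edges(*NEG_GRID_RANGE, NEG_GRID_SIZE)
    nodes = np.sqrt(edges[:-1] * edges[1:])
    return edges, nodes


@lru_cache(maxsize=8)
def _pos_grid() -> tuple[np.ndarray, np.ndarray]:
    edges = _log_edges(*POS_GRID_RANGE, POS_GRID_SIZE)
    nodes = np.sqrt(edges[:-1] * edges[1:])
    return edges, nodes


@lru_cache(maxsize=8)
def _beta_grid() -> tuple[np.ndarray, np.ndarray]:
    """(u-edges, S-nodes) for the rescaled-Beta support S in [-25, 25]."""
    u_edges = np.linspace(0.0, 1.0, BETA_GRID_SIZE + 1)
    u_nodes = 0.5 * (u_edges[:-1] + u_edges[1:])
    return u_edges, 2.0 * BETA_BOUND * u_nodes - BETA_BOUND


@lru_cache(maxsize=4)
def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def _panel_quadrature(f, edges: np.ndarray, n_nodes: int = 32) -> float:
    """Composite Gauss-Legendre integral of vectorized ``f`` over panels."""
    x0, w0 = _gl_nodes(n_nodes)
    a = edges[:-1][:, None]
    b = edges[1:][:, None]
    x = 0.5 * (b - a) * x0[None, :] + 0.5 * (a + b)
    w = 0.5 * (b - a) * w0[None, :]
    return float(np.sum(f(x.ravel()) * w.ravel()))


def _log_panels(lo: float, hi: float, n: int = 30) -> np.ndarray:
    return np.logspace(math.log10(lo), math.log10(hi), n + 1)


def fixation_ratio(S) -> np.ndarray:
    """Fixation rate relative to neutral, S / (1 - exp(-S)); 1 at S = 0."""
    S = np.asarray(S, dtype=float)
    out = np.empty_like(S)
    small = np.abs(S) < 1e-8
    out[small] = 1.0 + S[small] / 2.0
    with np.errstate(over="ignore", divide="ignore"):
        out[~small] = S[~small] / (-np.expm1(-S[~small]))
    # S very negative: -expm1(-S) overflows; the ratio underflows to 0
    out[np.isinf(out) | np.isnan(out)] = 0.0
    neg_big = S < -700
    out[neg_big] = 0.0
    return out


def sojourn_density(x, S) -> np.ndarray:
    """Diffusion sojourn density H(x; S) for sample frequency x in (0,1).

    Neutral limit 1/x at S = 0; numerically stable for |S| up to 1e5.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("x must lie strictly inside (0, 1)")
    S = float(S)
    if abs(S) < 1e-10:
        return 1.0 / x
    if S < -30.0:
        # (e^{S x} - e^{S}) / (x (1-x)) to leading order; e^S negligible
        return np.exp(S * x) / (x * (1.0 - x))
    with np.errstate(over="ignore"):
        num = np.expm1(-S * (1.0 - x))
        den = np.expm1(-S)
    return num / den / (x * (1.0 - x))


def sojourn_binomial(j, n: int, S) -> np.ndarray:
    """Closed-form B(j; n, S): expected sojourn mass in sample-count class j.

    Vectorized over ``S`` (and over ``j`` if both broadcast).  Equals 1/j at
    S = 0.
    """
    j = np.asarray(j, dtype=float)
    S = np.asarray(S, dtype=float)
    j_b, S_b = np.broadcast_arrays(j, S)
    out = np.empty(j_b.shape, dtype=float)
    base = n / (j_b * (n - j_b))
    near0 = np.abs(S_b) < 1e-8
    out[near0] = 1.0 / j_b[near0]
    neg = (S_b < 0) & ~near0
    if np.any(neg):
        jj, ss = j_b[neg], S_b[neg]
        M = hyp1f1(jj, n, ss)
        eS = np.exp(ss)
        out[neg] = base[neg] * (M - eS) / (1.0 - eS)
    pos = (S_b > 0) & ~near0
    if np.any(pos):
        jj, ss = j_b[pos], S_b[pos]
        # M(j,n,S) e^{-S} = M(n-j, n, -S)  (Kummer transform, overflow-safe)
        Mc = hyp1f1(n - jj, n, -ss)
        out[pos] = base[pos] * (1.0 - Mc) / (-np.expm1(-ss))
    return out


def folded_class_factors(n: int, S) -> np.ndarray:
    """Array over folded classes i=1..floor(n/2) of
    [B(i;n,S) + B(n-i;n,S)] / (1 + delta_{i,n-i}), for scalar S."""
    i = np.arange(1, n // 2 + 1)
    b = sojourn_binomial(i, n, S) + sojourn_binomial(n - i, n, S)
    return b / (1.0 + (i == n - i))


@lru_cache(maxsize=32)
def _sojourn_matrix(n: int, grid: str) -> np.ndarray:
    """Cached matrix F[i-1, g] of folded class factors over grid nodes."""
    if grid == "neg":
        nodes = -_neg_grid()[1]
    elif grid == "pos":
        nodes = _pos_grid()[1]
    elif grid == "beta":
        nodes = _beta_grid()[1]
    else:
        raise ValueError(grid)
    i = np.arange(1, n // 2 + 1)[:, None]
    b = sojourn_binomial(i, n, nodes[None, :]) + sojourn_binomial(n - i, n, nodes[None, :])
    return b / (1.0 + (i == n - i))


# ---------------------------------------------------------------------------
# DFE families


@dataclass(frozen=True)
class GammaZero:
    """Reflected gamma DFE of deleterious effects (no beneficial mass).

    ``mean_S`` is the (negative) mean scaled effect, ``shape`` the gamma
    shape parameter b.
    """

    mean_S: float  # negative
    shape: float

    family = "GammaZero"
    n_params = 2

    def __post_init__(self):
        if not self.mean_S < 0:
            raise ValueError("mean_S must be negative")
        if not self.shape > 0:
            raise ValueError("shape must be positive")

    def _gamma_weights(self) -> np.ndarray:
        edges, _ = _neg_grid()
        scale = -self.mean_S / self.shape
        cdf = gammainc(self.shape, edges / scale)
        w = np.diff(cdf)
        w[0] += cdf[0]  # sub-grid tail ~ neutral; folded into first node
        w[-1] += 1.0 - cdf[-1]
        return w

    def folded_factors(self, n: int) -> np.ndarray:
        return _sojourn_matrix(n, "neg") @ self._gamma_weights()

    def omega_na(self, include_positive: bool = False) -> float:
        # substitute t = scale*u so the measure is the unit-scale gamma; the
        # u^(shape-1) endpoint singularity is handled by an analytic head
        # (fixation ratio ~ 1 - S/2 there) plus log-spaced GL panels
        shape = self.shape
        scale = -self.mean_S / shape
        eps = min(1e-9, 1e-6 / scale)

        def integrand(u):
            return (
                np.exp((shape - 1.0) * np.log(u) - u - math.lgamma(shape))
                * fixation_ratio(-scale * u)
            )

        head = float(gammainc(shape, eps))  # ratio ~ 1 below eps
        return head + _panel_quadrature(integrand, _log_panels(eps, 60.0, 40))


@dataclass(frozen=True)
class GammaExpo:
    """Gamma deleterious DFE plus an exponential tail of beneficial effects.

    ``p_pos`` is the proportion of new non-synonymous mutations that are
    beneficial; their scaled effects are exponential with mean ``mean_S_pos``.
    """

    mean_S: float
    shape: float
    p_pos: float
    mean_S_pos: float

    family = "GammaExpo"
    n_params = 4

    def __post_init__(self):
        if not self.mean_S < 0:
            raise ValueError("mean_S must be negative")
        if not self.shape > 0:
            raise ValueError("shape must be positive")
        if not 0.0 <= self.p_pos <= 1.0:
            raise ValueError("p_pos must be in [0, 1]")
        if not self.mean_S_pos > 0:
            raise ValueError("mean_S_pos must be positive")

    def folded_factors(self, n: int) -> np.ndarray:
        neg = GammaZero(self.mean_S, self.shape).folded_factors(n)
        edges, _ = _pos_grid()
        cdf = -np.expm1(-edges / self.mean_S_pos)
        w = np.diff(cdf)
        w[0] += cdf[0]
        w[-1] += 1.0 - cdf[-1]
        pos = _sojourn_matrix(n, "pos") @ w
        return (1.0 - self.p_pos) * neg + self.p_pos * pos

    def omega_na(self, include_positive: bool = False) -> float:
        val = (1.0 - self.p_pos) * GammaZero(self.mean_S, self.shape).omega_na()
        if include_positive:
            val += self.omega_pos()
        return float(val)

    def omega_pos(self) -> float:
        """Expected dN/dS contribution of the beneficial component."""
        scale = self.mean_S_pos
        eps = min(1e-9, 1e-6 / scale)

        def integrand(u):
            return np.exp(-u) * fixation_ratio(scale * u)

        head = float(-np.expm1(-eps))
        pos = head + _panel_quadrature(integrand, _log_panels(eps, 60.0, 40))
        return float(self.p_pos * pos)


@dataclass(frozen=True)
class ScaledBeta:
    """Beta(a, b) DFE rescaled to scaled effects S in [-25, 25]."""

    a: float
    b: float

    family = "ScaledBeta"
    n_params = 2

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Beta shapes must be positive")

    def _weights(self) -> np.ndarray:
        u_edges, _ = _beta_grid()
        return np.diff(betainc(self.a, self.b, u_edges))

    def folded_factors(self, n: int) -> np.ndarray:
        return _sojourn_matrix(n, "beta") @ self._weights()

    def omega_na(self, include_positive: bool = False) -> float:
        hi = 1.0 if include_positive else 0.5  # u = 0.5 maps to S = 0

        def integrand(u):
            return stats.beta.pdf(u, self.a, self.b) * fixation_ratio(
                2.0 * BETA_BOUND * u - BETA_BOUND
            )

        # endpoint singularities of the Beta density carry an analytic head:
        # the fixation ratio is ~constant over [0, eps] and [1-eps, 1]
        eps = 1e-9
        val = float(betainc(self.a, self.b, eps)) * float(
            fixation_ratio(np.array(-BETA_BOUND))
        )
        val += _panel_quadrature(integrand, _log_panels(eps, 0.5, 25))
        if include_positive:
            upper = np.concatenate([[0.5], 1.0 - _log_panels(eps, 0.5, 25)[::-1]])
            val += _panel_quadrature(integrand, upper)
            val += float(1.0 - betainc(self.a, self.b, 1.0 - eps)) * float(
                fixation_ratio(np.array(BETA_BOUND))
            )
        return val


@dataclass(frozen=True)
class DiscreteDFE:
    """Point-mass DFE on explicit scaled effects; mostly for tests and oracles."""

    s_values: tuple
    weights: tuple

    family = "Discrete"

    def __post_init__(self):
        if len(self.s_values) != len(self.weights):
            raise ValueError("s_values and weights differ in length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def folded_factors(self, n: int) -> np.ndarray:
        out = np.zeros(n // 2)
        for s, w in zip(self.s_values, self.weights):
            out += w * folded_class_factors(n, s)
        return out

    def omega_na(self, include_positive: bool = False) -> float:
        total = 0.0
        for s, w in zip(self.s_values, self.weights):
            if s <= 0 or include_positive:
                total += w * float(fixation_ratio(np.array(s)))
        return total


DFEModel = GammaZero | GammaExpo | ScaledBeta | DiscreteDFE

FAMILY_CLASSES = {
    "GammaZero": GammaZero,
    "GammaExpo": GammaExpo,
    "ScaledBeta": ScaledBeta,
}


def predicted_omega_na(model: DFEModel, include_positive: bool = False) -> float:
    """Expected dN/dS under near-neutrality for a fitted DFE.

    Integrates the relative fixation rate S/(1 - e^-S) over the non-adaptive
    (S <= 0) component of the DFE; with ``include_positive`` fixations driven
    by a fitted weakly beneficial component are counted as non-adaptive too.
    """
    return model.omega_na(include_positive=include_positive)


def expected_folded_sfs(
    model: DFEModel | None,
    theta_site: float,
    r: np.ndarray | None,
    n: int,
    L: float,
    neutral: bool = False,
) -> np.ndarray:
    """Expected folded class counts E[c_i], i = 1..floor(n/2).

    ``neutral=True`` gives the synonymous expectation
    L theta r_i (1/i + 1/(n-i)) / (1 + delta); otherwise the DFE-weighted
    non-synonymous expectation.  ``r`` is the vector of per-class nuisance
    multipliers (r_1 = 1); ``None`` means all ones.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    nc = n // 2
    if r is None:
        r = np.ones(nc)
    r = np.asarray(r, dtype=float)
    if len(r) != nc:
        raise ValueError("nuisance vector has wrong length")
    if neutral:
        i = np.arange(1, nc + 1)
        base = (1.0 / i + 1.0 / (n - i)) / (1.0 + (i == n - i))
    else:
        base = model.folded_factors(n)
    return L * theta_site * r * base
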