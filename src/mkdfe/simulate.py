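"""Individual-based Wright-Fisher simulation of coding sequences.

A desk-scale forward simulator for the demographic-fluctuation control
experiment: a single panmictic diploid population evolving explicit coding
sequences (standard genetic code) under a gamma DFE of deleterious effects,
an optional exponential tail of beneficial effects, semidominance (h = 0.5)
and multiplicative fitness, with per-base crossover recombination and a
stepwise population-size schedule.  Synonymous changes are neutral by codon
classification, so the syn/nonsyn accounting matches the SFS toolkit
exactly.  Polymorphism (sampled folded SFS, pi_s) and divergence
(substitutions accumulated since the end of burn-in, against the burn-in
consensus) are recorded at requested time points.

Populations are meant to be run at reduced size with diffusion-invariant
rescaling (:func:`rescale_parameters` holds 4N*mu, 4N*s, 4N*rec and phase
durations in units of N constant), since absolute sizes only set runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .codon import BASES, translate_codon
from .mk import DivergenceCounts
from .sfs import FoldedSFS, NONSYNONYMOUS, PairedSFS, SYNONYMOUS, compute_pi

_B2I = {b: i for i, b in enumerate(BASES)}

# per-codon-integer lookup tables, built once
_AA = np.empty(64, dtype="<U1")
_OPP = np.zeros((64, 2))  # (L_syn, L_nonsyn) opportunity per codon
_CLASS = np.full((64, 3, 4), -1, dtype=np.int8)  # codon, pos, alt -> 0 syn,1 non,2 stop
for _ci in range(64):
    _codon = BASES[_ci // 16] + BASES[(_ci // 4) % 4] + BASES[_ci % 4]
    _aa = translate_codon(_codon)
    _AA[_ci] = _aa
    for _p in range(3):
        for _a in range(4):
            if BASES[_a] == _codon[_p]:
                continue
            _mut = _codon[:_p] + BASES[_a] + _codon[_p + 1 :]
            _maa = translate_codon(_mut)
            if _aa == "*" or _maa == "*":
                _CLASS[_ci, _p, _a] = 2
            elif _maa == _aa:
                _CLASS[_ci, _p, _a] = 0
                _OPP[_ci, 0] += 1.0 / 3.0
            else:
                _CLASS[_ci, _p, _a] = 1
                _OPP[_ci, 1] += 1.0 / 3.0

SYN, NON, STP = 0, 1, 2


@dataclass(frozen=True)
class DemographySchedule:
    """Cycled stepwise population sizes: phases of (duration, diploid N)."""

    phases: tuple

    def __post_init__(self):
        for dur, N in self.phases:
            if dur < 1 or N < 10:
                raise ValueError("phase durations must be >= 1 and N >= 10")

    @classmethod
    def constant(cls, N: int) -> "DemographySchedule":
        return cls(((1, N),))

    @classmethod
    def fluctuating(cls, N_low: int, N_high: int, period: int,
                    start_high: bool = True) -> "DemographySchedule":
        """Square-wave fluctuation with half-period ``period`` generations."""
        hi = (period, N_high)
        lo = (period, N_low)
        return cls((hi, lo) if start_high else (lo, hi))

    @property
    def cycle_length(self) -> int:
        return sum(d for d, _ in self.phases)

    @property
    def max_N(self) -> int:
        return max(N for _, N in self.phases)

    def size_at(self, gen: int) -> int:
        t = gen % self.cycle_length
        for dur, N in self.phases:
            if t < dur:
                return N
            t -= dur
        raise AssertionError


@dataclass(frozen=True)
class SimConfig:
    """Forward-simulation settings.

    The DFE means are interpreted in scaled units S = 4*ref_N*s when
    ``dfe_units == 'S'`` (the default, with the gamma mean of -740 and shape
    0.14 describing strongly deleterious amino-acid changes) or directly as
    raw selection coefficients when ``dfe_units == 's'`` (the beneficial
    exponential mean of 1e-4 is a raw s).
    """

    n_genes: int = 200
    gene_length: int = 999
    mu: float = 2.2e-9
    rec: float = 1e-7
    ref_N: int = 100_000
    dfe_neg_mean: float = -740.0
    dfe_neg_shape: float = 0.14
    dfe_neg_units: str = "S"
    dfe_pos_mean: float = 1e-4
    dfe_pos_units: str = "s"
    p_pos: float = 0.02
    stop_s: float = -0.9
    # spaced 2*ref_N generations so pi_s decorrelates between samples
    sample_times: tuple = (200_000, 400_000, 600_000, 800_000, 1_000_000)
    sample_n: int = 20
    burn_in_factor: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.gene_length % 3:
            raise ValueError("gene_length must be divisible by 3")
        if not (0 <= self.mu < 1 and 0 <= self.rec < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.dfe_neg_units not in ("S", "s") or self.dfe_pos_units not in ("S", "s"):
            raise ValueError("dfe units must be 'S' or 's'")

    @property
    def L(self) -> int:
        return self.n_genes * self.gene_length

    def neg_mean_s(self) -> float:
        m = abs(self.dfe_neg_mean)
        return m / (4.0 * self.ref_N) if self.dfe_neg_units == "S" else m

    def pos_mean_s(self) -> float:
        m = self.dfe_pos_mean
        return m / (4.0 * self.ref_N) if self.dfe_pos_units == "S" else m


def rescale_parameters(config: SimConfig, target_N: int) -> SimConfig:
    """Diffusion-invariant rescaling of a configuration to population size target_N.

    Holds 4N*mu, 4N*rec, 4N*s and durations measured in units of N constant.
    Scaled-unit ('S') DFE parameters are left untouched (they are already
    size-free); raw-s parameters are multiplied by ref_N/target_N.  Sample
    times scale with N.
    """
    if target_N < 50:
        raise ValueError("target_N must be >= 50")
    f = config.ref_N / target_N
    mu = config.mu * f
    if mu >= 1:
        raise ValueError("rescaled per-site mutation rate would reach 1")
    changes = dict(
        mu=mu,
        rec=config.rec * f,
        ref_N=target_N,
        sample_times=tuple(max(0, round(t / f)) for t in config.sample_times),
    )
    if config.dfe_neg_units == "s":
        changes["dfe_neg_mean"] = config.dfe_neg_mean * f
    if config.dfe_pos_units == "s":
        changes["dfe_pos_mean"] = config.dfe_pos_mean * f
    return replace(config, **changes)


def rescale_schedule(demog: DemographySchedule, factor: float) -> DemographySchedule:
    """Scale phase sizes by 1/factor and durations by 1/factor."""
    return DemographySchedule(
        tuple((max(1, round(d / factor)), max(10, round(N / factor))) for d, N in demog.phases)
    )


@dataclass
class TimePoint:
    generation: int
    N: int
    pair: PairedSFS
    div: DivergenceCounts
    pi_s: float


@dataclass
class SimOutput:
    config: SimConfig
    demog: DemographySchedule
    timepoints: list[TimePoint]
    n_substitutions: tuple  # (dS, dN) at end


class _Population:
    """Mutable simulation state: reference sequence + segregating mutations."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        n_codons = config.L // 3
        sense = np.flatnonzero(_AA != "*")
        self.ref_codons = rng.choice(sense, size=n_codons)
        self.positions = np.empty(0, dtype=np.int64)
        self._pos_set: set[int] = set()
        self.alts = np.empty(0, dtype=np.int8)
        self.sel = np.empty(0, dtype=float)
        self.klass = np.empty(0, dtype=np.int8)
        self.G = np.zeros((0, 0), dtype=bool)
        self.fixed_syn = 0
        self.fixed_non = 0

    # -- bookkeeping -------------------------------------------------------
    def site_counts(self) -> tuple[float, float]:
        opp = _OPP[self.ref_codons]
        return float(opp[:, 0].sum()), float(opp[:, 1].sum())

    def _classify(self, pos: int, alt: int) -> int:
        ci = pos // 3
        return int(_CLASS[self.ref_codons[ci], pos % 3, alt])

    def _ref_base(self, pos: int) -> int:
        codon = int(self.ref_codons[pos // 3])
        return (codon >> (2 * (2 - pos % 3))) & 3 if False else [codon // 16, (codon // 4) % 4, codon % 4][pos % 3]

    def _apply_fixation(self, pos: int, alt: int):
        ci, within = pos // 3, pos % 3
        digits = [self.ref_codons[ci] // 16, (self.ref_codons[ci] // 4) % 4,
                  self.ref_codons[ci] % 4]
        digits[within] = alt
        self.ref_codons[ci] = digits[0] * 16 + digits[1] * 4 + digits[2]

    # -- one generation ----------------------------------------------------
    def step(self, N_next: int):
        cfg, rng = self.cfg, self.rng
        n_hap, K = self.G.shape
        if n_hap == 0:
            self.G = np.zeros((2 * N_next, 0), dtype=bool)
            n_hap = 2 * N_next
        N_cur = n_hap // 2
        selected = np.flatnonzero(self.sel != 0.0) if K else np.empty(0, dtype=int)
        if len(selected):
            sub = self.G[:, selected]
            A = sub[0::2]
            Bh = sub[1::2]
            # selection coefficients are additive (heterozygous) effects so
            # that S = 4 N s matches the diffusion scaling of the DFE models;
            # semidominance makes the homozygote effect 2s (clipped above -1)
            s_sel = self.sel[selected]
            het = (A ^ Bh).astype(float)
            hom = (A & Bh).astype(float)
            logw = het @ np.log1p(np.maximum(s_sel, -0.95)) + hom @ np.log1p(
                np.maximum(2.0 * s_sel, -0.95))
            logw -= logw.max()
            w = np.exp(logw)
            p = w / w.sum()
        else:
            p = np.full(N_cur, 1.0 / N_cur)
        mothers = rng.choice(N_cur, size=N_next, p=p)
        fathers = rng.choice(N_cur, size=N_next, p=p)
        parents = np.empty(2 * N_next, dtype=np.int64)
        parents[0::2] = mothers
        parents[1::2] = fathers
        hap_choice = rng.integers(0, 2, size=2 * N_next)
        newG = self.G[2 * parents + hap_choice]
        if K:
            R = cfg.rec * cfg.L
            n_x = rng.poisson(R, size=2 * N_next)
            xg = np.flatnonzero(n_x)
            if len(xg):
                order = np.argsort(self.positions)
                pos_sorted = self.positions[order]
                # flip parity at each breakpoint; cumulative xor gives the
                # source haplotype of every column, vectorized over gametes
                delta = np.zeros((len(xg), K + 1), dtype=np.int16)
                rows = np.repeat(np.arange(len(xg)), n_x[xg])
                breaks = rng.integers(0, cfg.L, size=int(n_x[xg].sum()))
                idx = np.searchsorted(pos_sorted, breaks, side="right")
                np.add.at(delta, (rows, idx), 1)
                delta &= 1
                side_sorted = np.logical_xor.accumulate(delta[:, :K].astype(bool), axis=1)
                side = np.empty_like(side_sorted)
                side[:, order] = side_sorted
                hapB = self.G[2 * parents[xg] + 1 - hap_choice[xg]]
                newG[xg] = np.where(side == 1, hapB, newG[xg])
        self.G = newG
        self._mutate(2 * N_next)
        self._fix_and_lose(2 * N_next)

    def _mutate(self, n_hap: int):
        cfg, rng = self.cfg, self.rng
        n_mut = rng.poisson(n_hap * cfg.mu * cfg.L)
        if n_mut == 0:
            return
        pos = rng.integers(0, cfg.L, size=n_mut)
        existing = self._pos_set
        new_cols = []
        meta = []
        for pm in pos:
            pm = int(pm)
            if pm in existing:
                continue  # infinite-sites collision: skip
            existing.add(pm)
            ref = self._ref_base(pm)
            alt = int((ref + rng.integers(1, 4)) % 4)
            klass = self._classify(pm, alt)
            if klass == SYN:
                s = 0.0
            elif klass == STP:
                s = cfg.stop_s
            else:
                if rng.random() < cfg.p_pos:
                    s = rng.exponential(cfg.pos_mean_s())
                else:
                    s = -rng.gamma(cfg.dfe_neg_shape,
                                   cfg.neg_mean_s() / cfg.dfe_neg_shape)
            col = np.zeros(n_hap, dtype=bool)
            col[rng.integers(0, n_hap)] = True
            new_cols.append(col)
            meta.append((pm, alt, s, klass))
        if not new_cols:
            return
        block = np.stack(new_cols, axis=1)
        self.G = np.concatenate([self.G, block], axis=1) if self.G.shape[1] else block
        self.positions = np.concatenate([self.positions, [m[0] for m in meta]])
        self.alts = np.concatenate([self.alts, np.array([m[1] for m in meta], dtype=np.int8)])
        self.sel = np.concatenate([self.sel, [m[2] for m in meta]])
        self.klass = np.concatenate([self.klass, np.array([m[3] for m in meta], dtype=np.int8)])

    def _fix_and_lose(self, n_hap: int, record: bool = True):
        if self.G.shape[1] == 0:
            return
        counts = self.G.sum(axis=0)
        fixed = counts == n_hap
        lost = counts == 0
        if np.any(fixed):
            for idx in np.flatnonzero(fixed):
                if record:
                    if self.klass[idx] == SYN:
                        self.fixed_syn += 1
                    elif self.klass[idx] == NON:
                        self.fixed_non += 1
                self._apply_fixation(int(self.positions[idx]), int(self.alts[idx]))
        keep = ~(fixed | lost)
        if not np.all(keep):
            self._pos_set.difference_update(self.positions[~keep].tolist())
            self.G = self.G[:, keep]
            self.positions = self.positions[keep]
            self.alts = self.alts[keep]
            self.sel = self.sel[keep]
            self.klass = self.klass[keep]

    # -- observation -------------------------------------------------------
    def sample(self, sample_n: int, subset_rows: np.ndarray | None = None):
        rng = self.rng
        n_hap = self.G.shape[0]
        ind = rng.choice(n_hap // 2, size=min(sample_n, n_hap // 2), replace=False)
        rows = np.concatenate([2 * ind, 2 * ind + 1])
        m = len(rows)
        counts = self.G[rows].sum(axis=0) if self.G.shape[1] else np.empty(0, dtype=int)
        minor = np.minimum(counts, m - counts)
        L_syn, L_non = self.site_counts()
        syn_sfs = np.zeros(m // 2)
        non_sfs = np.zeros(m // 2)
        for k, kl in zip(minor, self.klass):
            if k == 0 or kl == STP:
                continue
            if kl == SYN:
                syn_sfs[k - 1] += 1
            else:
                non_sfs[k - 1] += 1
        return PairedSFS(
            FoldedSFS(m, syn_sfs, L_syn, SYNONYMOUS),
            FoldedSFS(m, non_sfs, L_non, NONSYNONYMOUS),
            species_id="sim",
        )


def simulate(config: SimConfig, demog: DemographySchedule) -> SimOutput:
    """Run the Wright-Fisher simulation; deterministic given ``config.seed``.

    Burn-in lasts ``burn_in_factor * max(N)`` generations; substitutions are
    recorded only afterwards, so divergence at each sample time is measured
    against the post-burn-in consensus.  ``sample_times`` are generations
    after burn-in.
    """
    rng = np.random.default_rng(config.seed)
    pop = _Population(config, rng)
    burn_in = config.burn_in_factor * demog.max_N
    horizon = burn_in + max(config.sample_times)
    sample_at = {burn_in + t for t in config.sample_times}
    # initialize population at the first phase size
    N0 = demog.size_at(0)
    pop.G = np.zeros((2 * N0, 0), dtype=bool)
    timepoints = []
    for gen in range(1, horizon + 1):
        N_next = demog.size_at(gen)
        pop.step(N_next)
        if gen == burn_in:
            pop.fixed_syn = 0
            pop.fixed_non = 0
        if gen in sample_at:
            pair = pop.sample(config.sample_n)
            L_syn, L_non = pop.site_counts()
            div = DivergenceCounts(
                dN=float(pop.fixed_non), dS=float(pop.fixed_syn),
                L_nonsyn_div=L_non, L_syn_div=L_syn,
            )
            timepoints.append(
                TimePoint(gen - burn_in, N_next, pair, div, compute_pi(pair.syn))
            )
    return SimOutput(config, demog, timepoints, (pop.fixed_syn, pop.fixed_non))


def mk_on_simulation(
    out: SimOutput,
    families=("GammaZero",),
    opts=None,
    min_ds: float = 10.0,
):
    """Per-timepoint (pi_s, omega_a) and the regression of omega_a on pi_s.

    Runs the DFE/MK estimator at every sampled time point (dropping points
    with fewer than ``min_ds`` synonymous substitutions or failed fits) and
    regresses omega_a on pi_s across the surviving points.  Returns
    (records, ols_result_or_None, n_dropped).
    """
    from .comparative import ols_regression
    from .mk import mk_analysis

    records = []
    dropped = 0
    for tp in out.timepoints:
        if tp.div.dS < min_ds or tp.pair.syn.total_snps <= 0:
            dropped += 1
            continue
        try:
            est, _ = mk_analysis(tp.pair, tp.div, families, opts)
        except Exception:
            dropped += 1
            continue
        records.append({"generation": tp.generation, "N": tp.N, "pi_s": tp.pi_s,
                        "omega_a": est.omega_a, "omega_na": est.omega_na,
                        "alpha": est.alpha, "omega_obs": est.omega_obs})
    reg = None
    if len(records) >= 3:
        x = [r["pi_s"] for r in records]
        y = [r["omega_a"] for r in records]
        try:
            reg = ols_regression(x, y)
        except ValueError:
            reg = None
    return records, reg, dropped
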