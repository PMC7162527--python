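"""Folded site frequency spectra: containers, projection, diversity statistics, pooling.

The folded SFS indexes SNPs by minor-allele count i = 1..floor(n/2) in a
sample of n chromosomes.  Counts may be fractional: uneven coverage across
individuals is handled by hypergeometric projection of each SNP down to a
common sample size, which distributes each SNP's unit mass across frequency
classes deterministically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
SUBSETS = ("all", "gc_conservative")


@dataclass
class FoldedSFS:
    """A folded site frequency spectrum with its mutational-opportunity size.

    Attributes
    ----------
    sample_size : number of chromosomes n (>= 2).
    counts : array of length floor(n/2); counts[i-1] is the (possibly
        fractional) number of SNPs at minor-allele count i.
    n_sites : mutational-opportunity length L (> 0).
    mutation_class : 'synonymous' or 'nonsynonymous'.
    subset : 'all' or 'gc_conservative'.
    """

    sample_size: int
    counts: np.ndarray
    n_sites: float
    mutation_class: str = SYNONYMOUS
    subset: str = "all"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.sample_size
        if n < 2:
            raise ValueError("sample_size must be >= 2")
        if len(self.counts) != n // 2:
            raise ValueError(
                f"counts has length {len(self.counts)}, expected floor(n/2) = {n // 2}"
            )
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")
        if not self.n_sites > 0:
            raise ValueError("n_sites must be positive")
        if self.mutation_class not in (SYNONYMOUS, NONSYNONYMOUS):
            raise ValueError(f"unknown mutation_class {self.mutation_class!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")

    @property
    def n_classes(self) -> int:
        return self.sample_size // 2

    @property
    def total_snps(self) -> float:
        return float(self.counts.sum())


@dataclass
class PairedSFS:
    """Synonymous + non-synonymous folded spectra for one species (or pool)."""

    syn: FoldedSFS
    nonsyn: FoldedSFS
    species_id: str = ""
    group_id: str = ""

    def __post_init__(self):
        if self.syn.sample_size != self.nonsyn.sample_size:
            raise ValueError("syn and nonsyn sample sizes differ")
        if self.syn.mutation_class != SYNONYMOUS or self.nonsyn.mutation_class != NONSYNONYMOUS:
            raise ValueError("mutation classes of the two halves are wrong")
        if self.syn.subset != self.nonsyn.subset:
            raise ValueError("syn and nonsyn subsets differ")

    @property
    def sample_size(self) -> int:
        return self.syn.sample_size

    @property
    def subset(self) -> str:
        return self.syn.subset

    @property
    def total_snps(self) -> float:
        return self.syn.total_snps + self.nonsyn.total_snps


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def projection_weights(k: int, c: int, m: int) -> np.ndarray:
    """Hypergeometric projection weights of one SNP to a smaller sample.

    A SNP observed at ``k`` copies among ``c`` called chromosomes contributes
    weight ``C(k,j) C(c-k, m-j) / C(c,m)`` to class ``j`` of a sample of
    ``m`` chromosomes, for j = 0..m.  The weights sum to 1; the mass at
    j = 0 and j = m is monomorphic after projection.
    """
    if not (0 <= k <= c):
        raise ValueError("need 0 <= k <= c")
    if m > c:
        raise ValueError("cannot project up (m > c)")
    j = np.arange(m + 1)
    with np.errstate(invalid="ignore"):
        logw = _log_comb(k, j) + _log_comb(c - k, m - j) - _log_comb(c, m)
    w = np.exp(logw)
    w[(j > k) | (m - j > c - k)] = 0.0
    return w


def _fold_unfolded(unfolded: np.ndarray, m: int) -> np.ndarray:
    """Fold classes j=0..m to minor-count classes 1..floor(m/2), dropping 0 and m."""
    folded = np.zeros(m // 2)
    for j in range(1, m):
        folded[min(j, m - j) - 1] += unfolded[j]
    return folded


def project_snps(ks, cs, m: int) -> np.ndarray:
    """Project SNPs given as (minor count k_i, called chromosomes c_i) to size m.

    Returns folded class counts of length floor(m/2).  SNPs with fewer than m
    called chromosomes are dropped with a warning.  Mass landing in the
    monomorphic classes (0 and m) after projection is dropped.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    ks = np.asarray(ks, dtype=int)
    cs = np.asarray(cs, dtype=int)
    folded = np.zeros(m // 2)
    n_dropped = 0
    for k, c in zip(ks, cs):
        if c < m:
            n_dropped += 1
            continue
        folded += _fold_unfolded(projection_weights(k, c, m), m)
    if n_dropped:
        warnings.warn(f"{n_dropped} SNP(s) with fewer than {m} called chromosomes dropped")
    return folded


def project_sfs(sfs: FoldedSFS, m: int) -> FoldedSFS:
    """Project a folded SFS down to ``m`` chromosomes (hypergeometric expectation).

    With ``m == sample_size`` this is the identity.  Output counts are
    fractional; mass that becomes monomorphic under the smaller sample is
    dropped.
    """
    if m == sfs.sample_size:
        return replace(sfs)
    if m > sfs.sample_size:
        raise ValueError("cannot project to a larger sample size")
    if m < 2:
        raise ValueError("m must be >= 2")
    c = sfs.sample_size
    folded = np.zeros(m // 2)
    for i, count in enumerate(sfs.counts, start=1):
        if count == 0:
            continue
        folded += count * _fold_unfolded(projection_weights(i, c, m), m)
    return FoldedSFS(m, folded, sfs.n_sites, sfs.mutation_class, sfs.subset)


def project_paired(pair: PairedSFS, m: int) -> PairedSFS:
    return PairedSFS(
        project_sfs(pair.syn, m), project_sfs(pair.nonsyn, m), pair.species_id, pair.group_id
    )


def compute_pi(sfs: FoldedSFS) -> float:
    """Per-site nucleotide diversity (mean pairwise difference), unbiased.

    pi = n/(n-1) * sum_i 2 (i/n)(1 - i/n) c_i / L
    """
    n = sfs.sample_size
    if not sfs.n_sites > 0:
        raise ValueError("n_sites must be positive")
    i = np.arange(1, sfs.n_classes + 1)
    per_snp = 2.0 * (i / n) * (1.0 - i / n) * n / (n - 1.0)
    return float((per_snp * sfs.counts).sum() / sfs.n_sites)


def watterson_theta(sfs: FoldedSFS) -> float:
    """Watterson's theta per site, S / (a_n L)."""
    n = sfs.sample_size
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(sfs.total_snps / (a1 * sfs.n_sites))


def tajimas_d(sfs: FoldedSFS) -> float:
    """Tajima's (1989) D from a folded spectrum.

    Returns NaN when there are no segregating sites.  Requires n >= 4.
    """
    n = sfs.sample_size
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    S = sfs.total_snps
    if S <= 0:
        return math.nan
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_total = compute_pi(sfs) * sfs.n_sites
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi_total - S / a1) / math.sqrt(var))


def neutral_folded_expectation(n: int) -> np.ndarray:
    """Unnormalized neutral folded spectrum shape: (1/i + 1/(n-i)) / (1 + [i == n-i])."""
    i = np.arange(1, n // 2 + 1)
    return (1.0 / i + 1.0 / (n - i)) / (1.0 + (i == n - i))


def pool_sfs(spectra: list[PairedSFS], group_id: str = "") -> PairedSFS:
    """Pool species spectra with equal species weights.

    Three-step recipe: (1) divide each species' synonymous and non-synonymous
    class counts by the species' total SNP count (syn + nonsyn); (2) sum the
    normalized spectra across species; (3) rescale so that the pooled total
    SNP count equals the summed total across species.  Pooled site counts are
    the per-species site counts summed.  Species with zero SNPs are excluded
    with a warning.  All spectra must share sample size and subset (project
    first otherwise).
    """
    if not spectra:
        raise ValueError("no spectra to pool")
    kept = []
    for sp in spectra:
        if sp.total_snps <= 0:
            warnings.warn(f"species {sp.species_id!r} has zero SNPs; excluded from pool")
            continue
        kept.append(sp)
    if not kept:
        raise ValueError("all species have zero SNPs")
    n = kept[0].sample_size
    subset = kept[0].subset
    for sp in kept[1:]:
        if sp.sample_size != n:
            raise ValueError("sample sizes differ; project spectra to a common size first")
        if sp.subset != subset:
            raise ValueError("subsets differ between species")
    norm_syn = np.zeros(n // 2)
    norm_non = np.zeros(n // 2)
    grand_total = 0.0
    L_syn = L_non = 0.0
    for sp in kept:
        tot = sp.total_snps
        norm_syn += sp.syn.counts / tot
        norm_non += sp.nonsyn.counts / tot
        grand_total += tot
        L_syn += sp.syn.n_sites
        L_non += sp.nonsyn.n_sites
    scale = grand_total / (norm_syn.sum() + norm_non.sum())
    return PairedSFS(
        FoldedSFS(n, norm_syn * scale, L_syn, SYNONYMOUS, subset),
        FoldedSFS(n, norm_non * scale, L_non, NONSYNONYMOUS, subset),
        species_id="pooled",
        group_id=group_id or kept[0].group_id,
    )


def choose_projection_size(ks, cs, candidates=None) -> int:
    """Pick the projection size m maximizing the total projected SNP count.

    Scans even m up to the maximum number of called chromosomes (SNPs with
    fewer called chromosomes than a candidate m are dropped for that
    candidate, so small m keeps more SNPs but coarsens the spectrum).
    """
    cs = np.asarray(cs, dtype=int)
    ks = np.asarray(ks, dtype=int)
    if len(cs) == 0:
        raise ValueError("no SNPs")
    cmax = int(cs.max())
    if candidates is None:
        candidates = range(2, cmax + 1, 2)
    best_m, best_mass = None, -1.0
    for m in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mass = project_snps(ks, cs, m).sum()
        if mass > best_mass + 1e-12:
            best_m, best_mass = m, mass
    return best_m
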