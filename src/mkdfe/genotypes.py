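"""Diploid genotype tables and the SFS built from them.

A :class:`GenotypeTable` is the minimal representation of called diploid
genotypes at biallelic coding SNPs: per site a codon context (reference
codon and position within it) and per individual the number of alternate
allele copies (0/1/2, -1 for missing).  It stands in for the output of any
upstream genotype caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import codon as codonmod
from .codon import SiteCounts, classify_snp, count_sites
from .sfs import NONSYNONYMOUS, SYNONYMOUS, FoldedSFS, PairedSFS, project_snps

MISSING = -1


@dataclass(frozen=True)
class Site:
    """One biallelic coding SNP with its codon context."""

    contig: str
    position: int  # 1-based within the contig's CDS
    codon: str  # reference codon
    pos_in_codon: int  # 1..3
    ref: str
    alt: str


@dataclass
class GenotypeTable:
    """Diploid genotypes (individuals x sites), values in {0,1,2,MISSING}."""

    sites: list[Site]
    genotypes: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.sites):
            raise ValueError("genotypes must be individuals x sites")
        seen = set()
        for s in self.sites:
            if s.ref not in codonmod.BASES or s.alt not in codonmod.BASES:
                raise ValueError(f"invalid alleles at {s.contig}:{s.position}")
            key = (s.contig, s.position)
            if key in seen:
                raise ValueError(f"duplicate site {key}")
            seen.add(key)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING


def site_context_from_cds(cds_map: dict[str, str], contig: str, position: int) -> tuple[str, int]:
    """Codon context (reference codon, 1-based position in codon) from a CDS map."""
    cds = cds_map[contig]
    idx = position - 1
    ci = idx // 3
    return cds[3 * ci : 3 * ci + 3].upper(), idx % 3 + 1


def total_site_counts(cds_map: dict[str, str], code: int = 1) -> SiteCounts:
    """Summed mutational-opportunity counts over all coding sequences."""
    total = SiteCounts(0.0, 0.0, 0.0, 0.0)
    for seq in cds_map.values():
        total = total + count_sites(seq, code)
    return total


def build_paired_sfs(
    gt: GenotypeTable,
    cds_map: dict[str, str],
    m: int,
    subset: str = "all",
    species_id: str = "",
    group_id: str = "",
    code: int = 1,
) -> PairedSFS:
    """Build folded synonymous/non-synonymous spectra from diploid genotypes.

    Per site the minor-allele count among called chromosomes is projected to
    ``m`` chromosomes by hypergeometric expectation (SNPs with fewer than
    ``m`` called chromosomes are dropped).  Stop-involving changes are
    excluded.  With ``subset='gc_conservative'`` both the SNPs and the site
    counts are restricted to GC-conservative changes.
    """
    if subset not in ("all", "gc_conservative"):
        raise ValueError(f"unknown subset {subset!r}")
    ks_syn, cs_syn, ks_non, cs_non = [], [], [], []
    for j, site in enumerate(gt.sites):
        g = gt.genotypes[:, j]
        called = g != MISSING
        c = 2 * int(called.sum())
        if c == 0:
            continue  # all genotypes missing
        alt_count = int(g[called].sum())
        k = min(alt_count, c - alt_count)
        if k == 0:
            continue  # monomorphic among called individuals
        klass, gc = classify_snp(site.codon, site.pos_in_codon, site.alt, code)
        if klass == codonmod.STOP:
            continue
        if subset == "gc_conservative" and not gc:
            continue
        if klass == codonmod.SYNONYMOUS:
            ks_syn.append(k)
            cs_syn.append(c)
        else:
            ks_non.append(k)
            cs_non.append(c)
    counts = total_site_counts(cds_map, code)
    L_syn, L_non = counts.for_subset(subset)
    syn_counts = project_snps(ks_syn, cs_syn, m) if ks_syn else np.zeros(m // 2)
    non_counts = project_snps(ks_non, cs_non, m) if ks_non else np.zeros(m // 2)
    return PairedSFS(
        FoldedSFS(m, syn_counts, L_syn, SYNONYMOUS, subset),
        FoldedSFS(m, non_counts, L_non, NONSYNONYMOUS, subset),
        species_id=species_id,
        group_id=group_id,
    )


def compute_fis(gt: GenotypeTable) -> float:
    """Inbreeding coefficient F_is = 1 - mean(H_obs)/mean(H_exp).

    Means are taken over polymorphic sites; H_exp carries the small-sample
    factor 2 n_c / (2 n_c - 1) with n_c called individuals at the site.
    Returns NaN when no site is polymorphic.
    """
    h_obs, h_exp = [], []
    for j in range(gt.n_sites):
        g = gt.genotypes[:, j]
        called = g != MISSING
        n_c = int(called.sum())
        if n_c == 0:
            continue
        gv = g[called]
        p = gv.sum() / (2.0 * n_c)
        if p <= 0.0 or p >= 1.0:
            continue
        h_obs.append(np.mean(gv == 1))
        h_exp.append(2.0 * p * (1.0 - p) * (2.0 * n_c) / (2.0 * n_c - 1.0))
    if not h_exp:
        return float("nan")
    return float(1.0 - np.mean(h_obs) / np.mean(h_exp))
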