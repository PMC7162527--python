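"""Model-consistent synthetic data for every pipeline stage.

Generators invert the estimation model: SFS class counts are Poisson draws
around the expected folded spectra of a known DFE (optionally distorted by
a nuisance vector r), divergence counts are Poisson with an injected true
omega_a, genotype matrices are Hardy-Weinberg draws at prescribed allele
frequencies, and species tables carry prescribed within-group slopes of
omega_a on pi_s.  Every generator is deterministic under its seed and
records the ground truth alongside the data.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon import classify_snp, STOP
from .dfe import DFEModel, expected_folded_sfs, predicted_omega_na
from .genotypes import GenotypeTable, MISSING, Site
from .mk import DivergenceCounts
from .sfs import FoldedSFS, NONSYNONYMOUS, PairedSFS, SYNONYMOUS

SENSE_CODONS = None  # populated lazily


@dataclass
class TruthRecord:
    """Ground truth stored alongside a generated dataset."""

    model: DFEModel
    theta_site: float
    omega_a_true: float
    omega_na_true: float
    r_distortion: np.ndarray
    seed: int


def mild_distortion(n_classes: int, amplitude: float = 0.2) -> np.ndarray:
    """Monotone nuisance ramp r_i = 1 + amplitude*(i-1)/(nc-1), r_1 = 1."""
    if n_classes == 1:
        return np.ones(1)
    i = np.arange(n_classes)
    return 1.0 + amplitude * i / (n_classes - 1)


def generate_sfs_dataset(
    model: DFEModel,
    theta: float,
    n: int,
    L_s: float,
    L_n: float,
    omega_a_true: float,
    d_s: float = 0.1,
    r_distortion: np.ndarray | str | None = "mild",
    seed: int = 0,
    subset: str = "all",
    species_id: str = "sim",
    group_id: str = "simgroup",
    scope: str = "species_branch",
    include_positive: bool = False,
) -> tuple[PairedSFS, DivergenceCounts, TruthRecord]:
    """Draw a paired SFS + divergence dataset with known DFE and true omega_a.

    SFS classes are Poisson around ``expected_folded_sfs`` (with
    ``r_distortion`` as the generating nuisance vector; the default is a
    mild +20% monotone ramp).  dS ~ Poisson(L_s d_s) and
    dN ~ Poisson(L_n d_s (omega_na(model) + omega_a_true)).
    """
    if omega_a_true < 0:
        raise ValueError("omega_a_true must be >= 0")
    rng = np.random.default_rng(seed)
    nc = n // 2
    if isinstance(r_distortion, str):
        r = mild_distortion(nc)
    elif r_distortion is None:
        r = np.ones(nc)
    else:
        r = np.asarray(r_distortion, dtype=float)
    lam_syn = expected_folded_sfs(None, theta, r, n, L_s, neutral=True)
    lam_non = expected_folded_sfs(model, theta, r, n, L_n)
    if np.any(lam_syn > 1e12) or np.any(lam_non > 1e12):
        raise OverflowError("expected class counts too large")
    syn = FoldedSFS(n, rng.poisson(lam_syn).astype(float), L_s, SYNONYMOUS, subset)
    non = FoldedSFS(n, rng.poisson(lam_non).astype(float), L_n, NONSYNONYMOUS, subset)
    omega_na_true = predicted_omega_na(model, include_positive=include_positive)
    dS = float(rng.poisson(L_s * d_s))
    dN = float(rng.poisson(L_n * d_s * (omega_na_true + omega_a_true)))
    pair = PairedSFS(syn, non, species_id, group_id)
    div = DivergenceCounts(dN, dS, L_n, L_s, scope, subset)
    truth = TruthRecord(model, theta, omega_a_true, omega_na_true, r, seed)
    return pair, div, truth


def _random_sense_codon(rng: np.random.Generator) -> tuple[str, int, str]:
    """A (codon, pos_in_codon, alt) whose change is not stop-involving."""
    global SENSE_CODONS
    if SENSE_CODONS is None:
        from .codon import BASES, translate_codon

        SENSE_CODONS = [
            a + b + c
            for a in BASES
            for b in BASES
            for c in BASES
            if translate_codon(a + b + c) != "*"
        ]
    from .codon import BASES

    while True:
        codon = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        pos = int(rng.integers(1, 4))
        alts = [b for b in BASES if b != codon[pos - 1]]
        alt = alts[rng.integers(3)]
        if classify_snp(codon, pos, alt)[0] != STOP:
            return codon, pos, alt


def generate_genotype_matrix(
    freqs,
    n_ind: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    contexts: list[tuple[str, int, str]] | None = None,
) -> GenotypeTable:
    """Hardy-Weinberg diploid genotypes at the given alternate-allele frequencies.

    ``contexts`` optionally supplies (codon, pos_in_codon, alt) per site;
    otherwise random non-stop codon contexts are attached.  Missing calls
    are dropped independently at ``missing_rate``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("freqs must lie in (0, 1)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sites = []
    for j, f in enumerate(freqs):
        if contexts is not None:
            codon, pos, alt = contexts[j]
        else:
            codon, pos, alt = _random_sense_codon(rng)
        ref = codon[pos - 1]
        sites.append(Site(f"cds{j}", pos, codon, pos, ref, alt))
    g = rng.binomial(2, freqs[None, :], size=(n_ind, len(freqs))).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return GenotypeTable(sites, g)


TRAITS = ("longevity", "fecundity", "propagule_size", "adult_size", "body_mass")


def generate_species_table(
    groups: int,
    species_per_group: int,
    group_pi_means,
    slopes,
    noise_sd: float = 0.0,
    intercepts=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Multi-group species table with prescribed within-group slopes.

    Per group g, species pi_s is drawn around ``group_pi_means[g]`` and
    omega_a = intercept_g + slope_g * pi_s + N(0, noise_sd).  Life-history
    traits are generated log-linearly in pi_s (negatively for fecundity,
    positively for the others) so that the trait correlations of real
    comparative tables are mimicked.
    """
    if groups < 2 or species_per_group < 3:
        raise ValueError("need >= 2 groups of >= 3 species")
    group_pi_means = np.asarray(group_pi_means, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if len(group_pi_means) != groups or len(slopes) != groups:
        raise ValueError("group_pi_means and slopes must have one entry per group")
    if intercepts is None:
        intercepts = np.full(groups, 0.05)
    rng = np.random.default_rng(seed)
    rows = []
    letters = string.ascii_uppercase
    for g in range(groups):
        for s in range(species_per_group):
            pi = group_pi_means[g] * np.exp(rng.normal(0.0, 0.4))
            omega_a = intercepts[g] + slopes[g] * pi + rng.normal(0.0, noise_sd)
            omega_na = max(0.25 - 5.0 * pi + rng.normal(0.0, noise_sd), 1e-4)
            lp = np.log10(pi)
            rows.append(
                {
                    "species": f"sp_{letters[g % 26]}{s}",
                    "group": f"group_{letters[g % 26]}",
                    "pi_s": pi,
                    "pi_n": pi * 0.15,
                    "omega_a": omega_a,
                    "omega_na": omega_na,
                    "alpha": omega_a / max(omega_a + omega_na, 1e-9),
                    "fis": rng.normal(0.0, 0.05),
                    "tajd": rng.normal(0.0, 0.3),
                    "longevity": 10 ** (-0.8 * lp - 1.5 + rng.normal(0.0, 0.2)),
                    "fecundity": 10 ** (1.2 * lp + 3.0 + rng.normal(0.0, 0.2)),
                    "propagule_size": 10 ** (-0.9 * lp - 3.0 + rng.normal(0.0, 0.2)),
                    "adult_size": 10 ** (-0.5 * lp - 2.0 + rng.normal(0.0, 0.4)),
                    "body_mass": 10 ** (-1.5 * lp - 6.0 + rng.normal(0.0, 0.5)),
                }
            )
    return pd.DataFrame(rows)
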