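"""Codon-level classification of point mutations and mutational-opportunity counting.

Synonymous/non-synonymous opportunity counts follow the classical per-codon
accounting: each of the three possible single-base changes at a position
contributes 1/3 of a site to the synonymous or non-synonymous total; changes
creating a stop codon contribute to neither.  GC-conservative opportunities
(A<->T and C<->G changes, immune to GC-biased gene conversion) are counted
separately: each position has exactly one GC-conservative change, which
contributes one full GC-conservative site to the class of that change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data import CodonTable

BASES = "ACGT"

#: the unique GC-conservative substitution partner of each base
GC_CONSERVATIVE_PARTNER = {"A": "T", "T": "A", "C": "G", "G": "C"}

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP = "stop"


@dataclass(frozen=True)
class SiteCounts:
    """Mutational-opportunity site counts for a coding sequence."""

    L_syn: float
    L_nonsyn: float
    L_syn_gc: float
    L_nonsyn_gc: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(
            self.L_syn + other.L_syn,
            self.L_nonsyn + other.L_nonsyn,
            self.L_syn_gc + other.L_syn_gc,
            self.L_nonsyn_gc + other.L_nonsyn_gc,
        )

    def for_subset(self, subset: str) -> tuple[float, float]:
        """Return (L_syn, L_nonsyn) for ``subset`` in {'all', 'gc_conservative'}."""
        if subset == "all":
            return self.L_syn, self.L_nonsyn
        if subset == "gc_conservative":
            return self.L_syn_gc, self.L_nonsyn_gc
        raise ValueError(f"unknown subset {subset!r}")


def _forward_table(code: int = 1) -> dict:
    table = CodonTable.unambiguous_dna_by_id[code]
    fwd = dict(table.forward_table)
    for stop in table.stop_codons:
        fwd[stop] = "*"
    return fwd


_CODE_CACHE: dict[int, dict] = {}


def translate_codon(codon: str, code: int = 1) -> str:
    """One-letter amino acid for ``codon`` ('*' for stop)."""
    if code not in _CODE_CACHE:
        _CODE_CACHE[code] = _forward_table(code)
    return _CODE_CACHE[code][codon.upper()]


def is_gc_conservative(ref: str, alt: str) -> bool:
    """True iff {ref, alt} is {A,T} or {C,G}."""
    return GC_CONSERVATIVE_PARTNER[ref.upper()] == alt.upper()


def classify_snp(codon: str, pos_in_codon: int, alt: str, code: int = 1) -> tuple[str, bool]:
    """Classify a single-base change within a codon.

    Parameters
    ----------
    codon : reference codon (3-mer).
    pos_in_codon : 1, 2 or 3.
    alt : alternate base, different from the reference base at that position.
    code : NCBI genetic-code id.

    Returns
    -------
    (klass, gc_conservative) where klass is 'synonymous', 'nonsynonymous' or
    'stop' (either allele encodes a stop; excluded downstream).
    """
    codon = codon.upper()
    alt = alt.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if alt not in BASES:
        raise ValueError(f"invalid base {alt!r}")
    if pos_in_codon not in (1, 2, 3):
        raise ValueError("pos_in_codon must be 1..3")
    ref = codon[pos_in_codon - 1]
    if ref == alt:
        raise ValueError("alt equals the reference base")
    mutant = codon[: pos_in_codon - 1] + alt + codon[pos_in_codon:]
    aa_ref = translate_codon(codon, code)
    aa_alt = translate_codon(mutant, code)
    gc = is_gc_conservative(ref, alt)
    if aa_ref == "*" or aa_alt == "*":
        return STOP, gc
    return (SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS), gc


def count_sites(cds: str, code: int = 1) -> SiteCounts:
    """Count synonymous/non-synonymous mutational opportunities of a CDS.

    Codons containing non-ACGT symbols are excluded with a warning; the
    sequence length must be a multiple of three and must not contain internal
    stop codons (a terminal stop codon is tolerated and skipped).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("coding sequence length not divisible by 3")
    l_syn = l_non = l_syn_gc = l_non_gc = 0.0
    n_codons = len(cds) // 3
    for ci in range(n_codons):
        codon = cds[3 * ci : 3 * ci + 3]
        if any(b not in BASES for b in codon):
            warnings.warn(f"codon {ci + 1} contains non-ACGT symbol; excluded")
            continue
        if translate_codon(codon, code) == "*":
            if ci == n_codons - 1:
                continue
            raise ValueError(f"internal stop codon at codon {ci + 1}")
        for pos in (1, 2, 3):
            ref = codon[pos - 1]
            for alt in BASES:
                if alt == ref:
                    continue
                klass, gc = classify_snp(codon, pos, alt, code)
                if klass == SYNONYMOUS:
                    l_syn += 1.0 / 3.0
                    if gc:
                        l_syn_gc += 1.0
                elif klass == NONSYNONYMOUS:
                    l_non += 1.0 / 3.0
                    if gc:
                        l_non_gc += 1.0
    return SiteCounts(l_syn, l_non, l_syn_gc, l_non_gc)
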