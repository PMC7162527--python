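"""File formats: SFS files, divergence and estimate tables, genotypes, FASTA.

The native SFS file is a small tab-separated text format:

    #species<TAB>group<TAB>n<TAB>subset
    SYN<TAB>L<TAB>c_1<TAB>...<TAB>c_{n//2}
    NONSYN<TAB>L<TAB>c_1<TAB>...<TAB>c_{n//2}

Counts and site totals are written with repr-precision so that a
write/read cycle is bit-exact.  Divergence counts, species tables and
estimate reports are plain TSV handled with pandas; species tables may
also be XLSX workbooks (S6-style layouts) via a column-mapping dict.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genotypes import GenotypeTable, MISSING, Site, site_context_from_cds
from .mk import DivergenceCounts, MKEstimate
from .sfs import FoldedSFS, NONSYNONYMOUS, PairedSFS, SYNONYMOUS


def _fmt(x: float) -> str:
    return repr(float(x))


def write_sfs(pair: PairedSFS, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{pair.species_id}\t{pair.group_id}\t{pair.sample_size}\t{pair.subset}\n")
        for tag, half in (("SYN", pair.syn), ("NONSYN", pair.nonsyn)):
            cells = [tag, _fmt(half.n_sites)] + [_fmt(c) for c in half.counts]
            fh.write("\t".join(cells) + "\n")


def read_sfs(path) -> PairedSFS:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing #species header line")
        species, group, n, subset = header[1:].split("\t")
        n = int(n)
        halves = {}
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            tag, L, counts = cells[0], float(cells[1]), [float(c) for c in cells[2:]]
            mclass = SYNONYMOUS if tag == "SYN" else NONSYNONYMOUS
            halves[tag] = FoldedSFS(n, np.array(counts), L, mclass, subset)
    if set(halves) != {"SYN", "NONSYN"}:
        raise ValueError(f"{path}: need one SYN and one NONSYN line")
    return PairedSFS(halves["SYN"], halves["NONSYN"], species, group)


DIV_COLUMNS = ["id", "scope", "subset", "dN", "dS", "L_nonsyn", "L_syn"]


def write_divergence(divs: dict[str, DivergenceCounts], path) -> None:
    rows = [
        {"id": k, "scope": d.scope, "subset": d.subset, "dN": d.dN, "dS": d.dS,
         "L_nonsyn": d.L_nonsyn_div, "L_syn": d.L_syn_div}
        for k, d in divs.items()
    ]
    pd.DataFrame(rows, columns=DIV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_divergence(path) -> dict[str, DivergenceCounts]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[str(row["id"])] = DivergenceCounts(
            dN=float(row["dN"]), dS=float(row["dS"]),
            L_nonsyn_div=float(row["L_nonsyn"]), L_syn_div=float(row["L_syn"]),
            scope=str(row.get("scope", "species_branch")),
            subset=str(row.get("subset", "all")),
        )
    return out


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_genotype_tsv(path, cds_map: dict[str, str]) -> GenotypeTable:
    """Genotype TSV: contig, pos, ref, alt then one 0/1/2/NA column per individual."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    meta = ["contig", "pos", "ref", "alt"]
    ind_cols = [c for c in df.columns if c not in meta]
    sites, columns = [], []
    for _, row in df.iterrows():
        codon, pic = site_context_from_cds(cds_map, row["contig"], int(row["pos"]))
        sites.append(Site(row["contig"], int(row["pos"]), codon, pic,
                          str(row["ref"]).upper(), str(row["alt"]).upper()))
    g = df[ind_cols].to_numpy(dtype=float)
    g = np.where(np.isnan(g), MISSING, g).astype(np.int8).T.copy()
    # transpose: file rows are sites, GenotypeTable rows are individuals
    return GenotypeTable(sites, g)


def read_vcf(path, cds_map: dict[str, str]) -> GenotypeTable:
    """Biallelic SNPs from a VCF whose contigs/positions are CDS coordinates."""
    from cyvcf2 import VCF

    sites, cols = [], []
    for var in VCF(str(path)):
        if not var.is_snp or len(var.ALT) != 1:
            continue
        codon, pic = site_context_from_cds(cds_map, var.CHROM, var.POS)
        sites.append(Site(var.CHROM, var.POS, codon, pic, var.REF.upper(),
                          var.ALT[0].upper()))
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(col.astype(np.int8))
    return GenotypeTable(sites, np.stack(cols, axis=1) if cols else
                         np.zeros((0, 0), dtype=np.int8))


# --- species tables ---------------------------------------------------------

SPECIES_COLUMNS = [
    "species", "group", "pi_s", "pi_n", "omega_a", "omega_na", "alpha",
    "fis", "tajd", "longevity", "fecundity", "propagule_size", "adult_size",
    "body_mass",
]


def read_species_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Species table from TSV/CSV/XLSX; ``column_map`` renames source columns
    (e.g. an S6-style workbook) onto the canonical names."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() != ".csv" else ",")
    if column_map:
        df = df.rename(columns=column_map)
    return df


def write_species_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def estimate_to_row(name: str, est: MKEstimate) -> dict:
    row = {"id": name, "alpha": est.alpha, "omega_a": est.omega_a,
           "omega_na": est.omega_na, "omega_obs": est.omega_obs}
    for fam, pm in est.per_model.items():
        row[f"alpha_{fam}"] = pm.alpha
        row[f"omega_a_{fam}"] = pm.omega_a
        row[f"omega_na_{fam}"] = pm.omega_na
        row[f"logL_{fam}"] = pm.logL
        row[f"AICw_{fam}"] = pm.aic_weight
    if est.ci:
        for stat, (lo, hi) in est.ci.items():
            row[f"{stat}_ci_low"] = lo
            row[f"{stat}_ci_high"] = hi
    return row


def write_estimates(estimates: dict[str, MKEstimate], path) -> None:
    pd.DataFrame([estimate_to_row(k, e) for k, e in estimates.items()]).to_csv(
        path, sep="\t", index=False
    )
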