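"""Readers and writers for the pipeline's file formats.

TSV dialect: tab-separated, header row, UTF-8, '.' for missing values.
Genotypes travel as minimal VCF (GT-only FORMAT; diploid 0/0, 0/1, 1/1 or
haploid 0, 1), trees as rooted newick with branch lengths, simulation truth
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .simulate import COUNT_COLUMNS, CompetitionDesign, SimulationTruth

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_counts",
    "read_counts",
    "write_truth",
    "read_truth",
    "write_vcf",
    "read_vcf",
    "write_newick",
    "read_newick",
]

MISSING = "."


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True, **kwargs)


def write_counts(table: pd.DataFrame, path) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table lacks columns: {missing}")
    write_tsv(table[COUNT_COLUMNS], path)


def read_counts(path) -> pd.DataFrame:
    table = read_tsv(path)
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: count table lacks columns: {missing}")
    if (table.reads < 0).any():
        bad = table.index[table.reads < 0][0]
        raise ValueError(f"{path}: negative read count at line {bad + 2}")
    table["reads"] = table.reads.astype(np.int64)
    table["timepoint"] = table.timepoint.astype(int)
    return table


def write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "true_s": truth.true_s,
        "outlier_barcodes": sorted(truth.outlier_barcodes),
        "outlier_effect": truth.outlier_effect,
        "true_mean_fitness": truth.true_mean_fitness.to_dict(orient="list"),
        "seed": truth.seed,
        "design": truth.design.__dict__ | {"conditions": list(truth.design.conditions)}
        if truth.design
        else None,
    }
    if truth.design is not None:
        payload["design"]["s_range"] = list(truth.design.s_range)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    design = None
    if payload.get("design"):
        d = dict(payload["design"])
        d["conditions"] = tuple(d["conditions"])
        d["s_range"] = tuple(d["s_range"])
        design = CompetitionDesign(**d)
    return SimulationTruth(
        true_s=payload["true_s"],
        outlier_barcodes=set(payload["outlier_barcodes"]),
        outlier_effect=payload["outlier_effect"],
        true_mean_fitness=pd.DataFrame(payload["true_mean_fitness"]),
        seed=payload["seed"],
        design=design,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(G: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """Write a genotype matrix as a minimal VCF.

    ``G`` has variants as rows and strains as columns, values 0/1/2
    (absent/het/hom).  Diploid strains (per ``meta.ploidy``) are written as
    0/0, 0/1, 1/1; haploid strains as 0 or 1.  Variants get synthetic
    positions on a single contig; the variant id is preserved in the ID
    column.
    """
    ploidy = meta.set_index("strain_id")["ploidy"]
    strains = list(G.columns)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chrSim,length={len(G) * 10 + 1000}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(strains),
    ]
    code_dip = {0: "0/0", 1: "0/1", 2: "1/1"}
    code_hap = {0: "0", 1: "1", 2: "1"}
    vals = G.to_numpy()
    hap = np.array([ploidy[s] == 1 for s in strains])
    for i, vid in enumerate(G.index):
        gts = [
            code_hap[int(v)] if h else code_dip[int(v)]
            for v, h in zip(vals[i], hap)
        ]
        lines.append(
            f"chrSim\t{(i + 1) * 10}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a variant × strain matrix with values 0/1/2.

    Handles mixed haploid (0, 1) and diploid (0/0, 0/1, 1/1, phased or not)
    GT fields.  Haploid carriers are coded 2 (present, non-heterozygous).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        gts = var.genotypes  # [allele1, allele2, phased] or [allele, phased]
        codes = []
        for g in gts:
            alleles = [a for a in g[:-1] if a != -1]
            if not alleles:
                codes.append(0)
            elif len(alleles) == 1:
                codes.append(2 if alleles[0] > 0 else 0)
            else:
                n_alt = sum(1 for a in alleles if a > 0)
                codes.append({0: 0, 1: 1, 2: 2}[n_alt])
        rows.append(codes)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    vcf.close()
    return pd.DataFrame(rows, index=ids, columns=strains, dtype=np.int8)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=False)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", rooting="default-rooted")
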