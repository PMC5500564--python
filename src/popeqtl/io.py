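"""Readers/writers for the pipeline's tabular formats (TSV, VCF 4.2, GMT)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from popeqtl.simulate import GenotypeMatrix


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"stage": str, "subtype": str, "population": str})


def write_eqtls(eqtls: pd.DataFrame, path) -> None:
    eqtls.to_csv(path, sep="\t", index=False)


def read_eqtls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_frequency_table(freqs: pd.DataFrame, path) -> None:
    """Long-format frequency TSV: snp_id, chrom, pos, population, alt_freq."""
    pops = [c for c in freqs.columns if c not in ("chrom", "pos")]
    long = freqs.reset_index().melt(
        id_vars=["snp_id", "chrom", "pos"], value_vars=pops, var_name="population", value_name="alt_freq"
    )
    long.sort_values(["snp_id", "population"]).to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> pd.DataFrame:
    """Read the long-format frequency TSV back to wide (snp_id x population)."""
    long = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    wide = long.pivot_table(index="snp_id", columns="population", values="alt_freq", sort=False)
    pos = long.drop_duplicates("snp_id").set_index("snp_id")[["chrom", "pos"]]
    out = pos.join(wide)
    out.columns.name = None
    return out[[c for c in out.columns]]


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT fields; missing dosage (-1) -> ./."""
    samples = list(genotypes.dosages.columns)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(genotypes.positions["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        order = genotypes.positions.sort_values(["chrom", "pos"]).index
        for snp in order:
            chrom = genotypes.positions.loc[snp, "chrom"]
            pos = int(genotypes.positions.loc[snp, "pos"])
            gts = "\t".join(gt_map[int(d)] for d in genotypes.dosages.loc[snp, samples])
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (alternate-allele count; ./. -> -1)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dos = np.array([{0: 0, 1: 1, 2: -1, 3: 2}[t] for t in var.gt_types], dtype=np.int64)
        rows.append(dos)
    dmat = pd.DataFrame(np.vstack(rows), index=pd.Index(snp_ids, name="snp_id"), columns=samples)
    positions = pd.DataFrame({"chrom": chroms, "pos": poss}, index=dmat.index)
    return GenotypeMatrix(dosages=dmat, positions=positions)


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path) -> dict:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_pairs(pairs: list, path, header=("id_a", "id_b")) -> None:
    pd.DataFrame(pairs, columns=list(header)).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))
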