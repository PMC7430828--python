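"""Readers and writers for the standard interchange formats.

Pedigree and phenotype tables are plain CSV. Genotypes travel as PLINK-style
.ped/.map text files or as uncompressed VCF 4.2 (biallelic records only; the
VCF reader uses cyvcf2 when available). Dosage is the count of the alternate
(VCF) or second-listed (PLINK) allele; missing calls are preserved.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeSet, Pedigree


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_csv(path)


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.to_csv(path)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["id"] = df["id"].astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PLINK .ped/.map text dialect

_PLINK_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}


def write_plink(genotypes: GenotypeSet, prefix) -> None:
    """Write <prefix>.ped and <prefix>.map; allele A = reference, B = counted."""
    prefix = Path(prefix)
    m = genotypes.snp_map
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in m.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\n")
    dos = genotypes.dosages
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for k, sample in enumerate(genotypes.samples):
            fields = ["FAM", sample, "0", "0", "0", "-9"]
            for g in dos[k]:
                a, b = _PLINK_ALLELES[int(g)]
                fields.extend([a, b])
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix) -> GenotypeSet:
    """Read a .ped/.map pair; dosage counts the second-listed allele."""
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str, "snp": str},
    )[["snp", "chrom", "pos"]]
    n_snps = len(snp_map)
    samples, rows = [], []
    # second-listed allele per SNP = counted allele; determined per SNP from data
    with open(prefix.with_suffix(".ped")) as fh:
        raw = [line.split() for line in fh if line.strip()]
    for fields in raw:
        if len(fields) != 6 + 2 * n_snps:
            raise ValueError(
                f"ped line for {fields[1] if len(fields) > 1 else '?'} has "
                f"{len(fields) - 6} allele fields, map expects {2 * n_snps}"
            )
        samples.append(fields[1])
    alleles = np.array([f[6:] for f in raw], dtype="U8").reshape(len(raw), n_snps, 2)
    dos = np.full((len(raw), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = alleles[:, j, :]
        called = col[col != "0"]
        uniq = sorted(set(called.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"SNP {snp_map['snp'][j]} has more than two alleles")
        counted = uniq[-1] if uniq else "B"  # second-listed (e.g. B over A)
        miss = (col == "0").any(axis=1)
        dos[:, j] = np.where(miss, MISSING, (col == counted).sum(axis=1).astype(np.int8))
    return GenotypeSet(samples=samples, dosages=dos, snp_map=snp_map)


# ---------------------------------------------------------------------------
# VCF 4.2

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeSet, path) -> None:
    """Minimal uncompressed VCF 4.2 with GT-only biallelic records."""
    m = genotypes.snp_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=roegen\n")
        for chrom in m["chrom"].unique():
            maxpos = int(m.loc[m["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples) + "\n"
        )
        dos = genotypes.dosages
        for j, row in m.iterrows():
            gts = "\t".join(_GT_CODE[int(g)] for g in dos[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp']}\tA\tB\t.\t.\t.\tGT\t{gts}\n")


def _read_vcf_text(path) -> GenotypeSet:
    samples, recs, dosage_rows = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            if "," in f[4]:
                warnings.warn(f"skipping multi-allelic record {f[2]} at {f[0]}:{f[1]}")
                continue
            row = []
            for cell in f[9:]:
                gt = cell.split(":")[0].replace("|", "/")
                if "." in gt:
                    row.append(MISSING)
                else:
                    row.append(sum(int(x) for x in gt.split("/")))
            recs.append((f[2], f[0], int(f[1])))
            dosage_rows.append(row)
    snp_map = pd.DataFrame(recs, columns=["snp", "chrom", "pos"])
    dos = np.array(dosage_rows, dtype=np.int8).T if dosage_rows else np.zeros((len(samples), 0), np.int8)
    return GenotypeSet(samples=samples, dosages=dos, snp_map=snp_map)


def read_vcf(path) -> GenotypeSet:
    """Read biallelic GT records from an uncompressed VCF (multi-allelic records
    are skipped with a warning)."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    v = VCF(str(path))
    samples = list(v.samples)
    recs, rows = [], []
    for var in v:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record {var.ID} at {var.CHROM}:{var.POS}")
            continue
        gts = np.array(var.genotypes)[:, :2]
        miss = (gts < 0).any(axis=1)
        d = gts.clip(0).sum(axis=1)
        rows.append(np.where(miss, MISSING, d).astype(np.int8))
        recs.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS))
    snp_map = pd.DataFrame(recs, columns=["snp", "chrom", "pos"])
    dos = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    return GenotypeSet(samples=samples, dosages=dos, snp_map=snp_map)


def read_genotypes(path, fmt: str | None = None) -> GenotypeSet:
    """Dispatch on format: 'plink' (prefix of .ped/.map) or 'vcf'."""
    p = Path(path)
    if fmt is None:
        fmt = "vcf" if p.suffix == ".vcf" else "plink"
    if fmt == "vcf":
        return read_vcf(p)
    if fmt == "plink":
        return read_plink(p.with_suffix("") if p.suffix in (".ped", ".map") else p)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed=None) -> None:
    """TSV with a provenance header comment (config hash + seed)."""
    with open(path, "w") as fh:
        fh.write(f"# roegen config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(obj) -> str:
    import json

    return hashlib.sha1(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]
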