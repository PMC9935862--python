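"""Readers and writers for the pipeline's standard formats.

Supported: GCTA ".ma" summary-statistic TSV (SNP A1 A2 freq b se p N),
proteome run matrices as TSV (rows = runs/samples, cols = features, empty
cell = missing), VCF with GT:DS fields, PLINK bed/bim/fam, TSS annotation
TSV and YAML configs. Positions are 1-based inclusive throughout.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd
import yaml

from .simulate import GenotypeMatrix

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def write_ma(stats: pd.DataFrame, path) -> None:
    """Write AssocStats in the GCTA .ma layout (extra columns are dropped)."""
    out = stats.rename(columns={"snp": "SNP", "a1": "A1", "a2": "A2", "n": "N"})
    out[MA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ma(path) -> pd.DataFrame:
    """Read a .ma file back into the internal AssocStats column names."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing .ma columns {missing}")
    return df.rename(columns={"SNP": "snp", "A1": "a1", "A2": "a2", "N": "n"})


def write_proteome_tsv(values: pd.DataFrame, path) -> None:
    """Runs/samples x features TSV; missing cells written empty."""
    values.to_csv(path, sep="\t", index_label="sample")


def read_proteome_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_replicate_map(replicate_map: dict, path) -> None:
    rows = [(s, r) for s, runs in replicate_map.items() for r in runs]
    pd.DataFrame(rows, columns=["sample", "run"]).to_csv(path, sep="\t", index=False)


def read_replicate_map(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list] = {}
    for _, r in df.iterrows():
        out.setdefault(r["sample"], []).append(r["run"])
    return out


def write_tss_table(tss: pd.DataFrame, path) -> None:
    """TSS annotation: columns (feature, chrom, tss)."""
    tss[["feature", "chrom", "tss"]].to_csv(path, sep="\t", index=False)


def read_tss_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"feature", "chrom", "tss"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: TSS table needs columns {sorted(need)}")
    return df


# ---------------------------------------------------------------------------
# VCF (text, GT:DS)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT (hard calls) and DS (dosage) per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, geno.samples)) + "\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in geno.variants.iterrows():
            ds = geno.dosage[:, j]
            calls = np.clip(np.rint(ds), 0, 2).astype(int)
            cells = [f"{gt_code[int(c)]}:{d:g}" for c, d in zip(calls, ds)]
            # a1 is the counted (ALT) allele; a2 is REF
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['a2']}\t{v['a1']}"
                f"\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read the dialect written by :func:`write_vcf` (DS preferred, GT fallback)."""
    samples, rows, meta = None, [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if samples is None or len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: malformed VCF record")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            ds_i = fmt.index("DS") if "DS" in fmt else None
            gt_i = fmt.index("GT") if "GT" in fmt else None
            vals = []
            for cell in parts[9:]:
                fields = cell.split(":")
                if ds_i is not None:
                    vals.append(float(fields[ds_i]))
                elif gt_i is not None:
                    gt = fields[gt_i].replace("|", "/")
                    vals.append(float(sum(int(a) for a in gt.split("/") if a != ".")))
                else:
                    raise ValueError(f"{path}:{lineno}: no GT or DS field")
            rows.append(vals)
            meta.append((vid, chrom, int(pos), alt, ref))
    dosage = np.array(rows).T
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "a1", "a2"])
    f = dosage.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(f, 1 - f)
    variants["rsq"] = 1.0
    return GenotypeMatrix(list(samples), variants, dosage)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def write_plink(geno: GenotypeMatrix, prefix: str) -> None:
    """Write hard-called genotypes as PLINK bed/bim/fam (SNP-major)."""
    bim = pd.DataFrame(
        {
            "chrom": geno.variants["chrom"],
            "id": geno.variants["id"],
            "cm": 0,
            "pos": geno.variants["pos"].astype(int),
            "a1": geno.variants["a1"],
            "a2": geno.variants["a2"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": geno.samples, "iid": geno.samples, "pat": 0, "mat": 0, "sex": 0, "phen": -9}
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    n = geno.n_samples
    calls = np.clip(np.rint(geno.dosage), 0, 2).astype(int)
    # bed codes (a1 counted): 2 copies -> 00, het -> 10, 0 copies -> 11, missing -> 01
    code = {2: 0b00, 1: 0b10, 0: 0b11}
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(struct.pack("3B", 0x6C, 0x1B, 0x01))
        for j in range(geno.n_variants):
            byts = bytearray()
            for i0 in range(0, n, 4):
                b = 0
                for k, i in enumerate(range(i0, min(i0 + 4, n))):
                    b |= code[int(calls[i, j])] << (2 * k)
                byts.append(b)
            fh.write(bytes(byts))


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK bed/bim/fam into dosages (missing -> NaN)."""
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phen"],
    )
    samples = list(fam["iid"].astype(str))
    n, m = len(samples), len(bim)
    decode = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != bytes([0x6C, 0x1B, 0x01]):
            raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
        nbytes = (n + 3) // 4
        dosage = np.empty((n, m))
        for j in range(m):
            chunk = fh.read(nbytes)
            col = np.empty(n)
            for i in range(n):
                b = chunk[i // 4]
                col[i] = decode[(b >> (2 * (i % 4))) & 0b11]
            dosage[:, j] = col
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    f = np.nanmean(dosage, axis=0) / 2.0
    variants["maf"] = np.minimum(f, 1 - f)
    variants["rsq"] = 1.0
    return GenotypeMatrix(samples, variants, dosage)


# ---------------------------------------------------------------------------
# YAML config


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
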