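"""Readers and writers for the standard file formats.

VCF is read with cyvcf2 and written as plain uncompressed text; PLINK
bed/bim/fam is decoded directly (the bed format is a fixed 2-bit code).
Summary statistics, phenotypes and gene annotation travel as TSV/BED/GFF3,
single-nucleus counts as MatrixMarket + TSV metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .datamodel import (
    GeneAnnotation,
    GenotypeMatrix,
    PhenotypeTable,
    SummaryStats,
    VALID_BASES,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load a genotype file into a :class:`GenotypeMatrix`.

    Dosages are oriented to the ALT allele for VCF and to allele 1 (the bim
    A1 allele) for PLINK.  Non-SNP and multi-allelic records are skipped with
    a count kept in ``.skipped`` on the returned matrix.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    individuals = list(vcf.samples)
    rows, dosage_cols = [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in VALID_BASES or alt not in VALID_BASES:
            skipped += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{ref}:{alt}"
        rows.append((vid, str(rec.CHROM), int(rec.POS), alt, ref))
        dosage_cols.append(dos)
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "effect_allele", "other_allele"])
    dup = variants["id"][variants["id"].duplicated()].tolist()
    if dup:
        raise ParseError(f"duplicate variant IDs in {path}: {dup}")
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(individuals), 0))
    )
    g = GenotypeMatrix(individuals, variants, dosages)
    g.skipped = skipped
    return g


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write hard-called genotypes as an uncompressed VCFv4.2 file."""
    calls = g.hard_calls()
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individuals) + "\n")
        v = g.variants
        for j in range(g.n_variants):
            gts = [gt_map.get(calls[i, j], "./.") for i in range(g.n_individuals)]
            fh.write(
                f"{v['chrom'][j]}\t{v['pos'][j]}\t{v['id'][j]}\t"
                f"{v['other_allele'][j]}\t{v['effect_allele'][j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


_PLINK_CODE = {0: 2.0, 1: np.nan, 2: 1.0, 3: 0.0}  # 2-bit code -> A1 dosage


def _read_plink(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str)
    bim["pos"] = bim["pos"].astype(int)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ParseError(f"{prefix}.bed: bad magic bytes (SNP-major bed required)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * m:
        raise ParseError(f"{prefix}.bed: size mismatch for {n} samples x {m} variants")
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]  # variants x individuals
    lut = np.array([_PLINK_CODE[c] for c in range(4)])
    dosages = lut[codes].T  # individuals x variants, counts A1
    variants = pd.DataFrame({
        "id": bim["id"], "chrom": bim["chrom"], "pos": bim["pos"],
        "effect_allele": bim["a1"], "other_allele": bim["a2"],
    })
    sex_map = {"1": "male", "2": "female"}
    sex = [sex_map.get(s) for s in fam["sex"]]
    if any(s is None for s in sex):
        sex = None
    dup = variants["id"][variants["id"].duplicated()].tolist()
    if dup:
        raise ParseError(f"duplicate variant IDs in {prefix}.bim: {dup}")
    return GenotypeMatrix(fam["iid"].tolist(), variants, dosages, sex=sex)


# ---------------------------------------------------------------------------
# summary statistics / phenotypes / annotation
# ---------------------------------------------------------------------------

def read_summary_stats(path, stratum: str = "all") -> SummaryStats:
    t = pd.read_csv(path, sep="\t")
    return SummaryStats(t, stratum=stratum)


def write_summary_stats(ss: SummaryStats, path) -> None:
    ss.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    t = pd.read_csv(path, sep="\t", index_col=0)
    return PhenotypeTable(t)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, sep="\t", index_label="individual")


def read_gene_annotation(path, format: str | None = None) -> GeneAnnotation:
    """Read gene bodies from BED (0-based half-open; converted) or GFF3/TSV.

    For BED, the union-exon length defaults to the gene-body span unless a
    7th column supplies it.  TSV must already carry the five canonical
    columns.
    """
    path = str(path)
    if format is None:
        format = "bed" if path.endswith(".bed") else ("gff" if path.endswith((".gff", ".gff3")) else "tsv")
    if format == "tsv":
        return GeneAnnotation(pd.read_csv(path, sep="\t"))
    if format == "bed":
        t = pd.read_csv(path, sep="\t", header=None, comment="#")
        out = pd.DataFrame({
            "gene_id": t[3],
            "chrom": t[0].astype(str),
            "start": t[1].astype(int) + 1,  # BED is 0-based half-open
            "end": t[2].astype(int),
        })
        out["length"] = t[6].astype(int) if t.shape[1] > 6 else out["end"] - out["start"] + 1
        return GeneAnnotation(out)
    if format == "gff":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gid = attrs.get("gene_id") or attrs.get("ID")
                rows.append((gid, f[0], int(f[3]), int(f[4])))
        out = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
        out["length"] = out["end"] - out["start"] + 1
        return GeneAnnotation(out)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# single-nucleus counts (MTX bundle)
# ---------------------------------------------------------------------------

def read_umi_bundle(directory):
    """Read ``matrix.mtx`` (genes x nuclei), ``genes.tsv`` and ``barcodes.tsv``.

    Returns ``(counts, gene_ids, nucleus_meta)`` where counts is a dense
    nuclei x genes integer array and nucleus_meta carries ``individual`` and
    ``cell_type`` per nucleus.
    """
    directory = Path(directory)
    mat = mmread(directory / "matrix.mtx")
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(directory / "barcodes.tsv", sep="\t")
    counts = np.asarray(mat.todense()).T  # nuclei x genes
    if counts.shape != (len(meta), len(genes)):
        raise ParseError(
            f"{directory}: matrix {counts.shape} does not match "
            f"{len(meta)} barcodes x {len(genes)} genes"
        )
    return counts, genes, meta


def write_umi_bundle(directory, counts, gene_ids, nucleus_meta) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), csr_matrix(np.asarray(counts).T))
    pd.Series(gene_ids).to_csv(directory / "genes.tsv", sep="\t", index=False, header=False)
    nucleus_meta.to_csv(directory / "barcodes.tsv", sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
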