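"""Core data containers shared by every analysis stage.

Conventions used throughout the package:

* coordinates are 1-based and inclusive (VCF convention); BED input is
  converted on read,
* dosages count copies of the recorded *effect allele* and live in [0, 2],
  with ``nan`` marking a missing genotype,
* variants are keyed by ``(chrom, pos, frozenset{allele pair})`` so that an
  allele swap between two files still identifies the same site; rsIDs are
  carried as labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

#: column order for the per-variant metadata table
VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele"]


def variant_key(chrom: str, pos: int, a1: str, a2: str) -> tuple:
    """Orientation-free key for a biallelic SNP."""
    return (str(chrom), int(pos)) + tuple(sorted((a1, a2)))


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) allele pairs."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with a recorded effect (counted) allele."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None = None

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele identical")
        if self.pos < 1:
            raise ValueError(f"{self.id}: pos must be >= 1, got {self.pos}")
        for a in (self.effect_allele, self.other_allele):
            if a not in VALID_BASES:
                raise ValueError(f"{self.id}: non-SNP allele {a!r}")

    @property
    def key(self) -> tuple:
        return variant_key(self.chrom, self.pos, self.effect_allele, self.other_allele)


class GenotypeMatrix:
    """Individuals x variants effect-allele dosage matrix.

    Parameters
    ----------
    individuals : sequence of str
        Unique sample IDs (rows).
    variants : pandas.DataFrame
        One row per variant with columns ``id, chrom, pos, effect_allele,
        other_allele`` (order preserved; columns beyond these are carried
        through untouched).
    dosages : ndarray, shape (n_individuals, n_variants)
        Effect-allele dosages in [0, 2]; ``nan`` = missing.
    sex : sequence of {"male", "female"}, optional
    population_label : sequence of str, optional
    """

    def __init__(
        self,
        individuals: Sequence[str],
        variants: pd.DataFrame,
        dosages: np.ndarray,
        sex: Sequence[str] | None = None,
        population_label: Sequence[str] | None = None,
    ):
        individuals = list(individuals)
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual IDs")
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(individuals), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(individuals)} individuals x {len(variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(dosages, initial=0.0) < 0 or np.nanmax(dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2] or be nan")
        dup = variants["id"][variants["id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate variant IDs: {dup}")
        self.individuals = individuals
        self.variants = variants.reset_index(drop=True)
        self.dosages = dosages
        self.sex = None if sex is None else np.asarray(sex, dtype=object)
        self.population_label = (
            None if population_label is None else np.asarray(population_label, dtype=object)
        )

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[tuple]:
        v = self.variants
        return [
            variant_key(c, p, a, b)
            for c, p, a, b in zip(v["chrom"], v["pos"], v["effect_allele"], v["other_allele"])
        ]

    # -- derived per-variant statistics --------------------------------------
    def eaf(self) -> np.ndarray:
        """Effect-allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        eaf = self.eaf()
        return np.minimum(eaf, 1.0 - eaf)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def hard_calls(self) -> np.ndarray:
        """Round dosages to {0,1,2} at 0.5/1.5 cut-points; nan preserved."""
        g = np.full_like(self.dosages, np.nan)
        ok = ~np.isnan(self.dosages)
        g[ok] = np.clip(np.floor(self.dosages[ok] + 0.5), 0, 2)
        return g

    def dosages_imputed(self) -> np.ndarray:
        """Mean-impute missing dosages per variant (analysis-time only)."""
        d = self.dosages.copy()
        mask = np.isnan(d)
        if mask.any():
            with np.errstate(invalid="ignore"):
                col_means = np.nanmean(d, axis=0)
            col_means = np.where(np.isnan(col_means), 0.0, col_means)
            d[mask] = np.take(col_means, np.nonzero(mask)[1])
        return d

    # -- subsetting ----------------------------------------------------------
    def select_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return GenotypeMatrix(
            self.individuals,
            self.variants.iloc[idx],
            self.dosages[:, idx],
            sex=self.sex,
            population_label=self.population_label,
        )

    def select_individuals(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return GenotypeMatrix(
            [self.individuals[i] for i in idx],
            self.variants,
            self.dosages[idx, :],
            sex=None if self.sex is None else self.sex[idx],
            population_label=None
            if self.population_label is None
            else self.population_label[idx],
        )


class SummaryStats:
    """Per-variant association summary records (GWAS or eQTL side).

    Thin wrapper around a DataFrame with columns ``id, chrom, pos,
    effect_allele, other_allele, eaf, beta, se, p, n`` and an optional
    ``stratum`` in {"all", "male", "female"}.
    """

    REQUIRED = ["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]

    def __init__(self, table: pd.DataFrame, stratum: str = "all"):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if (table["se"] <= 0).any():
            raise ValueError("se must be > 0")
        p = table["p"].to_numpy(dtype=float)
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p must lie in (0, 1]")
        if not np.isfinite(table["beta"].to_numpy(dtype=float)).all():
            raise ValueError("beta must be finite")
        self.table = table.reset_index(drop=True)
        self.stratum = stratum

    def __len__(self) -> int:
        return len(self.table)

    def variant_keys(self) -> list[tuple]:
        t = self.table
        return [
            variant_key(c, p, a, b)
            for c, p, a, b in zip(t["chrom"], t["pos"], t["effect_allele"], t["other_allele"])
        ]

    def subset(self, mask) -> "SummaryStats":
        return SummaryStats(self.table[np.asarray(mask)].reset_index(drop=True), self.stratum)


@dataclass
class GeneAnnotation:
    """Gene bodies (1-based inclusive) plus a length used for TPM."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, length

    def __post_init__(self):
        t = self.table
        for col in ("gene_id", "chrom", "start", "end", "length"):
            if col not in t.columns:
                raise ValueError(f"gene annotation missing column {col!r}")
        if (t["start"] > t["end"]).any():
            raise ValueError("gene start must be <= end")
        if (t["length"] < 1).any():
            raise ValueError("gene length must be >= 1")
        self.table = t.reset_index(drop=True)

    def lengths_for(self, gene_ids: Iterable[str]) -> np.ndarray:
        lut = dict(zip(self.table["gene_id"], self.table["length"]))
        missing = [g for g in gene_ids if g not in lut]
        if missing:
            raise KeyError(f"genes without annotated length: {missing}")
        return np.array([lut[g] for g in gene_ids], dtype=float)


@dataclass
class PhenotypeTable:
    """Per-individual outcomes and covariates.

    ``table`` is indexed by individual ID; conventional columns are the lipid
    outcomes (``tg``, ``hdl``, ``tc``), ``bmi``, ``age``, ``sex`` (male/female),
    ``tc_medication`` (bool) and any number of covariate columns (genetic PCs
    etc.).
    """

    table: pd.DataFrame

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise ValueError("duplicate individual IDs in phenotype table")

    def aligned_to(self, individuals: Sequence[str]) -> pd.DataFrame:
        missing = [i for i in individuals if i not in self.table.index]
        if missing:
            raise KeyError(f"individuals without phenotypes: {missing[:5]}")
        return self.table.loc[list(individuals)]


@dataclass
class CisWindow:
    """A gene-anchored cis region: gene body extended by ``flank`` bases."""

    gene_id: str
    chrom: str
    start: int
    end: int

    @classmethod
    def from_gene(cls, gene_id: str, chrom: str, start: int, end: int,
                  flank: int = 500_000) -> "CisWindow":
        return cls(gene_id, str(chrom), max(1, int(start) - flank), int(end) + flank)

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= int(pos) <= self.end


def windows_from_annotation(annotation: GeneAnnotation, genes: Iterable[str] | None = None,
                            flank: int = 500_000, anchor: str = "gene_body") -> dict[str, CisWindow]:
    """Build cis windows per gene.

    ``anchor="gene_body"`` extends both gene ends by ``flank``;
    ``anchor="tss"`` centres a window of half-width ``flank`` on the start
    coordinate (the alternate convention used by bulk meta-analyses).
    """
    t = annotation.table
    if genes is not None:
        genes = set(genes)
        t = t[t["gene_id"].isin(genes)]
    out = {}
    for row in t.itertuples(index=False):
        if anchor == "gene_body":
            out[row.gene_id] = CisWindow.from_gene(row.gene_id, row.chrom, row.start, row.end, flank)
        elif anchor == "tss":
            out[row.gene_id] = CisWindow(row.gene_id, str(row.chrom),
                                         max(1, int(row.start) - flank), int(row.start) + flank)
        else:
            raise ValueError(f"unknown window anchor {anchor!r}")
    return out
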