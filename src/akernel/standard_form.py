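"""Standard-form encoding of case/control SNP genotype data.

A biallelic SNP genotype is an unordered pair of nucleotides.  The standard
organization re-codes each SNP as an *ordered* pair of allele compartments:
under the fixed nucleotide order A < C < G < T, the allele with the higher
rank ("hi") is written first, and each compartment records symbol 2 when it
carries the hi allele and symbol 1 otherwise.  A heterozygote therefore
always encodes (2, 1); a hi homozygote (2, 2); a lo homozygote (1, 1).
The first compartment of SNP k is the *odd* locus (column 2k-1, 1-based)
and the second the *even* locus (column 2k).

This module also implements the data-cleaning rules used downstream:
dropping SNPs with more than a fixed number of missing symbols and filling
the few remaining gaps with the column's modal symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: integer marker for a missing symbol inside an :class:`AlleleMatrix`
MISSING: int = 0

#: fixed total order on nucleotides used to decide which allele is "hi"
NUCLEOTIDE_ALIAS: dict[str, int] = {"A": 1, "C": 2, "G": 3, "T": 4}

DISEASE = "disease"
CONTROL = "control"

_MISSING_GENOTYPES = {None, "", "..", "00", "NN", "--", "./.", ". .", "0 0"}


@dataclass(frozen=True)
class SnpDef:
    """Definition of one biallelic SNP.

    ``allele_hi`` is the allele with the larger rank under the fixed
    nucleotide order and aliases to symbol 2; ``allele_lo`` aliases to 1.
    """

    snp_id: str
    chromosome: str
    position: int
    allele_hi: str
    allele_lo: str

    def __post_init__(self) -> None:
        for a in (self.allele_hi, self.allele_lo):
            if a not in NUCLEOTIDE_ALIAS:
                raise ValueError(
                    f"{self.snp_id}: allele {a!r} not a nucleotide in ACGT"
                )
        if self.allele_hi == self.allele_lo:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if NUCLEOTIDE_ALIAS[self.allele_hi] < NUCLEOTIDE_ALIAS[self.allele_lo]:
            raise ValueError(
                f"{self.snp_id}: allele_hi={self.allele_hi} ranks below "
                f"allele_lo={self.allele_lo} under A<C<G<T"
            )

    @classmethod
    def from_alleles(
        cls, snp_id: str, chromosome: str, position: int, a: str, b: str
    ) -> "SnpDef":
        """Build a definition from two alleles in arbitrary order."""
        hi, lo = (a, b) if NUCLEOTIDE_ALIAS.get(a, 0) > NUCLEOTIDE_ALIAS.get(b, 0) else (b, a)
        return cls(snp_id, chromosome, position, hi, lo)


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one allele compartment (one column of an AlleleMatrix)."""

    snp_index: int  # 1-based SNP number
    compartment: str  # "odd" | "even"
    snp: SnpDef | None = None
    label: str | None = None  # SNP name when no SnpDef is available (TSV input)

    @property
    def locus_id(self) -> str:
        if self.snp is not None:
            sid = self.snp.snp_id
        elif self.label is not None:
            sid = self.label
        else:
            sid = f"snp{self.snp_index}"
        return f"{sid}.{'o' if self.compartment == 'odd' else 'e'}"


@dataclass
class AlleleMatrix:
    """Samples x allele-loci matrix of standard-form symbols.

    ``symbols`` holds values in {1, 2, MISSING} with dtype int8; column
    2k-2/2k-1 (0-based) are the odd/even compartments of SNP k.
    """

    symbols: np.ndarray
    loci: list[LocusMeta]
    sample_ids: list[str]
    labels: np.ndarray  # per-sample, values in {"disease", "control"}

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=object)
        n, l = self.symbols.shape
        if l != len(self.loci):
            raise ValueError(f"{l} columns but {len(self.loci)} locus records")
        if l % 2:
            raise ValueError("odd number of allele columns; SNP pairing broken")
        if n != len(self.sample_ids) or n != len(self.labels):
            raise ValueError("sample_ids/labels length mismatch with rows")
        bad = set(self.labels) - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.symbols.shape[0]

    @property
    def n_loci(self) -> int:
        return self.symbols.shape[1]

    @property
    def n_snps(self) -> int:
        return self.symbols.shape[1] // 2

    @property
    def disease_mask(self) -> np.ndarray:
        return self.labels == DISEASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.labels == CONTROL

    def cohort(self, label: str) -> np.ndarray:
        """Symbol rows of one cohort."""
        if label not in (DISEASE, CONTROL):
            raise ValueError(f"unknown cohort {label!r}")
        return self.symbols[self.labels == label]

    @property
    def locus_ids(self) -> list[str]:
        return [m.locus_id for m in self.loci]


def _decode_pair(g: object) -> tuple[str, str] | None:
    """Normalise one raw genotype cell to a nucleotide pair or None."""
    if isinstance(g, float) and np.isnan(g):
        return None
    if g in _MISSING_GENOTYPES:
        return None
    if isinstance(g, str):
        if len(g) != 2:
            raise ValueError(f"genotype string {g!r} is not two characters")
        return g[0], g[1]
    if isinstance(g, (tuple, list, np.ndarray)) and len(g) == 2:
        a, b = str(g[0]), str(g[1])
        if a in ("0", ".", "N") or b in ("0", ".", "N"):
            return None
        return a, b
    raise ValueError(f"cannot interpret genotype cell {g!r}")


def encode_standard_form(
    genotypes: Sequence[Sequence[object]],
    snps: Sequence[SnpDef],
    sample_ids: Sequence[str] | None = None,
    labels: Sequence[str] | None = None,
) -> AlleleMatrix:
    """Encode unordered genotype pairs into the standard organization.

    Parameters
    ----------
    genotypes
        samples x M array whose cells are unordered nucleotide pairs
        ("AT", ("A", "T")) or a missing marker (None, "", "..", "00").
    snps
        One :class:`SnpDef` per column of ``genotypes``.
    sample_ids, labels
        Optional sample annotations; defaults are generated ids and
        all-control labels (statistics then need labels supplied later).

    Returns
    -------
    AlleleMatrix
        samples x 2M matrix over {1, 2, MISSING}: each SNP emits an odd
        and an even compartment, heterozygotes as (2, 1), hi homozygotes
        as (2, 2), lo homozygotes as (1, 1).
    """
    geno = np.asarray(genotypes, dtype=object)
    if geno.ndim != 2:
        raise ValueError("genotypes must be a 2-D samples x SNPs array")
    n, m = geno.shape
    if m != len(snps):
        raise ValueError(f"{m} genotype columns but {len(snps)} SNP definitions")

    symbols = np.full((n, 2 * m), MISSING, dtype=np.int8)
    for k, snp in enumerate(snps):
        hi, lo = snp.allele_hi, snp.allele_lo
        for i in range(n):
            pair = _decode_pair(geno[i, k])
            if pair is None:
                continue
            a, b = pair
            if a not in (hi, lo) or b not in (hi, lo):
                raise ValueError(
                    f"{snp.snp_id}: genotype {a}{b} contains an allele outside "
                    f"({hi},{lo}) for sample {i}"
                )
            n_hi = (a == hi) + (b == hi)
            if n_hi == 2:
                symbols[i, 2 * k], symbols[i, 2 * k + 1] = 2, 2
            elif n_hi == 1:
                symbols[i, 2 * k], symbols[i, 2 * k + 1] = 2, 1
            else:
                symbols[i, 2 * k], symbols[i, 2 * k + 1] = 1, 1

    loci: list[LocusMeta] = []
    for k, snp in enumerate(snps):
        loci.append(LocusMeta(k + 1, "odd", snp))
        loci.append(LocusMeta(k + 1, "even", snp))
    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    if labels is None:
        labels = np.array([CONTROL] * n, dtype=object)
    return AlleleMatrix(symbols, loci, list(sample_ids), np.asarray(labels, dtype=object))


def decode_standard_form(m: AlleleMatrix) -> np.ndarray:
    """Invert the encoding back to unordered nucleotide pairs (hi first)."""
    n = m.n_samples
    out = np.empty((n, m.n_snps), dtype=object)
    for k in range(m.n_snps):
        snp = m.loci[2 * k].snp
        if snp is None:
            raise ValueError(f"SNP {k + 1} carries no allele definitions")
        lut = {2: snp.allele_hi, 1: snp.allele_lo}
        for i in range(n):
            o, e = m.symbols[i, 2 * k], m.symbols[i, 2 * k + 1]
            out[i, k] = None if MISSING in (o, e) else lut[o] + lut[e]
    return out


def filter_missing_loci(
    m: AlleleMatrix, max_missing: int = 2
) -> tuple[AlleleMatrix, pd.DataFrame]:
    """Drop every SNP with more than ``max_missing`` missing symbols.

    The count is over both compartments and all samples jointly (a missing
    genotype contributes two missing symbols).  Returns the filtered matrix
    and a report of removed SNPs with their missing-symbol counts.
    """
    miss = m.symbols == MISSING
    per_snp = miss.reshape(m.n_samples, m.n_snps, 2).sum(axis=(0, 2))
    drop = per_snp > max_missing
    keep_cols = np.repeat(~drop, 2)

    removed = pd.DataFrame(
        {
            "snp_id": [m.loci[2 * k].locus_id.rsplit(".", 1)[0] for k in np.flatnonzero(drop)],
            "n_missing": per_snp[drop],
        }
    )
    loci = [lm for lm, k in zip(m.loci, keep_cols) if k]
    # re-number SNPs consecutively so snp_index stays 1..M'
    renum: list[LocusMeta] = []
    for j, lm in enumerate(loci):
        renum.append(replace(lm, snp_index=j // 2 + 1))
    out = AlleleMatrix(m.symbols[:, keep_cols], renum, list(m.sample_ids), m.labels.copy())
    return out, removed


def impute_modal(m: AlleleMatrix, tie_symbol: int = 2) -> AlleleMatrix:
    """Replace every missing symbol by its column's modal symbol.

    The mode is taken over all samples, both cohorts pooled, so imputation
    never looks at phenotype labels.  An exact 50/50 tie imputes
    ``tie_symbol`` (default 2).
    """
    sym = m.symbols.copy()
    obs = sym != MISSING
    if not obs.any(axis=0).all():
        bad = np.flatnonzero(~obs.any(axis=0))
        raise ValueError(f"cannot impute all-missing column(s) {bad.tolist()}")
    n2 = ((sym == 2)).sum(axis=0)
    n1 = ((sym == 1)).sum(axis=0)
    mode = np.where(n2 > n1, 2, np.where(n1 > n2, 1, tie_symbol)).astype(np.int8)
    miss_r, miss_c = np.nonzero(~obs)
    sym[miss_r, miss_c] = mode[miss_c]
    return AlleleMatrix(sym, list(m.loci), list(m.sample_ids), m.labels.copy())


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id TAB {disease|control} file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    bad = set(df["label"]) - {DISEASE, CONTROL}
    if bad:
        raise ValueError(f"phenotype file {path}: unknown labels {sorted(bad)}")
    return dict(zip(df["sample_id"], df["label"]))


def _labels_for(sample_ids: Sequence[str], pheno: dict[str, str], where: str) -> np.ndarray:
    missing = [s for s in sample_ids if s not in pheno]
    if missing:
        raise ValueError(f"{where}: samples absent from phenotype file: {missing[:5]}")
    return np.array([pheno[s] for s in sample_ids], dtype=object)


def read_vcf(path: str | Path, phenotype_path: str | Path) -> AlleleMatrix:
    """Read biallelic SNP records from a VCF into standard form.

    Multi-allelic or non-SNP records are skipped with a warning.  Labels
    come from a phenotype sidecar TSV.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snps: list[SnpDef] = []
    cols: list[list[object]] = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            logger.warning("skipping non-biallelic-SNP record %s:%s", var.CHROM, var.POS)
            continue
        ref, alt = var.REF, var.ALT[0]
        sid = var.ID or f"{var.CHROM}:{var.POS}"
        snp = SnpDef.from_alleles(sid, str(var.CHROM), var.POS, ref, alt)
        alleles = (ref, alt)
        col: list[object] = []
        for gt in var.genotypes:
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                col.append(None)
            else:
                col.append(alleles[a0] + alleles[a1])
        snps.append(snp)
        cols.append(col)
    geno = np.array(cols, dtype=object).T if cols else np.empty((len(sample_ids), 0), object)
    pheno = read_phenotypes(phenotype_path)
    labels = _labels_for(sample_ids, pheno, str(path))
    return encode_standard_form(geno, snps, sample_ids, labels)


def read_ped_map(
    ped_path: str | Path, map_path: str | Path, phenotype_path: str | Path
) -> AlleleMatrix:
    """Read PLINK .ped/.map text genotypes into standard form.

    Alleles are nucleotide letters with 0 for missing; SNP alleles are
    inferred from the observed letters at each locus.  A locus observed
    with more than two alleles is rejected; a monomorphic locus gets an
    arbitrary second allele so the encoding stays well defined.
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chromosome", "snp_id", "cm", "position"], dtype=str,
    )
    rows = []
    sample_ids = []
    with open(ped_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            sample_ids.append(tok[1])
            rows.append(tok[6:])
    n_snps = len(mp)
    geno = np.empty((len(rows), n_snps), dtype=object)
    for i, alleles in enumerate(rows):
        if len(alleles) != 2 * n_snps:
            raise ValueError(
                f"{ped_path}: sample {sample_ids[i]} has {len(alleles)} allele "
                f"fields, expected {2 * n_snps}"
            )
        for k in range(n_snps):
            a, b = alleles[2 * k], alleles[2 * k + 1]
            geno[i, k] = None if "0" in (a, b) else (a, b)

    snps = []
    for k in range(n_snps):
        seen = sorted({a for g in geno[:, k] if g is not None for a in g})
        if len(seen) > 2:
            raise ValueError(f"{mp.snp_id[k]}: more than two alleles observed: {seen}")
        if len(seen) == 1:
            seen.append("A" if seen[0] != "A" else "C")
        elif not seen:
            seen = ["A", "C"]
        snps.append(
            SnpDef.from_alleles(mp.snp_id[k], mp.chromosome[k], int(mp.position[k]), *seen)
        )
    pheno = read_phenotypes(phenotype_path)
    labels = _labels_for(sample_ids, pheno, str(ped_path))
    return encode_standard_form(geno, snps, sample_ids, labels)


def write_standard_tsv(m: AlleleMatrix, path: str | Path) -> None:
    """Write the internal standard-form TSV (cells in {1,2,NA})."""
    df = pd.DataFrame(m.symbols, index=m.sample_ids, columns=m.locus_ids)
    df = df.astype(object).mask(df == MISSING, "NA")
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_phenotype_tsv(m: AlleleMatrix, path: str | Path) -> None:
    pd.DataFrame({"sample_id": m.sample_ids, "label": m.labels}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_standard_tsv(path: str | Path, phenotype_path: str | Path) -> AlleleMatrix:
    """Read the internal standard-form TSV produced by :func:`write_standard_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    sym = df.to_numpy(dtype=float)
    sym = np.where(np.isnan(sym), MISSING, sym).astype(np.int8)
    loci: list[LocusMeta] = []
    for j, cid in enumerate(df.columns):
        base, _, tag = cid.rpartition(".")
        if tag not in ("o", "e"):
            raise ValueError(f"{path}: column {cid!r} lacks the .o/.e compartment tag")
        loci.append(LocusMeta(j // 2 + 1, "odd" if tag == "o" else "even", None,
                              label=base))
    sample_ids = [str(s) for s in df.index]
    pheno = read_phenotypes(phenotype_path)
    labels = _labels_for(sample_ids, pheno, str(path))
    return AlleleMatrix(sym, loci, sample_ids, labels)


def read_genotypes(
    path: str | Path,
    fmt: str,
    phenotype_path: str | Path,
    map_path: str | Path | None = None,
) -> AlleleMatrix:
    """Dispatch reader: ``vcf``, ``ped_map`` (or ``ped``) or ``tsv``."""
    if fmt == "vcf":
        return read_vcf(path, phenotype_path)
    if fmt in ("ped", "ped_map"):
        if map_path is None:
            map_path = Path(path).with_suffix(".map")
        return read_ped_map(path, map_path, phenotype_path)
    if fmt == "tsv":
        return read_standard_tsv(path, phenotype_path)
    raise ValueError(f"unknown genotype format {fmt!r}")
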