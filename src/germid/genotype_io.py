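"""Genotype and passport input/output.

The shared data model of the package is a diploidized biallelic genotype
matrix: every call is coded 0 (homozygous reference pattern), 1 (both
alleles present) or 2 (homozygous alternate pattern), with an explicit
missing mask.  Polyploid calls collapse onto this coding by allele
*presence*: a GT of any ploidy that contains both the reference and the
alternate allele is a heterozygote (code 1), regardless of dosage.  This
is the natural scoring for single-dose SNP panels in high polyploids,
where dosage is not resolvable but presence/absence is.

No imputation is performed anywhere: missing stays missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PassportTable",
    "read_vcf",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_passport",
]

MISSING_TOKEN = "NA"


class PanelError(ValueError):
    """Raised when an input panel is structurally unusable."""


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of diploidized genotype codes.

    Parameters
    ----------
    sample_ids, locus_ids
        Unique, ordered identifiers for the two axes.
    calls
        ``int8`` array of shape ``(n_samples, n_loci)`` with values in
        ``{0, 1, 2}``.  Entries under the missing mask are ignored.
    missing
        Boolean array of the same shape; ``True`` marks a missing call.
    """

    sample_ids: list
    locus_ids: list
    calls: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.missing is None:
            self.missing = np.zeros(self.calls.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PanelError("duplicate sample identifiers")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise PanelError("duplicate locus identifiers")
        expected = (len(self.sample_ids), len(self.locus_ids))
        if self.calls.shape != expected or self.missing.shape != expected:
            raise PanelError(
                f"calls/missing shape {self.calls.shape}/{self.missing.shape} "
                f"does not match ids {expected}"
            )
        valid = np.isin(self.calls, (0, 1, 2)) | self.missing
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise PanelError(
                f"invalid genotype code {self.calls[tuple(bad)]} at "
                f"sample {self.sample_ids[bad[0]]}, locus {self.locus_ids[bad[1]]}"
            )
        # canonicalize: masked entries carry no code
        self.calls = np.where(self.missing, 0, self.calls).astype(np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def shape(self) -> tuple:
        return (self.n_samples, self.n_loci)

    def as_float(self) -> np.ndarray:
        """Calls as float with NaN at missing entries."""
        out = self.calls.astype(float)
        out[self.missing] = np.nan
        return out

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset(self, samples=None, loci=None) -> "GenotypeMatrix":
        """Restrict to the given sample ids and/or locus ids (or index arrays)."""
        rows = np.arange(self.n_samples)
        cols = np.arange(self.n_loci)
        if samples is not None:
            samples = list(samples)
            if samples and isinstance(samples[0], str):
                rows = self.sample_index(samples)
            else:
                rows = np.asarray(samples)
                if rows.dtype == bool:
                    rows = np.flatnonzero(rows)
                else:
                    rows = rows.astype(int)
        if loci is not None:
            loci = list(loci)
            if loci and isinstance(loci[0], str):
                lookup = {l: i for i, l in enumerate(self.locus_ids)}
                cols = np.array([lookup[l] for l in loci], dtype=int)
            else:
                cols = np.asarray(loci)
                if cols.dtype == bool:
                    cols = np.flatnonzero(cols)
                else:
                    cols = cols.astype(int)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in rows],
            [self.locus_ids[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
            self.missing[np.ix_(rows, cols)],
        )

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeMatrix)
            and self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.missing, other.missing)
            and np.array_equal(
                np.where(self.missing, 0, self.calls),
                np.where(other.missing, 0, other.calls),
            )
        )


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices sharing the same locus panel."""
    if a.locus_ids != b.locus_ids:
        raise PanelError("locus panels differ; cannot concatenate samples")
    return GenotypeMatrix(
        a.sample_ids + b.sample_ids,
        a.locus_ids,
        np.vstack([a.calls, b.calls]),
        np.vstack([a.missing, b.missing]),
    )


@dataclass
class PassportTable:
    """Per-clone collection metadata.

    ``clone_code`` is the unique accession identifier and indexes the
    table; ``clone_name`` is free text and may be shared by several
    accessions (homonym candidates).  ``replicate_group`` marks sets of
    samples propagated from one clone as internal genotyping controls.
    """

    table: pd.DataFrame
    warnings: list = field(default_factory=list)

    REQUIRED = ("clone_code", "clone_name", "recorded_species")
    OPTIONAL = ("origin", "replicate_group")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"passport table missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in self.table.columns:
                self.table[col] = pd.NA
        if self.table["clone_code"].duplicated().any():
            dups = self.table.loc[self.table["clone_code"].duplicated(), "clone_code"]
            raise ValueError(f"duplicate clone_code values: {sorted(set(dups))}")
        grp = self.table["replicate_group"].dropna()
        singletons = grp.value_counts()
        bad = singletons[singletons < 2]
        if len(bad):
            raise ValueError(
                f"replicate_group must name >=2 samples; singleton groups: {list(bad.index)}"
            )
        self.table = self.table.set_index("clone_code", drop=False)

    @property
    def clone_codes(self) -> list:
        return list(self.table["clone_code"])

    def name_of(self, code: str) -> str:
        return self.table.at[code, "clone_name"]

    def species_of(self, code: str) -> str:
        return self.table.at[code, "recorded_species"]

    def replicate_ids(self, group=None) -> list:
        """Sample ids in the given replicate-control group (or the first one)."""
        grp = self.table["replicate_group"].dropna()
        if grp.empty:
            return []
        if group is None:
            group = grp.iloc[0]
        return list(grp[grp == group].index)


def _diploidize(alleles) -> int:
    """Collapse a GT allele tuple of any ploidy to a presence-pattern code.

    Returns -1 for a missing call (any missing allele), else 0/1/2.
    """
    if any(a < 0 for a in alleles):
        return -1
    has_ref = any(a == 0 for a in alleles)
    has_alt = any(a > 0 for a in alleles)
    if has_ref and has_alt:
        return 1
    return 2 if has_alt else 0


def read_vcf(path, min_depth: int = 20, min_allele_reads: int = 2) -> GenotypeMatrix:
    """Read a VCF into a diploidized genotype matrix.

    Multiallelic records are dropped.  When depth fields are present a
    call is set to missing if total depth is below ``min_depth`` or if
    any allele claimed by the call is supported by fewer than
    ``min_allele_reads`` reads (freebayes RO/AO or an AD field).  VCF
    sample order is preserved.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError on bad files
        raise PanelError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    locus_ids, columns, miss_cols = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        codes = np.array([_diploidize(gt[:-1]) for gt in var.genotypes], dtype=np.int8)
        miss = codes < 0
        dp = var.format("DP")
        if dp is not None:
            dp = dp[:, 0].astype(np.int64)
            miss |= (dp < min_depth) | (dp < 0)
        ro, ao = var.format("RO"), var.format("AO")
        if ro is None and var.format("AD") is not None:
            ad = var.format("AD")
            if ad.shape[1] >= 2:
                ro, ao = ad[:, :1], ad[:, 1:2]
        if ro is not None and ao is not None:
            ro = ro[:, 0].astype(np.int64)
            ao = ao[:, 0].astype(np.int64)
            needs_ref = np.isin(codes, (0, 1))
            needs_alt = np.isin(codes, (1, 2))
            miss |= needs_ref & (ro < min_allele_reads)
            miss |= needs_alt & (ao < min_allele_reads)
        codes = np.where(miss, 0, codes)
        lid = var.ID or f"{var.CHROM}:{var.POS}"
        locus_ids.append(lid)
        columns.append(codes)
        miss_cols.append(miss)
    if not locus_ids:
        raise PanelError(f"no biallelic sites in {path}")
    calls = np.column_stack(columns)
    missing = np.column_stack(miss_cols)
    return GenotypeMatrix(samples, locus_ids, calls, missing)


def read_genotype_csv(path) -> GenotypeMatrix:
    """Read a genotype CSV (rows = samples, columns = loci, cells 0/1/2/NA)."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise PanelError(f"duplicate sample or locus identifiers in {path}")
    raw = df.to_numpy()
    missing = (raw == MISSING_TOKEN) | (raw == "")
    calls = np.zeros(raw.shape, dtype=np.int8)
    ok = np.isin(raw, ("0", "1", "2"))
    bad = ~(ok | missing)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PanelError(
            f"invalid genotype code {raw[i, j]!r} at sample {df.index[i]!r}, "
            f"locus {df.columns[j]!r}"
        )
    calls[ok] = raw[ok].astype(np.int8)
    return GenotypeMatrix(list(df.index), list(df.columns), calls, missing)


def write_genotype_csv(gm: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as CSV; exact round-trip with :func:`read_genotype_csv`."""
    cells = gm.calls.astype(object)
    cells[gm.missing] = MISSING_TOKEN
    df = pd.DataFrame(cells, index=gm.sample_ids, columns=gm.locus_ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def write_structure_format(gm: GenotypeMatrix, path, pops=None) -> None:
    """Export the panel in the two-row-per-individual STRUCTURE layout.

    Alleles are coded 0/1 (reference/alternate) with -9 for missing; an
    optional per-sample population label column is written after the id.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(gm.locus_ids) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            rows = ([], [])
            for j in range(gm.n_loci):
                if gm.missing[i, j]:
                    a = b = "-9"
                else:
                    code = gm.calls[i, j]
                    a = "1" if code >= 1 else "0"
                    b = "1" if code == 2 else "0"
                rows[0].append(a)
                rows[1].append(b)
            prefix = [str(sid)] + ([str(pops[i])] if pops is not None else [])
            for row in rows:
                fh.write("\t".join(prefix + row) + "\n")


def read_passport(path, genotypes: GenotypeMatrix = None) -> PassportTable:
    """Read a passport CSV and validate it against a genotype matrix.

    Samples present in only one of the two inputs are reported as
    warnings (stored on the table and emitted via :mod:`warnings`), not
    errors: a genebank passport ledger routinely covers more material
    than any one genotyping run.
    """
    df = pd.read_csv(path, dtype=str)
    passport = PassportTable(df)
    if genotypes is not None:
        geno = set(genotypes.sample_ids)
        listed = set(passport.clone_codes)
        for code in sorted(listed - geno):
            passport.warnings.append(f"passport row {code} has no genotyped sample")
        for code in sorted(geno - listed):
            passport.warnings.append(f"genotyped sample {code} has no passport row")
        for msg in passport.warnings:
            warnings.warn(msg, stacklevel=2)
    return passport
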