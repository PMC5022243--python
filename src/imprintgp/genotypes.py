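"""Phased genotype and phenotype containers, file IO and quality control.

Genotypes are stored as two allele matrices (paternal and maternal) with
entries in {0, 1} and -1 for missing calls.  Allele code 1 is the allele
whose population frequency is denoted ``p`` throughout the package (the
"A2" allele); code 0 is the other allele ("A1").  In phased VCF input the
first allele of each ``a|b`` pair is taken to be the paternal one.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

__all__ = [
    "PhasedGenotypes",
    "PhenotypeTable",
    "QCReport",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "allele_frequency",
    "hwe_test",
    "qc_filter",
]


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype input (unphased or multiallelic records)."""


@dataclasses.dataclass
class PhasedGenotypes:
    """Phased biallelic genotypes for ``n`` individuals at ``m`` SNPs.

    Attributes
    ----------
    sample_ids : ndarray of str, shape (n,)
    snp_ids : ndarray of str, shape (m,)
    chrom : ndarray of str, shape (m,)
    pos : ndarray of int, shape (m,)
        1-based physical positions.
    paternal, maternal : ndarray of int8, shape (n, m)
        Allele codes, ``-1`` marking a missing call.  Both matrices share
        their missingness pattern: a genotype is either fully observed or
        fully missing.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    paternal: np.ndarray
    maternal: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        if self.paternal.shape != self.maternal.shape:
            raise ValueError("paternal and maternal matrices must share shape")
        if self.paternal.shape != (self.n_samples, self.n_snps):
            raise ValueError("allele matrices inconsistent with id vectors")
        for mat in (self.paternal, self.maternal):
            bad = ~np.isin(mat, (0, 1, MISSING))
            if bad.any():
                raise ValueError("allele codes must be 0, 1 or -1 (missing)")
        if ((self.paternal == MISSING) != (self.maternal == MISSING)).any():
            raise ValueError("missingness must be shared between the two alleles")
        if len(set(self.sample_ids)) != self.n_samples:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != self.n_snps:
            raise ValueError("duplicate SNP ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, m) mask of missing genotypes."""
        return self.paternal == MISSING

    def dosage(self) -> np.ndarray:
        """Count of allele-1 copies (0/1/2) as float, NaN where missing."""
        d = (self.paternal + self.maternal).astype(float)
        d[self.missing_mask] = np.nan
        return d

    def subset(self, samples: np.ndarray | None = None, snps: np.ndarray | None = None) -> "PhasedGenotypes":
        """Return a copy restricted to the given sample/SNP index arrays."""
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        vi = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return PhasedGenotypes(
            sample_ids=self.sample_ids[si],
            snp_ids=self.snp_ids[vi],
            chrom=self.chrom[vi],
            pos=self.pos[vi],
            paternal=self.paternal[np.ix_(si, vi)],
            maternal=self.maternal[np.ix_(si, vi)],
        )


@dataclasses.dataclass
class PhenotypeTable:
    """Corrected phenotypes with litter and birth-year structure.

    Wraps a DataFrame with columns ``id``, ``y_c``, ``litter``,
    ``birth_year`` and ``birth_date`` (datetime).
    """

    frame: pd.DataFrame

    REQUIRED = ("id", "y_c", "litter", "birth_year", "birth_date")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if self.frame["id"].duplicated().any():
            dup = self.frame.loc[self.frame["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate sample id in phenotypes: {dup!r}")
        if not np.isfinite(self.frame["y_c"].to_numpy(float)).all():
            raise ValueError("non-finite corrected phenotype y_c")
        self.frame = self.frame.reset_index(drop=True)
        self.frame["birth_date"] = pd.to_datetime(self.frame["birth_date"])
        years = self.frame["birth_date"].dt.year.to_numpy()
        if (years != self.frame["birth_year"].to_numpy()).any():
            raise ValueError("birth_date inconsistent with birth_year")

    def __len__(self) -> int:
        return len(self.frame)

    def aligned_to(self, sample_ids: np.ndarray) -> "PhenotypeTable":
        """Reorder rows to match ``sample_ids``; error on absent ids."""
        idx = self.frame.set_index("id")
        absent = [s for s in sample_ids if s not in idx.index]
        if absent:
            raise ValueError(f"{len(absent)} genotyped ids lack phenotypes, e.g. {absent[0]!r}")
        return PhenotypeTable(idx.loc[list(sample_ids)].reset_index())


@dataclasses.dataclass
class QCReport:
    """Counts of samples/SNPs removed by each quality-control filter."""

    thresholds: dict
    n_samples_in: int
    n_snps_in: int
    samples_removed_call_rate: int
    snps_removed_call_rate: int
    snps_removed_maf: int
    snps_removed_hwe: int

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_call_rate

    @property
    def n_snps_out(self) -> int:
        return (self.n_snps_in - self.snps_removed_call_rate
                - self.snps_removed_maf - self.snps_removed_hwe)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sample_call_rate", "sample", self.samples_removed_call_rate,
             self.thresholds["sample_call_rate_min"]),
            ("snp_call_rate", "snp", self.snps_removed_call_rate,
             self.thresholds["snp_call_rate_min"]),
            ("maf", "snp", self.snps_removed_maf, self.thresholds["maf_min"]),
            ("hwe", "snp", self.snps_removed_hwe, self.thresholds["hwe_p_min"]),
        ]
        return pd.DataFrame(rows, columns=["filter", "unit", "removed", "threshold"])


def read_phased_vcf(path: str | Path) -> PhasedGenotypes:
    """Read a phased, biallelic VCF into a :class:`PhasedGenotypes`.

    The first allele of each phased pair is recorded as paternal.  Unphased
    or multiallelic records raise :class:`GenotypeFormatError`; a missing
    genotype (``./.`` or ``.|.``) becomes missing in both matrices.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = np.asarray(vcf.samples, dtype=object)
    pat_cols, mat_cols, snp_ids, chroms, poss = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise GenotypeFormatError(
                f"non-biallelic record at {v.CHROM}:{v.POS} ({len(v.ALT)} ALT alleles)")
        g = np.asarray(v.genotypes, dtype=np.int64)  # columns: allele1, allele2, phased
        observed = (g[:, 0] >= 0) & (g[:, 1] >= 0)
        if (observed & (g[:, 2] == 0)).any():
            bad = samples[observed & (g[:, 2] == 0)][0]
            raise GenotypeFormatError(
                f"unphased genotype at {v.CHROM}:{v.POS} for sample {bad!r}")
        pat = np.where(observed, g[:, 0], MISSING).astype(np.int8)
        mat = np.where(observed, g[:, 1], MISSING).astype(np.int8)
        pat_cols.append(pat)
        mat_cols.append(mat)
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
    vcf.close()
    if not snp_ids:
        raise GenotypeFormatError(f"no variant records in {path}")
    return PhasedGenotypes(
        sample_ids=samples,
        snp_ids=np.asarray(snp_ids, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss),
        paternal=np.column_stack(pat_cols),
        maternal=np.column_stack(mat_cols),
    )


def write_phased_vcf(path: str | Path, genotypes: PhasedGenotypes) -> None:
    """Write genotypes as a minimal phased VCF (GT only, ``|`` separator)."""
    g = genotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##phasing=paternal_allele_first\n')
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.sample_ids)) + "\n")
        for j in range(g.n_snps):
            calls = []
            for i in range(g.n_samples):
                a, b = g.paternal[i, j], g.maternal[i, j]
                calls.append(".|." if a == MISSING else f"{a}|{b}")
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\tA\tB\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_phenotypes(path: str | Path, genotypes: PhasedGenotypes | None = None) -> PhenotypeTable:
    """Read a tab-separated phenotype file.

    Rows whose ``y_c`` does not parse as a number are dropped (counted in a
    log message); duplicate ids or missing required columns raise.  If
    ``genotypes`` is given, ids are cross-checked and rows re-ordered to the
    genotype sample order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "litter": str})
    missing = [c for c in PhenotypeTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} missing columns: {missing}")
    y = pd.to_numeric(df["y_c"], errors="coerce")
    n_bad = int(y.isna().sum())
    if n_bad:
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d rows with non-numeric y_c from %s", n_bad, path)
        df = df[~y.isna()].copy()
        y = y[~y.isna()]
    df["y_c"] = y.astype(float)
    table = PhenotypeTable(df)
    if genotypes is not None:
        table = table.aligned_to(genotypes.sample_ids)
    return table


def write_phenotypes(path: str | Path, table: PhenotypeTable) -> None:
    out = table.frame.copy()
    out["birth_date"] = out["birth_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)


def allele_frequency(genotypes: PhasedGenotypes) -> np.ndarray:
    """Frequency of allele 1 ("A2") per SNP from non-missing calls.

    Raises if any SNP has no observed calls.
    """
    pat = genotypes.paternal.astype(float)
    mat = genotypes.maternal.astype(float)
    obs = ~genotypes.missing_mask
    n_alleles = 2 * obs.sum(axis=0)
    if (n_alleles == 0).any():
        bad = genotypes.snp_ids[n_alleles == 0]
        raise ValueError(f"SNPs with all calls missing: {list(bad[:5])}")
    count = np.where(obs, pat, 0).sum(axis=0) + np.where(obs, mat, 0).sum(axis=0)
    return count / n_alleles


def hwe_test(genotypes: PhasedGenotypes) -> np.ndarray:
    """One-df chi-square test of Hardy-Weinberg equilibrium per SNP.

    Reciprocal heterozygotes are pooled (the test concerns the unordered
    genotype).  Where an expected genotype count is zero (allele fixed in
    the observed calls) the p-value is 1.
    """
    d = genotypes.dosage()
    obs = ~np.isnan(d)
    n = obs.sum(axis=0).astype(float)
    if (n == 0).any():
        raise ValueError("SNP with no observed genotypes")
    n0 = np.nansum(d == 0, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n2 = np.nansum(d == 2, axis=0).astype(float)
    p = (n1 + 2.0 * n2) / (2.0 * n)
    e0, e1, e2 = n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2)
    pvals = np.where((e0 == 0) | (e1 == 0) | (e2 == 0), 1.0,
                     stats.chi2.sf(chi2, df=1))
    return pvals


def qc_filter(
    genotypes: PhasedGenotypes,
    maf_min: float = 0.01,
    snp_call_rate_min: float = 0.9,
    hwe_p_min: float = 1e-7,
    sample_call_rate_min: float = 0.8,
) -> tuple[PhasedGenotypes, QCReport]:
    """Apply the standard SNP/sample quality-control cascade.

    Order: (1) samples with call rate below ``sample_call_rate_min`` are
    excluded; then SNPs must have (2) call rate strictly above
    ``snp_call_rate_min``, (3) minor allele frequency strictly above
    ``maf_min`` and (4) HWE chi-square p-value strictly above ``hwe_p_min``.
    All inequalities are strict on the retain side, so a SNP with MAF
    exactly at the floor is removed.
    """
    for name, t in [("maf_min", maf_min), ("snp_call_rate_min", snp_call_rate_min),
                    ("hwe_p_min", hwe_p_min), ("sample_call_rate_min", sample_call_rate_min)]:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {name}={t} outside [0, 1]")
    n_in, m_in = genotypes.n_samples, genotypes.n_snps

    sample_cr = 1.0 - genotypes.missing_mask.mean(axis=1)
    keep_samples = np.flatnonzero(sample_cr >= sample_call_rate_min)
    g = genotypes.subset(samples=keep_samples)

    snp_cr = 1.0 - g.missing_mask.mean(axis=0)
    pass_cr = snp_cr > snp_call_rate_min
    g1 = g.subset(snps=np.flatnonzero(pass_cr))

    p = allele_frequency(g1)
    maf = np.minimum(p, 1.0 - p)
    pass_maf = maf > maf_min
    g2 = g1.subset(snps=np.flatnonzero(pass_maf))

    pass_hwe = hwe_test(g2) > hwe_p_min
    g3 = g2.subset(snps=np.flatnonzero(pass_hwe))

    report = QCReport(
        thresholds=dict(maf_min=maf_min, snp_call_rate_min=snp_call_rate_min,
                        hwe_p_min=hwe_p_min, sample_call_rate_min=sample_call_rate_min),
        n_samples_in=n_in,
        n_snps_in=m_in,
        samples_removed_call_rate=n_in - g.n_samples,
        snps_removed_call_rate=int((~pass_cr).sum()),
        snps_removed_maf=int((~pass_maf).sum()),
        snps_removed_hwe=int((~pass_hwe).sum()),
    )
    if g3.n_snps == 0:
        raise ValueError("quality control removed every SNP; review thresholds")
    return g3, report
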