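"""Additive, dominance and parent-of-origin design-matrix codings.

For a biallelic SNP with alleles A1 and A2 at frequencies ``1 - p`` and
``p``, genotypes are coded per individual as

=============  ==========  ================  ==========
genotype       additive     dominance         imprinting
=============  ==========  ================  ==========
A1A1           -2p          -2p^2             0
A1A2 (pat A1)  1 - 2p       2p(1 - p)         +1
A2A1 (pat A2)  1 - 2p       2p(1 - p)         -1
A2A2           2 - 2p       -2(1 - p)^2       0
=============  ==========  ================  ==========

The additive coding is the usual frequency-centered allele count; the
dominance coding is a centered heterozygosity contrast (mean zero under
Hardy-Weinberg proportions); the imprinting coding is a signed contrast of
the two reciprocal heterozygotes, so a nonzero effect means the phenotype
depends on which parent transmitted A2.  Under random mating both
heterozygote orders are equally frequent and the column has mean zero.

Missing genotypes are filled with the coding-column expectation (zero for
all three codings) when ``expectation_fill`` is enabled; otherwise they
raise.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genotypes import PhasedGenotypes, allele_frequency

__all__ = [
    "DesignMatrixSet",
    "additive_codes",
    "dominance_codes",
    "imprinting_codes",
    "build_design_matrices",
]


@dataclasses.dataclass
class DesignMatrixSet:
    """The three coding matrices plus the allele frequencies used to center."""

    M_a: np.ndarray
    M_d: np.ndarray
    M_i: np.ndarray
    freqs: np.ndarray

    def matrix(self, effect: str) -> np.ndarray:
        return {"additive": self.M_a, "dominance": self.M_d, "imprinting": self.M_i}[effect]

    def dump_tsv(self, path, sample_ids=None, snp_ids=None) -> None:
        """Debugging export: dense TSV with one row per (sample, SNP).

        Not a pipeline format — intended for eyeballing codings on small
        instances.
        """
        import pandas as pd

        n, m = self.M_a.shape
        si = np.asarray(sample_ids) if sample_ids is not None else np.arange(n)
        vi = np.asarray(snp_ids) if snp_ids is not None else np.arange(m)
        rows = pd.DataFrame({
            "sample": np.repeat(si, m),
            "snp": np.tile(vi, n),
            "freq": np.tile(self.freqs, n),
            "M_a": self.M_a.ravel(),
            "M_d": self.M_d.ravel(),
            "M_i": self.M_i.ravel(),
        })
        rows.to_csv(path, sep="\t", index=False)


def _check_freqs(freqs: np.ndarray, n_snps: int) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (n_snps,):
        raise ValueError(f"expected {n_snps} frequencies, got shape {freqs.shape}")
    if ((freqs <= 0.0) | (freqs >= 1.0)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    return freqs


def _dosage_filled(genotypes: PhasedGenotypes, expectation_fill: bool) -> np.ndarray:
    d = (genotypes.paternal + genotypes.maternal).astype(float)
    miss = genotypes.missing_mask
    if miss.any() and not expectation_fill:
        raise ValueError("missing genotypes present; enable expectation_fill or impute upstream")
    return d, miss


def additive_codes(genotypes: PhasedGenotypes, freqs: np.ndarray,
                   expectation_fill: bool = True) -> np.ndarray:
    """Centered allele-count coding: A1A1 -> -2p, het -> 1-2p, A2A2 -> 2-2p."""
    freqs = _check_freqs(freqs, genotypes.n_snps)
    d, miss = _dosage_filled(genotypes, expectation_fill)
    M = d - 2.0 * freqs[None, :]
    M[miss] = 0.0
    return M


def dominance_codes(genotypes: PhasedGenotypes, freqs: np.ndarray,
                    expectation_fill: bool = True) -> np.ndarray:
    """Dominance coding: A1A1 -> -2p^2, het -> 2p(1-p), A2A2 -> -2(1-p)^2."""
    freqs = _check_freqs(freqs, genotypes.n_snps)
    d, miss = _dosage_filled(genotypes, expectation_fill)
    p = freqs[None, :]
    M = np.where(d == 1, 2.0 * p * (1.0 - p),
                 np.where(d == 0, -2.0 * p**2, -2.0 * (1.0 - p) ** 2))
    M[miss] = 0.0
    return M


def imprinting_codes(genotypes: PhasedGenotypes,
                     expectation_fill: bool = True) -> np.ndarray:
    """Signed heterozygote coding: +1 if the paternal allele is A1, -1 if A2.

    Homozygotes are 0.  Requires known parental origin at every
    heterozygote; with ``expectation_fill`` a missing genotype codes 0.
    """
    pat, mat = genotypes.paternal, genotypes.maternal
    miss = genotypes.missing_mask
    if miss.any() and not expectation_fill:
        raise ValueError("missing genotypes present; enable expectation_fill or impute upstream")
    M = np.zeros(pat.shape, dtype=float)
    M[(pat == 0) & (mat == 1)] = 1.0
    M[(pat == 1) & (mat == 0)] = -1.0
    M[miss] = 0.0
    return M


def build_design_matrices(genotypes: PhasedGenotypes,
                          freqs: np.ndarray | None = None,
                          expectation_fill: bool = True) -> DesignMatrixSet:
    """Build all three codings.

    Frequencies default to those observed in ``genotypes`` (the analyzed
    individuals), which keeps centering honest when the object holds only a
    training set.
    """
    if freqs is None:
        freqs = allele_frequency(genotypes)
    freqs = _check_freqs(np.asarray(freqs, float), genotypes.n_snps)
    return DesignMatrixSet(
        M_a=additive_codes(genotypes, freqs, expectation_fill),
        M_d=dominance_codes(genotypes, freqs, expectation_fill),
        M_i=imprinting_codes(genotypes, expectation_fill),
        freqs=freqs,
    )
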