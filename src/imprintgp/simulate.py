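"""Simulation of phased populations with known genetic architecture.

Emulates a pig breeding data set: full-sib litters nested in birth years,
biallelic autosomal SNPs, and corrected phenotypes built from birth-year
effects, additive + dominance + imprinting SNP effects drawn from a
four-class normal mixture, litter effects and residuals.  Default
parameters mirror the backfat-thickness study conditions: 8113
individuals, 33 004 SNPs, mean full-sib litter size 2.44, 17 birth years,
a 23 % tail of the population born after the validation cutoff, and
variance targets (additive 0.341, dominance 0.045, imprinting 0.015,
litter 0.059, residual 0.657 in phenotype units squared).

Two generations are simulated: founder sires/dams receive independent
Hardy-Weinberg gametes; each litter shares one sire and one dam, and each
offspring draws one allele per parent per SNP by Mendelian sampling (no
linkage between SNPs).  The paternal allele is always the first allele of
the phase pair.  Only the offspring generation is returned.

Ground truth (per-SNP effects with their mixture class, per-individual
genetic and litter values) is stored so downstream estimation can be
tested for recovery; SNP effects are rescaled after drawing so the
analytic genetic variance of each effect type hits its target exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import DesignMatrixSet, build_design_matrices
from .genotypes import PhasedGenotypes, PhenotypeTable, write_phased_vcf, write_phenotypes
from .variance import coding_column_variances

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "simulate_allele_frequencies",
    "simulate_phased_genotypes",
    "simulate_snp_effects",
    "simulate_phenotypes",
    "simulate_population",
]

EFFECT_TYPES = ("additive", "dominance", "imprinting")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic population.

    ``target_variances`` are on the phenotypic scale (units squared of the
    trait); the defaults reproduce the backfat variance profile of the
    full three-effect model.  ``mixing_proportions`` govern how SNP
    effects are spread over the four mixture classes.
    """

    n_individuals: int = 8113
    n_snps: int = 33_004
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    target_variances: dict = dataclasses.field(default_factory=lambda: {
        "additive": 0.341, "dominance": 0.045, "imprinting": 0.015,
        "litter": 0.059, "residual": 0.657})
    mixing_proportions: tuple[float, ...] = (0.889, 0.1, 0.01, 0.001)
    mean_litter_size: float = 2.44
    n_birth_years: int = 17
    first_birth_year: int = 1998
    birth_year_effect_sd: float = 0.2
    validation_fraction: float = 0.23
    missing_rate: float = 0.0
    maf_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.mixing_proportions, dtype=float)
        if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-12 or (pi < 0).any():
            raise ValueError("mixing_proportions must be 4 non-negative values summing to 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"allele_freq_range {self.allele_freq_range} not within (0, 1)")
        if lo < self.maf_floor:
            raise ValueError("allele_freq_range minimum below the MAF floor")
        if any(v < 0 for v in self.target_variances.values()):
            raise ValueError("target variances must be non-negative")
        if self.mean_litter_size < 1:
            raise ValueError("mean_litter_size must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclasses.dataclass
class SimulatedPopulation:
    """A simulated data set with full ground truth."""

    config: SimulationConfig
    genotypes: PhasedGenotypes
    phenotypes: PhenotypeTable
    design: DesignMatrixSet
    true_effects: pd.DataFrame        # per SNP: effect + class per type
    true_components: pd.DataFrame     # per individual: genetic/litter values
    realized_variances: dict
    cutoff_date: pd.Timestamp

    def save(self, out_prefix: str | Path) -> dict[str, Path]:
        """Write VCF, phenotype TSV and truth TSVs under a directory."""
        out = Path(out_prefix)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": out / "genotypes.vcf",
            "phenotypes": out / "phenotypes.tsv",
            "true_effects": out / "true_effects.tsv",
            "true_components": out / "true_components.tsv",
        }
        write_phased_vcf(paths["genotypes"], self.genotypes)
        write_phenotypes(paths["phenotypes"], self.phenotypes)
        self.true_effects.to_csv(paths["true_effects"], sep="\t", index=False)
        self.true_components.to_csv(paths["true_components"], sep="\t", index=False)
        return paths


def simulate_allele_frequencies(n_snps: int, freq_range: tuple[float, float],
                                rng: np.random.Generator) -> np.ndarray:
    """Draw per-SNP frequencies of allele A2 uniformly in ``freq_range``."""
    lo, hi = freq_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"invalid allele frequency range ({lo}, {hi})")
    return rng.uniform(lo, hi, size=n_snps)


def _draw_litter_sizes(n_individuals: int, mean_size: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Shifted-Poisson litter sizes (minimum 1) truncated to n_individuals."""
    sizes = []
    total = 0
    while total < n_individuals:
        s = 1 + int(rng.poisson(max(mean_size - 1.0, 0.0)))
        s = min(s, n_individuals - total)
        sizes.append(s)
        total += s
    return np.asarray(sizes)


def simulate_phased_genotypes(config: SimulationConfig, freqs: np.ndarray,
                              rng: np.random.Generator
                              ) -> tuple[PhasedGenotypes, np.ndarray]:
    """Simulate litters of full sibs; returns genotypes and litter ids.

    Each litter has its own founder sire and dam whose four gametes are
    independent Bernoulli(p_j) draws per SNP; offspring alleles follow by
    Mendelian sampling, the paternal gamete recorded first.
    """
    n, m = config.n_individuals, config.n_snps
    sizes = _draw_litter_sizes(n, config.mean_litter_size, rng)
    n_lit = len(sizes)
    litter_of = np.repeat(np.arange(n_lit), sizes)

    sire = rng.random((2, n_lit, m)) < freqs    # two gametes per sire
    dam = rng.random((2, n_lit, m)) < freqs
    pick_pat = rng.integers(0, 2, size=(n, m))
    pick_mat = rng.integers(0, 2, size=(n, m))
    lit = litter_of[:, None]
    paternal = np.where(pick_pat == 0, sire[0][litter_of], sire[1][litter_of]).astype(np.int8)
    maternal = np.where(pick_mat == 0, dam[0][litter_of], dam[1][litter_of]).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        paternal[miss] = -1
        maternal[miss] = -1

    width = len(str(n))
    genotypes = PhasedGenotypes(
        sample_ids=np.array([f"ind{i + 1:0{width}d}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp{j + 1}" for j in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1) * 1000,
        paternal=paternal,
        maternal=maternal,
    )
    litter_ids = np.array([f"lit{k + 1}" for k in litter_of], dtype=object)
    return genotypes, litter_ids


def simulate_snp_effects(n_snps: int, mixing_proportions, target_variance: float,
                         freqs: np.ndarray, effect_type: str,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw mixture-distributed SNP effects and rescale to the target.

    Each SNP is assigned a class by the mixing proportions and its effect
    drawn from that class's normal (class SDs on a geometric ladder).  The
    vector is then rescaled so the analytic genetic variance
    ``sum_j w_j q_j^2`` (with ``w_j`` the coding-column variance) equals
    ``target_variance`` exactly; a zero target gives a zero vector.
    """
    if target_variance < 0:
        raise ValueError("target_variance must be >= 0")
    pi = np.asarray(mixing_proportions, dtype=float)
    classes = rng.choice(4, size=n_snps, p=pi)
    if target_variance == 0 or n_snps == 0:
        return np.zeros(n_snps), classes
    ladder = 10.0 ** (np.arange(4) - 3.0)  # relative class variances
    effects = rng.standard_normal(n_snps) * np.sqrt(ladder[classes])
    w = coding_column_variances(effect_type, freqs)
    analytic = float(w @ effects**2)
    if analytic <= 0:
        raise ValueError("degenerate draw: zero analytic variance before rescaling")
    effects *= np.sqrt(target_variance / analytic)
    return effects, classes


def _assign_birth_dates(litter_ids: np.ndarray, config: SimulationConfig,
                        rng: np.random.Generator):
    """Give every litter a birth date so the last ``validation_fraction`` of
    individuals is born on/after the returned cutoff date."""
    unique, first_pos = np.unique(litter_ids, return_index=True)
    order = unique[np.argsort(first_pos)]          # litters in creation order
    n_lit = len(order)
    start = pd.Timestamp(f"{config.first_birth_year}-01-01")
    end = pd.Timestamp(f"{config.first_birth_year + config.n_birth_years - 1}-12-31")
    days = np.sort(rng.integers(0, (end - start).days + 1, size=n_lit))
    date_of = {lid: start + pd.Timedelta(int(d), "D") for lid, d in zip(order, days)}
    dates = pd.Series([date_of[l] for l in litter_ids])
    # cutoff: smallest litter date such that the tail holds ~ the target share
    n = len(litter_ids)
    counts = pd.Series(litter_ids).value_counts().reindex(order).to_numpy()
    cum = np.cumsum(counts)
    k = int(np.searchsorted(cum, (1.0 - config.validation_fraction) * n))
    k = min(max(k, 1), n_lit - 1)
    cutoff = date_of[order[k]]
    return dates, cutoff


def simulate_phenotypes(genotypes: PhasedGenotypes, litter_ids: np.ndarray,
                        design: DesignMatrixSet, effects: dict[str, np.ndarray],
                        config: SimulationConfig, rng: np.random.Generator):
    """Assemble corrected phenotypes from the generative model.

    y_c = birth-year effect + M_a q_a + M_d q_d + M_i q_i + litter + residual.
    Litter effects are drawn once per litter; residuals are i.i.d.

    Returns ``(PhenotypeTable, per-individual component frame, cutoff date)``.
    """
    n = genotypes.n_samples
    dates, cutoff = _assign_birth_dates(litter_ids, config, rng)
    years = dates.dt.year.to_numpy()
    uyears = np.unique(years)
    year_eff = dict(zip(uyears, rng.normal(0.0, config.birth_year_effect_sd, len(uyears))))

    components = {}
    for eff in EFFECT_TYPES:
        components[eff] = design.matrix(eff) @ effects[eff]
    ulit, lit_idx = np.unique(litter_ids, return_inverse=True)
    lit_vals = rng.normal(0.0, np.sqrt(config.target_variances.get("litter", 0.0)), len(ulit))
    components["litter"] = lit_vals[lit_idx]
    residual = rng.normal(0.0, np.sqrt(config.target_variances.get("residual", 0.0)), n)

    y = (np.array([year_eff[yr] for yr in years])
         + components["additive"] + components["dominance"]
         + components["imprinting"] + components["litter"] + residual)

    table = PhenotypeTable(pd.DataFrame({
        "id": genotypes.sample_ids, "y_c": y, "litter": litter_ids,
        "birth_year": years, "birth_date": dates.to_numpy()}))
    comp_frame = pd.DataFrame({"id": genotypes.sample_ids, **components,
                               "residual": residual})
    return table, comp_frame, cutoff


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Full generative pipeline: frequencies -> genotypes -> effects -> y_c."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_allele_frequencies(config.n_snps, config.allele_freq_range, rng)
    genotypes, litter_ids = simulate_phased_genotypes(config, freqs, rng)
    # center and scale everything by the frequencies observed in the
    # simulated individuals, the same reference downstream analysis uses
    design = build_design_matrices(genotypes)
    effects, classes = {}, {}
    for eff in EFFECT_TYPES:
        effects[eff], classes[eff] = simulate_snp_effects(
            config.n_snps, config.mixing_proportions,
            config.target_variances.get(eff, 0.0), design.freqs, eff, rng)
    phenotypes, comp_frame, cutoff = simulate_phenotypes(
        genotypes, litter_ids, design, effects, config, rng)

    realized = {eff: float(np.var(comp_frame[eff])) for eff in EFFECT_TYPES}
    realized["litter"] = float(np.var(comp_frame["litter"]))
    realized["residual"] = float(np.var(comp_frame["residual"]))
    true_effects = pd.DataFrame({
        "snp_id": genotypes.snp_ids, "freq": design.freqs,
        **{f"{e}_effect": effects[e] for e in EFFECT_TYPES},
        **{f"{e}_class": classes[e] + 1 for e in EFFECT_TYPES}})
    return SimulatedPopulation(
        config=config, genotypes=genotypes, phenotypes=phenotypes,
        design=design, true_effects=true_effects, true_components=comp_frame,
        realized_variances=realized, cutoff_date=cutoff)
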