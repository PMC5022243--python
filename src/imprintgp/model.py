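"""Bayesian mixture models for genomic prediction with non-additive effects.

The central object is :class:`SNPMixtureModel`, built from a phenotype
table and phased genotypes, which fits one of the models

* ``A``    — additive SNP effects only,
* ``AD``   — additive + dominance,
* ``AI``   — additive + imprinting,
* ``ADI``  — additive + dominance + imprinting,

all with birth-year fixed effects and random litter effects:

    y_c = X b + M_a q_a [+ M_d q_d] [+ M_i q_i] + Z l + e.

Each SNP-effect vector has a four-component normal mixture prior with
known mixing proportions and estimated class variances constrained to be
strictly increasing; class variances, litter variance and residual
variance all carry flat priors.  ``fit`` runs a single Gibbs chain and
returns a :class:`SNPMixtureResults` carrying posterior means/SDs, the
variance decomposition, per-observation conditional predictive ordinates
(for pseudo-Bayes-factor model comparison) and convergence diagnostics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import _gibbs
from .coding import build_design_matrices
from .diagnostics import MCMCError, mcmc_standard_error
from .genotypes import PhasedGenotypes, PhenotypeTable
from .variance import VarianceDecomposition, coding_column_variances

__all__ = ["ModelSpec", "SNPMixtureModel", "SNPMixtureResults",
           "MODEL_EFFECTS", "DEFAULT_MIXING"]

MODEL_EFFECTS = {
    "A": ("additive",),
    "AD": ("additive", "dominance"),
    "AI": ("additive", "imprinting"),
    "ADI": ("additive", "dominance", "imprinting"),
}
DEFAULT_MIXING = (0.889, 0.1, 0.01, 0.001)


@dataclasses.dataclass
class ModelSpec:
    """Model configuration: effect set, mixture prior and chain control."""

    effect_set: tuple[str, ...] = ("additive", "dominance", "imprinting")
    mixing_proportions: tuple[float, ...] = DEFAULT_MIXING
    chain_length: int = 50_000
    burn_in: int = 20_000
    thinning: int = 10
    seed: int = 0
    # fixed-variance switches used by oracle tests and degenerate runs
    update_class_variances: bool = True
    update_litter_variance: bool = True
    update_residual_variance: bool = True
    fixed_class_variances: np.ndarray | None = None  # (n_types, 4)
    fixed_litter_variance: float | None = None
    fixed_residual_variance: float | None = None
    store_effect_samples: bool = False
    resync_every: int = 1000
    trace_every: int = 1000

    def __post_init__(self) -> None:
        self.effect_set = tuple(self.effect_set)
        valid = ("additive", "dominance", "imprinting")
        if any(e not in valid for e in self.effect_set):
            raise ValueError(f"effect_set entries must be among {valid}")
        if "additive" not in self.effect_set:
            raise ValueError("the additive effect is always part of the model")
        pi = np.asarray(self.mixing_proportions, dtype=float)
        if pi.shape != (4,) or (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("mixing proportions must be 4 non-negative values summing to 1")
        if not 0 <= self.burn_in < self.chain_length:
            raise ValueError("require 0 <= burn_in < chain_length")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def model_code(self) -> str:
        for code, effects in MODEL_EFFECTS.items():
            if tuple(sorted(effects)) == tuple(sorted(self.effect_set)):
                return code
        raise AssertionError

    @property
    def n_saved(self) -> int:
        return (self.chain_length - self.burn_in) // self.thinning


def initialize_chain(spec: ModelSpec, y: np.ndarray, year_index: np.ndarray,
                     n_years: int, weights_by_effect: dict[str, float]) -> dict:
    """Deterministic starting state.

    Year effects start at year means of ``y``; litter and SNP effects at
    zero; residual variance at half the phenotypic variance (floored for
    degenerate input) and litter variance at 5 % of it.  Class variances
    start on a geometric ladder ``base * 10^(c-3)`` so the ordering
    constraint holds from the start, with ``base`` chosen so the implied
    genetic variance of each effect type equals half the phenotypic
    variance.  Starting the ladder at data scale matters: a chain whose
    effect-variance hierarchy starts many orders of magnitude below the
    data can be absorbed near zero before any SNP effect picks up signal.
    """
    n = y.size
    if n < n_years + 2:
        raise ValueError(f"need at least n_years + 2 = {n_years + 2} observations, got {n}")
    var_y = float(np.var(y))
    floor0 = max(var_y, 1.0) * 1e-8
    var_e = max(0.5 * var_y, floor0)
    var_l = max(0.05 * var_y, floor0)
    b0 = np.zeros(n_years)
    counts = np.bincount(year_index, minlength=n_years).astype(float)
    sums = np.bincount(year_index, weights=y, minlength=n_years)
    b0 = sums / counts
    class_vars = np.empty((len(spec.effect_set), 4))
    ladder = 10.0 ** (np.arange(4) - 3.0)
    pi = np.asarray(spec.mixing_proportions, dtype=float)
    for t, eff in enumerate(spec.effect_set):
        denom = float(pi @ ladder) * max(weights_by_effect[eff], 1e-12)
        base = 0.5 * max(var_y, floor0) / denom
        v = base * ladder
        # keep the whole ladder below the phenotypic-variance ceiling
        scale = min(1.0, max(var_y, floor0) / v[-1])
        class_vars[t] = v * scale
    if spec.fixed_class_variances is not None:
        class_vars = np.asarray(spec.fixed_class_variances, dtype=float).reshape(
            len(spec.effect_set), 4).copy()
    if spec.fixed_litter_variance is not None:
        var_l = float(spec.fixed_litter_variance)
    if spec.fixed_residual_variance is not None:
        var_e = float(spec.fixed_residual_variance)
    return dict(b0=b0, var_e=var_e, var_l=var_l, class_vars=class_vars,
                var_floor=max(var_y, 1e-300) * _gibbs.VAR_FLOOR_REL,
                var_ceiling=max(var_y, floor0))


class SNPMixtureModel:
    """Genomic-prediction mixture model bound to one phenotype/genotype set.

    Parameters
    ----------
    phenotypes : PhenotypeTable
        Corrected phenotypes with litter and birth-year columns; rows are
        re-ordered to the genotype sample order.
    genotypes : PhasedGenotypes
        Phased training genotypes.  Design matrices are centered with
        allele frequencies computed from these (the analyzed) individuals.
    effects : str or sequence of str
        A model code ("A", "AD", "AI", "ADI") or an explicit effect set.
    """

    def __init__(self, phenotypes: PhenotypeTable, genotypes: PhasedGenotypes,
                 effects: str | tuple[str, ...] = "ADI") -> None:
        if isinstance(effects, str):
            effects = MODEL_EFFECTS[effects.upper()]
        self.effects = tuple(effects)
        self.genotypes = genotypes
        self.phenotypes = phenotypes.aligned_to(genotypes.sample_ids)
        self.design = build_design_matrices(genotypes)
        frame = self.phenotypes.frame
        self.endog = frame["y_c"].to_numpy(float)
        self.year_index, self.year_labels = pd.factorize(frame["birth_year"])
        self.litter_index, self.litter_labels = pd.factorize(frame["litter"])
        self.year_index = np.ascontiguousarray(self.year_index, dtype=np.int64)
        self.litter_index = np.ascontiguousarray(self.litter_index, dtype=np.int64)

    @classmethod
    def from_files(cls, genotype_vcf, phenotype_tsv, effects="ADI",
                   qc: bool = True, **qc_kwargs) -> "SNPMixtureModel":
        from .genotypes import qc_filter, read_phased_vcf, read_phenotypes

        genotypes = read_phased_vcf(genotype_vcf)
        if qc:
            genotypes, _ = qc_filter(genotypes, **qc_kwargs)
        phenotypes = read_phenotypes(phenotype_tsv, genotypes=genotypes)
        return cls(phenotypes, genotypes, effects=effects)

    def _stacked_design(self) -> tuple[np.ndarray, np.ndarray]:
        cols = [self.design.matrix(e).T for e in self.effects]  # (m, n) each
        MT = np.ascontiguousarray(np.vstack(cols), dtype=np.float64)
        col_type = np.repeat(np.arange(len(self.effects)), self.genotypes.n_snps)
        return MT, np.ascontiguousarray(col_type, dtype=np.int64)

    def fit(self, chain_length: int = 50_000, burn_in: int = 20_000,
            thinning: int = 10, seed: int = 0,
            mixing_proportions=DEFAULT_MIXING, spec: ModelSpec | None = None,
            ) -> "SNPMixtureResults":
        """Run the Gibbs chain and summarize the posterior.

        Either pass chain-control arguments directly or a full
        :class:`ModelSpec` (which wins and must carry this model's effect
        set).
        """
        if spec is None:
            spec = ModelSpec(effect_set=self.effects, chain_length=chain_length,
                             burn_in=burn_in, thinning=thinning, seed=seed,
                             mixing_proportions=tuple(mixing_proportions))
        elif tuple(spec.effect_set) != self.effects:
            raise ValueError("spec.effect_set does not match the model's effects")

        weights = {e: float(coding_column_variances(e, self.design.freqs).sum())
                   for e in self.effects}
        init = initialize_chain(spec, self.endog, self.year_index,
                                len(self.year_labels), weights)
        MT, col_type = self._stacked_design()
        year_counts = np.bincount(self.year_index, minlength=len(self.year_labels)).astype(float)
        litter_counts = np.bincount(self.litter_index, minlength=len(self.litter_labels)).astype(float)
        pi = np.asarray(spec.mixing_proportions, dtype=float)

        out = _gibbs.run_chain_kernel(
            self.endog, self.year_index, year_counts,
            self.litter_index, litter_counts,
            MT, col_type, len(self.effects), pi,
            spec.chain_length, spec.burn_in, spec.thinning, int(spec.seed) & 0x7FFFFFFF,
            init["b0"], np.zeros(len(self.litter_labels)), init["class_vars"],
            init["var_l"], init["var_e"],
            spec.update_class_variances, spec.update_litter_variance,
            spec.update_residual_variance,
            init["var_floor"], init["var_ceiling"], spec.store_effect_samples,
            spec.resync_every, spec.trace_every)
        (status, class_var_samples, var_l_samples, var_e_samples,
         q_sum, q_sumsq, cls_counts, q_samples,
         cpo_inv, trace, max_resync, n_saved, b_final, l_final, e_final) = out
        if status != 0:
            raise FloatingPointError(f"non-finite sampler state at iteration {status}")
        if n_saved != spec.n_saved:
            raise AssertionError("saved-sample bookkeeping mismatch")
        return SNPMixtureResults(self, spec, class_var_samples, var_l_samples,
                                 var_e_samples, q_sum, q_sumsq, cls_counts,
                                 q_samples, cpo_inv, trace, max_resync, n_saved)


class SNPMixtureResults:
    """Posterior summary of one fitted chain.

    Exposes variance-component samples and means, per-SNP posterior mean
    effects, genomic predictions (GBV/GTV), conditional predictive
    ordinates, time-series standard errors and a text ``summary()``.
    """

    def __init__(self, model, spec, class_var_samples, var_l_samples,
                 var_e_samples, q_sum, q_sumsq, cls_counts, q_samples,
                 cpo_inv, trace, max_resync, n_saved):
        self.model = model
        self.spec = spec
        self.n_saved = int(n_saved)
        self.class_var_samples = class_var_samples  # (nsave, n_types, 4)
        self.trace = trace
        self.max_resync_deviation = float(max_resync)
        self.effect_samples = q_samples if q_samples.size else None

        m = model.genotypes.n_snps
        self.effect_means = {}
        self.effect_sds = {}
        self.class_probabilities = {}
        for t, eff in enumerate(model.effects):
            sl = slice(t * m, (t + 1) * m)
            mean = q_sum[sl] / n_saved
            var = np.maximum(q_sumsq[sl] / n_saved - mean**2, 0.0)
            self.effect_means[eff] = mean
            self.effect_sds[eff] = np.sqrt(var)
            self.class_probabilities[eff] = cls_counts[sl] / n_saved

        pi = np.asarray(spec.mixing_proportions, float)
        self.component_samples: dict[str, np.ndarray] = {}
        for t, eff in enumerate(model.effects):
            w = coding_column_variances(eff, model.design.freqs).sum()
            self.component_samples[eff] = w * (class_var_samples[:, t, :] @ pi)
        self.component_samples["litter"] = var_l_samples
        self.component_samples["residual"] = var_e_samples

        # CPO_i = harmonic mean over saved iterations of N(y_i; fitted_i, s2_e)
        self.cpo = n_saved / cpo_inv

    # -- variance components -------------------------------------------------
    def variance_decomposition(self) -> VarianceDecomposition:
        return VarianceDecomposition.from_samples(self.component_samples)

    @property
    def variance_components(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.component_samples.items()}

    @property
    def lpml(self) -> float:
        """Log pseudo-marginal likelihood: sum of log CPOs."""
        return float(np.log(self.cpo).sum())

    # -- diagnostics ---------------------------------------------------------
    def mcse(self) -> dict[str, MCMCError]:
        return {name: mcmc_standard_error(s)
                for name, s in self.component_samples.items()}

    @property
    def converged(self) -> bool:
        return all(v.converged for v in self.mcse().values())

    # -- prediction ----------------------------------------------------------
    def predict(self, genotypes: PhasedGenotypes | None = None,
                scope: str = "GTV") -> np.ndarray:
        """Genomic predictions for the training set or new genotypes.

        ``scope="GBV"`` gives the estimated breeding value ``M_a q_a``;
        ``scope="GTV"`` the total genetic value, summing every effect in
        the fitted model.  New genotypes are coded with the training
        allele frequencies.
        """
        if scope not in ("GBV", "GTV"):
            raise ValueError("scope must be 'GBV' or 'GTV'")
        if genotypes is None:
            design = self.model.design
        else:
            design = build_design_matrices(genotypes, freqs=self.model.design.freqs)
        effects = ("additive",) if scope == "GBV" else self.model.effects
        for e in effects:
            if e not in self.effect_means:
                raise ValueError(f"effect {e!r} absent from the fitted model")
        pred = np.zeros(design.M_a.shape[0])
        for e in effects:
            pred += design.matrix(e) @ self.effect_means[e]
        return pred

    # -- reporting -----------------------------------------------------------
    def effects_frame(self) -> pd.DataFrame:
        g = self.model.genotypes
        data = {"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos,
                "freq": self.model.design.freqs}
        for eff in self.model.effects:
            data[f"{eff}_mean"] = self.effect_means[eff]
            data[f"{eff}_sd"] = self.effect_sds[eff]
        return pd.DataFrame(data)

    def summary(self) -> str:
        dec = self.variance_decomposition()
        lines = [
            f"SNP mixture model {self.spec.model_code} "
            f"(n={len(self.model.endog)}, m={self.model.genotypes.n_snps})",
            f"chain {self.spec.chain_length}, burn-in {self.spec.burn_in}, "
            f"thinning {self.spec.thinning}, saved {self.n_saved}, seed {self.spec.seed}",
            "",
            dec.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            f"narrow-sense h2 = {dec.narrow_h2:.4f}; broad-sense H2 = {dec.broad_H2:.4f}",
            f"LPML = {self.lpml:.2f}",
        ]
        flags = self.mcse()
        bad = [k for k, v in flags.items() if not v.converged]
        lines.append("time-series SE < 5% of posterior mean: "
                     + ("all components" if not bad else f"NOT converged: {bad}"))
        return "\n".join(lines)
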