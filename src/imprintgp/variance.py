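"""Genetic variance components, proportions and heritabilities.

Each SNP-effect class variance is converted to a genetic variance on the
phenotypic scale by weighting with the population variance of the coding
column.  For the additive coding that weight is ``2 p (1 - p)``, giving

    sigma2_a = sum_j 2 p_j (1 - p_j) * sum_i pi_i sigma2_{a,i},

the standard conversion for mixture-prior SNP models.  The dominance and
imprinting weights follow from the variances of their coding columns under
Hardy-Weinberg proportions and random mating:

* dominance column variance: ``(2 p (1 - p))^2`` — the column takes values
  ``-2p^2 / 2p(1-p) / -2(1-p)^2`` with HWE frequencies, which has mean zero
  and second moment ``(2p(1-p))^2``;
* imprinting column variance: ``2 p (1 - p)`` — the column is +/-1 on the
  two reciprocal heterozygotes (each with frequency ``p(1-p)``) and zero
  otherwise.

These two weights are derived here rather than quoted: only the additive
case has a canonical printed form, and alternative dominance
parameterizations in the literature lead to different weights.  The tests
cross-check them by enumerating genotype classes and by Monte Carlo.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np

__all__ = [
    "VarianceDecomposition",
    "coding_column_variances",
    "additive_variance",
    "dominance_variance",
    "imprinting_variance",
    "genetic_variance",
    "heritabilities",
]

GENETIC_EFFECTS = ("additive", "dominance", "imprinting")


def coding_column_variances(effect: str, freqs: np.ndarray) -> np.ndarray:
    """Per-SNP population variance of the coding column for ``effect``."""
    p = np.asarray(freqs, dtype=float)
    h = 2.0 * p * (1.0 - p)
    if effect == "additive":
        return h
    if effect == "dominance":
        return h**2
    if effect == "imprinting":
        return h
    raise ValueError(f"unknown effect type {effect!r}")


def genetic_variance(effect: str, mixing_proportions: np.ndarray,
                     class_variances: np.ndarray, freqs: np.ndarray) -> float:
    """Genetic variance of one effect type from its mixture-class variances."""
    pi = np.asarray(mixing_proportions, dtype=float)
    v = np.asarray(class_variances, dtype=float)
    if pi.shape != v.shape:
        raise ValueError(f"mixing proportions {pi.shape} and class variances {v.shape} differ")
    if (v < 0).any():
        raise ValueError("class variances must be non-negative")
    return float(coding_column_variances(effect, freqs).sum() * (pi @ v))


def additive_variance(mixing_proportions, class_variances, freqs) -> float:
    return genetic_variance("additive", mixing_proportions, class_variances, freqs)


def dominance_variance(mixing_proportions, class_variances, freqs) -> float:
    return genetic_variance("dominance", mixing_proportions, class_variances, freqs)


def imprinting_variance(mixing_proportions, class_variances, freqs) -> float:
    return genetic_variance("imprinting", mixing_proportions, class_variances, freqs)


def heritabilities(components: Mapping[str, float]) -> dict[str, float]:
    """Proportions of phenotypic variance for the components present.

    ``components`` maps names among {additive, dominance, imprinting,
    litter, residual} to variances.  Returns one proportion per component
    (``h2_additive``, ..., ``l2``, ``e2``) plus ``narrow_h2`` (the additive
    share; parent-of-origin independent by convention) and ``broad_H2``
    (total genetic share).  Proportions sum to one over the components
    present.
    """
    unknown = set(components) - {"additive", "dominance", "imprinting", "litter", "residual"}
    if unknown:
        raise ValueError(f"unknown variance components: {sorted(unknown)}")
    values = {k: float(v) for k, v in components.items()}
    if any(v < 0 for v in values.values()):
        raise ValueError("variance components must be non-negative")
    total = sum(values.values())
    if total <= 0:
        raise ValueError("total variance must be positive")
    out: dict[str, float] = {}
    for name, v in values.items():
        key = {"litter": "l2", "residual": "e2"}.get(name, f"h2_{name}")
        out[key] = v / total
    out["narrow_h2"] = values.get("additive", 0.0) / total
    out["broad_H2"] = sum(values.get(e, 0.0) for e in GENETIC_EFFECTS) / total
    return out


@dataclasses.dataclass
class VarianceDecomposition:
    """Posterior summary of variance components and their proportions.

    ``components`` and ``component_sds`` map component names to posterior
    means and SDs on the phenotypic scale; ``proportions`` and
    ``proportion_sds`` hold the matching shares of total variance
    (posterior means of per-sample proportions).
    """

    components: dict[str, float]
    component_sds: dict[str, float]
    proportions: dict[str, float]
    proportion_sds: dict[str, float]
    narrow_h2: float
    broad_H2: float

    @classmethod
    def from_samples(cls, samples: Mapping[str, np.ndarray]) -> "VarianceDecomposition":
        """Build from per-saved-iteration component samples.

        Proportions are computed per MCMC sample and then averaged, so the
        reported shares are posterior means of the shares, consistent with
        using posterior means as point estimates throughout.
        """
        names = list(samples)
        arr = np.column_stack([np.asarray(samples[k], float) for k in names])
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("need at least one sample per component")
        totals = arr.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("non-positive total variance in a sample")
        props = arr / totals[:, None]
        comp_mean = dict(zip(names, arr.mean(axis=0)))
        genetic = [k for k in names if k in GENETIC_EFFECTS]
        narrow = (arr[:, names.index("additive")] / totals).mean() if "additive" in names else 0.0
        broad = (arr[:, [names.index(k) for k in genetic]].sum(axis=1) / totals).mean()
        def _pname(k):
            return {"litter": "l2", "residual": "e2"}.get(k, f"h2_{k}")
        return cls(
            components=comp_mean,
            component_sds=dict(zip(names, arr.std(axis=0, ddof=1) if arr.shape[0] > 1
                                   else np.zeros(arr.shape[1]))),
            proportions={_pname(k): float(m) for k, m in zip(names, props.mean(axis=0))},
            proportion_sds={_pname(k): float(s) for k, s in
                            zip(names, props.std(axis=0, ddof=1) if arr.shape[0] > 1
                                else np.zeros(arr.shape[1]))},
            narrow_h2=float(narrow),
            broad_H2=float(broad),
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, est in self.components.items():
            pname = {"litter": "l2", "residual": "e2"}.get(name, f"h2_{name}")
            rows.append((name, est, self.component_sds[name],
                         self.proportions[pname], self.proportion_sds[pname]))
        return pd.DataFrame(rows, columns=["component", "estimate", "posterior_sd",
                                           "proportion", "proportion_sd"])
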