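"""Model comparison (pseudo Bayes factors) and hold-out validation.

Model comparison uses per-observation conditional predictive ordinates
(CPO), estimated as the harmonic mean over saved MCMC iterations of the
observation's conditional density N(y_i; fitted_i, s2_e).  Twice the log
ratio of pseudo-marginal likelihoods (sums of log CPOs), 2lnK, is read on
the conventional evidence bands: 2-6 positive, 6-10 very strong, above 10
decisive.

Validation splits by birth date, computes reliability
r^2 = cor^2(prediction, y_c) / h2_yc, tests reliability differences
against the additive baseline with the Hotelling-Williams t test for
dependent correlations sharing y_c, and measures bias by ordinary least
squares of y_c on the predictions (slope 1, intercept 0 = unbiased).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import PhenotypeTable

__all__ = [
    "ModelComparison",
    "ValidationReport",
    "pseudo_bayes_factor",
    "evidence_label",
    "compare_models",
    "split_by_date",
    "reliability",
    "h2_of_corrected_phenotype",
    "hotelling_williams_test",
    "bias_regression",
    "validate_predictions",
]


def evidence_label(two_ln_k: float) -> str:
    if two_ln_k < 0:
        return "negative"
    if two_ln_k < 2:
        return "weak"
    if two_ln_k < 6:
        return "positive"
    if two_ln_k <= 10:
        return "very strong"
    return "decisive"


def pseudo_bayes_factor(cpo_alt: np.ndarray, cpo_base: np.ndarray) -> tuple[float, str]:
    """2lnK between two models from their per-observation CPO vectors."""
    a = np.asarray(cpo_alt, float)
    b = np.asarray(cpo_base, float)
    if a.shape != b.shape:
        raise ValueError("CPO vectors must cover the same observations")
    for name, v in (("alternative", a), ("baseline", b)):
        bad = ~np.isfinite(v) | (v <= 0)
        if bad.any():
            raise ValueError(f"non-positive or non-finite CPO in {name} model "
                             f"at observation {int(np.flatnonzero(bad)[0])}")
    two_ln_k = float(2.0 * (np.log(a).sum() - np.log(b).sum()))
    return two_ln_k, evidence_label(two_ln_k)


@dataclasses.dataclass
class ModelComparison:
    """Per-model LPML and evidence versus the additive baseline."""

    lpml: dict[str, float]
    two_ln_k: dict[str, float]
    labels: dict[str, str]
    baseline: str = "A"

    def to_frame(self) -> pd.DataFrame:
        rows = [(m, self.lpml[m], self.two_ln_k[m], self.labels[m])
                for m in self.lpml]
        return pd.DataFrame(rows, columns=["model", "lpml", "two_ln_k_vs_" + self.baseline,
                                           "evidence"])


def compare_models(cpos: dict[str, np.ndarray], baseline: str = "A") -> ModelComparison:
    """Pseudo-Bayes-factor comparison of several fitted models."""
    if baseline not in cpos:
        raise ValueError(f"baseline model {baseline!r} not among {list(cpos)}")
    lpml, bf, labels = {}, {}, {}
    for name, cpo in cpos.items():
        k, lab = pseudo_bayes_factor(cpo, cpos[baseline])
        lpml[name] = float(np.log(np.asarray(cpo, float)).sum())
        bf[name] = k
        labels[name] = lab
    return ModelComparison(lpml=lpml, two_ln_k=bf, labels=labels, baseline=baseline)


def split_by_date(phenotypes: PhenotypeTable, cutoff_date) -> tuple[np.ndarray, np.ndarray]:
    """Train/validation sample ids: born before the cutoff train, on/after validate."""
    cutoff = pd.Timestamp(cutoff_date)
    frame = phenotypes.frame
    is_val = frame["birth_date"] >= cutoff
    train = frame.loc[~is_val, "id"].to_numpy()
    val = frame.loc[is_val, "id"].to_numpy()
    if len(train) == 0:
        raise ValueError(f"no individuals born before {cutoff.date()}: empty training set")
    if len(val) == 0:
        raise ValueError(f"no individuals born on/after {cutoff.date()}: empty validation set")
    return train, val


def h2_of_corrected_phenotype(sigma2_a: float, sigma2_l: float, sigma2_e: float) -> float:
    """h2_yc = s2_a / (s2_a + s2_l + s2_e); computed once (additive fit) and
    reused to scale reliabilities for every model."""
    denom = sigma2_a + sigma2_l + sigma2_e
    if denom <= 0:
        raise ValueError("total variance must be positive")
    return sigma2_a / denom


def reliability(predictions: np.ndarray, y_c: np.ndarray, h2_yc: float) -> float:
    """Squared correlation of prediction with y_c, divided by h2_yc.

    The definition does not cap at 1.
    """
    if not 0.0 < h2_yc <= 1.0:
        raise ValueError("h2_yc must lie in (0, 1]")
    p = np.asarray(predictions, float)
    y = np.asarray(y_c, float)
    if p.size != y.size or p.size < 3:
        raise ValueError("need at least 3 aligned prediction/phenotype pairs")
    if np.var(p) == 0 or np.var(y) == 0:
        raise ValueError("zero-variance predictions or phenotypes")
    r = float(np.corrcoef(p, y)[0, 1])
    return r * r / h2_yc


def hotelling_williams_test(r13: float, r23: float, r12: float, n: int
                            ) -> tuple[float, float]:
    """Williams' t test for two dependent correlations sharing variable 3.

    Here variables 1 and 2 are the predictions of two models and variable
    3 is y_c.  Returns the t statistic (df = n - 3) and the two-sided
    p-value.
    """
    if n < 4:
        raise ValueError("need n >= 4 (df = n - 3 >= 1)")
    for name, r in (("r13", r13), ("r23", r23), ("r12", r12)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    if r13 == r23:
        return 0.0, 1.0
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if detR <= -1e-12:
        raise ValueError("inconsistent correlation triple (|R| <= 0)")
    detR = max(detR, 0.0)
    rbar = 0.5 * (r13 + r23)
    denom = 2.0 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1.0 - r12) ** 3
    if denom <= 0:
        raise ValueError("degenerate denominator in Williams statistic")
    t = (r13 - r23) * np.sqrt((n - 1) * (1.0 + r12) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def bias_regression(y_c: np.ndarray, predictions: np.ndarray) -> dict[str, float]:
    """OLS of y_c on predictions; slope 1 and intercept 0 mean no bias."""
    y = np.asarray(y_c, float)
    p = np.asarray(predictions, float)
    if y.size != p.size or y.size < 3:
        raise ValueError("need at least 3 aligned pairs")
    if np.var(p) == 0:
        raise ValueError("zero prediction variance")
    res = stats.linregress(p, y)
    mean_y = float(y.mean())
    return {
        "slope": float(res.slope),
        "slope_se": float(res.stderr),
        "intercept": float(res.intercept),
        "intercept_mean_ratio": float(res.intercept / mean_y) if mean_y != 0 else np.nan,
    }


@dataclasses.dataclass
class ValidationReport:
    """Hold-out evaluation of several models against an additive baseline."""

    cutoff_date: pd.Timestamp
    n_train: int
    n_validation: int
    h2_yc: float
    reliability_table: pd.DataFrame   # model x {r2_GTV, r2_GBV, p-values vs baseline}
    bias_table: pd.DataFrame          # model x {slope, slope_se, intercept ratio} per scope

    def __str__(self) -> str:
        return (f"validation split at {self.cutoff_date.date()}: "
                f"{self.n_train} train / {self.n_validation} validation, "
                f"h2_yc = {self.h2_yc:.3f}\n\n"
                + self.reliability_table.to_string(index=False) + "\n\n"
                + self.bias_table.to_string(index=False))


def validate_predictions(predictions: dict[str, dict[str, np.ndarray]],
                         y_val: np.ndarray, h2_yc: float,
                         cutoff_date, n_train: int,
                         baseline: str = "A") -> ValidationReport:
    """Build reliability and bias tables for hold-out predictions.

    ``predictions[model][scope]`` holds validation-set predictions for
    scope in {"GBV", "GTV"}.  Reliability differences against the baseline
    model are tested per scope with the Hotelling-Williams t test applied
    to the correlations with y_c.
    """
    if baseline not in predictions:
        raise ValueError(f"baseline {baseline!r} missing from predictions")
    y = np.asarray(y_val, float)
    n = y.size
    rel_rows, bias_rows = [], []
    for name, scopes in predictions.items():
        row = {"model": name}
        for scope in ("GTV", "GBV"):
            pred = np.asarray(scopes[scope], float)
            row[f"r2_{scope}"] = reliability(pred, y, h2_yc)
            if name == baseline:
                row[f"p_{scope}"] = np.nan
            else:
                base = np.asarray(predictions[baseline][scope], float)
                r13 = float(np.corrcoef(pred, y)[0, 1])
                r23 = float(np.corrcoef(base, y)[0, 1])
                r12 = float(np.corrcoef(pred, base)[0, 1])
                _, p = hotelling_williams_test(r13, r23, r12, n)
                row[f"p_{scope}"] = p
            reg = bias_regression(y, pred)
            bias_rows.append({"model": name, "scope": scope, **reg})
        rel_rows.append(row)
    return ValidationReport(
        cutoff_date=pd.Timestamp(cutoff_date), n_train=int(n_train),
        n_validation=n, h2_yc=float(h2_yc),
        reliability_table=pd.DataFrame(rel_rows),
        bias_table=pd.DataFrame(bias_rows),
    )
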