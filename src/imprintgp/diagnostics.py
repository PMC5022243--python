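"""MCMC convergence diagnostics: batch-means time-series standard error."""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["MCMCError", "mcmc_standard_error"]


@dataclasses.dataclass
class MCMCError:
    se: float
    relative: float
    converged: bool
    relative_to: str  # "mean" or "sd" (used when the posterior mean is zero)


def mcmc_standard_error(samples: np.ndarray, threshold: float = 0.05) -> MCMCError:
    """Batch-means time-series standard error of a posterior mean.

    Splits the chain into ``floor(sqrt(T))`` consecutive batches and uses
    the SD of batch means over ``sqrt(n_batches)``, which is robust to the
    autocorrelation of Gibbs output.  The chain is flagged as converged
    when the SE is below ``threshold`` relative to the absolute posterior
    mean; for a zero posterior mean the posterior SD is used as the
    reference instead (noted in ``relative_to``).
    """
    x = np.asarray(samples, dtype=float).ravel()
    T = x.size
    if T < 10:
        raise ValueError(f"need at least 10 samples for a time-series SE, got {T}")
    nb = int(math.floor(math.sqrt(T)))
    bs = T // nb
    bm = x[: nb * bs].reshape(nb, bs).mean(axis=1)
    se = float(bm.std(ddof=1) / math.sqrt(nb))
    mean = float(x.mean())
    if mean != 0.0:
        rel = se / abs(mean)
        ref = "mean"
    else:
        sd = float(x.std(ddof=1))
        rel = se / sd if sd > 0 else 0.0
        ref = "sd"
    return MCMCError(se=se, relative=rel, converged=rel < threshold, relative_to=ref)
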