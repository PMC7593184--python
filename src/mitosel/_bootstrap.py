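"""Bias-corrected (BC) percentile bootstrap confidence intervals."""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def bc_percentile_ci(
    theta_hat: float, boot: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Bias-corrected percentile CI from a bootstrap sample.

    The bias-correction constant is z0 = Phi^-1(fraction of bootstrap
    replicates below the point estimate); the interval endpoints are the
    bootstrap quantiles at Phi(2 z0 +/- z_{alpha/2}). Degenerate
    bootstrap distributions collapse the interval to the point estimate.
    """

    boot = np.asarray(boot, dtype=float)
    boot = boot[np.isfinite(boot)]
    if boot.size == 0 or np.all(boot == boot[0]):
        return (float(theta_hat), float(theta_hat))
    prop_below = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
    # clip away from 0/1 so z0 stays finite when the estimate is extreme
    prop_below = np.clip(prop_below, 0.5 / boot.size, 1 - 0.5 / boot.size)
    z0 = norm.ppf(prop_below)
    z = norm.ppf(1 - alpha / 2)
    lo_q = norm.cdf(2 * z0 - z)
    hi_q = norm.cdf(2 * z0 + z)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return (float(lo), float(hi))
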