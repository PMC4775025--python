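"""Statistical comparison of two model configurations over CV repetitions.

Each repeated nested cross-validation yields one metric value (R^2 or
RMSE) per repetition; two model configurations are compared through the
difference in the mean of those distributions. The default test is an
unpaired two-sample t-test with the Welch unequal-variance correction,
reported with its (1 - alpha) confidence interval on the mean difference;
a paired mode is available when both models were run with identical base
seeds (shared fold groupings). The Mann-Whitney rank-sum test serves as a
distribution-free cross-check (p-value only, no CI): exact enumeration
for small samples (both n < 20), normal approximation with tie correction
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ComparisonResult", "compare_models"]

_EXACT_MW_BELOW = 20


@dataclass(frozen=True)
class ComparisonResult:
    """Mean difference between two metric distributions with CI and p-value.

    The difference is mean(a) - mean(b). For the t-test the confidence
    interval brackets the mean difference; Mann-Whitney reports no CI.
    ``significant`` is ``p_value < alpha``.
    """

    metric: str
    mean_difference: float
    ci_low: float | None
    ci_high: float | None
    p_value: float
    test: str
    alpha: float
    significant: bool

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "test": self.test,
            "mean_difference": self.mean_difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def compare_models(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    metric: str = "r2",
    test: str = "t",
    alpha: float = 0.05,
    paired: bool = False,
) -> ComparisonResult:
    """Compare two sets of per-repetition metric values.

    Parameters
    ----------
    samples_a, samples_b : per-repetition metric values for models A and B.
    metric : label carried into the result ("r2" or "rmse", say).
    test : "t" (Welch unpaired by default, or paired) or "mann_whitney".
    alpha : significance level; p < alpha flags the difference significant.
    paired : pair samples by repetition (requires equal lengths; only
        meaningful when both runs shared base seeds / fold groupings).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per model")
    if test not in ("t", "mann_whitney"):
        raise ValueError(f"test must be 't' or 'mann_whitney', got {test!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    diff = float(a.mean() - b.mean())

    if test == "t":
        if paired:
            if a.size != b.size:
                raise ValueError("paired comparison requires equal sample counts")
            d = a - b
            if d.std(ddof=1) == 0.0:
                raise ValueError("zero-variance paired differences; t-test undefined")
            res = stats.ttest_rel(a, b)
            se = float(d.std(ddof=1) / np.sqrt(d.size))
            df = d.size - 1
        else:
            if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
                raise ValueError("both samples have zero variance; t-test undefined")
            res = stats.ttest_ind(a, b, equal_var=False)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se = float(np.sqrt(va / a.size + vb / b.size))
            # Welch-Satterthwaite degrees of freedom
            df = (va / a.size + vb / b.size) ** 2 / (
                (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
            )
        p = float(res.pvalue)
        tcrit = float(stats.t.ppf(1 - alpha / 2, df))
        ci_low, ci_high = diff - tcrit * se, diff + tcrit * se
    else:
        method = "exact" if max(a.size, b.size) < _EXACT_MW_BELOW else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        p = float(res.pvalue)
        ci_low = ci_high = None

    return ComparisonResult(
        metric=metric,
        mean_difference=diff,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        test=test,
        alpha=alpha,
        significant=p < alpha,
    )
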