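"""Statistical primitives shared by every pipeline stage.

Welch's unpaired two-tailed t test, chi-square goodness of fit, one-sided
binomial enrichment, and Benjamini-Hochberg FDR adjustment.  These are thin,
validated wrappers over scipy / statsmodels that return a uniform
:class:`TestResult` record so the assay modules can report statistics
consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "welch_t",
    "chi2_gof",
    "binomial_enrichment",
    "bh_adjust",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` may be fractional (Welch-Satterthwaite).  ``p_adj`` is filled only
    after multiple-testing adjustment of a family containing this test.
    """

    statistic: float
    p: float
    method: str
    df: float | None = None
    estimate: float | None = None
    p_adj: float | None = None
    extra: dict = field(default_factory=dict)


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Unpaired two-tailed t test with Welch's correction.

    Parameters
    ----------
    a, b:
        The two samples; each needs at least two observations and at least
        one of them must have positive variance.

    Returns
    -------
    TestResult with the t statistic, Welch-Satterthwaite degrees of freedom,
    the two-tailed p value, and the mean difference ``mean(a) - mean(b)`` as
    the estimate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        # Degenerate: identical constants compare as "no difference";
        # scipy returns nan here, but t = 0 / p = 1 is the useful answer
        # when both groups are exactly constant and equal.
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, "welch_t", df=float(a.size + b.size - 2),
                              estimate=0.0)
        raise ValueError("both samples have zero variance and unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite df (scipy >= 1.10 exposes res.df; recompute for
    # independence from scipy internals).
    na, nb = a.size, b.size
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    df = num / den
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        method="welch_t",
        df=float(df),
        estimate=float(a.mean() - b.mean()),
    )


def chi2_gof(observed: Sequence[float],
             expected_weights: Sequence[float] | None = None) -> TestResult:
    """Chi-square goodness-of-fit test of observed counts against a ratio.

    ``expected_weights`` are relative weights (e.g. ``[1, 2, 1]`` for a
    Mendelian 1:2:1 cross); they are normalized and scaled to the observed
    total.  Degrees of freedom = k - 1.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("chi2_gof needs at least 2 categories (df >= 1)")
    if obs.sum() <= 0:
        raise ValueError("observed counts sum to zero")
    if expected_weights is None:
        w = np.ones_like(obs)
    else:
        w = np.asarray(expected_weights, dtype=float)
    if w.shape != obs.shape:
        raise ValueError("weights shape mismatch")
    if np.any(w <= 0):
        raise ValueError("expected weights must be positive")
    expected = w / w.sum() * obs.sum()
    stat, p = sps.chisquare(obs, f_exp=expected)
    return TestResult(float(stat), float(p), "chi2_gof", df=float(obs.size - 1),
                      extra={"expected": expected})


def binomial_enrichment(carriers: int, n_trials: int,
                        population_freq: float,
                        two_sided: bool = False) -> TestResult:
    """Exact binomial test for enrichment of carriers over a reference rate.

    One-sided upper by default: ``p = P(X >= carriers | Bin(n, freq))``,
    the probability of observing at least this many carriers by chance.
    ``two_sided=True`` doubles the one-sided p, capped at 1.
    """
    if not (0 <= carriers <= n_trials):
        raise ValueError("carriers must be in [0, n_trials]")
    if not (0.0 < population_freq < 1.0):
        raise ValueError("population_freq must be in (0, 1)")
    p = float(sps.binom.sf(carriers - 1, n_trials, population_freq))
    if two_sided:
        p = min(1.0, 2.0 * p)
    return TestResult(float(carriers), p,
                      "binomial_enrichment" + ("_two_sided" if two_sided else ""),
                      estimate=carriers / n_trials if n_trials else np.nan)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj
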