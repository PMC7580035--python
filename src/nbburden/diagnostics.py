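"""Model-fit diagnostics.

``ks_overdispersion`` quantifies how badly a constant-rate (Poisson/
binomial) model fits observed per-bin counts: it fits the genome-wide
constant rate by maximum likelihood, repeatedly simulates count vectors
under it, and records the two-sample Kolmogorov-Smirnov statistic
between observed and simulated counts.  Poisson-like data yields small
statistics; overdispersed data pushes the whole distribution toward 1.

``qq_table`` prepares expected-vs-observed -log10 p coordinates for
calibration plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class KSReport:
    """KS statistics of observed counts vs constant-rate simulations."""

    statistics: np.ndarray  # one per replicate
    lambda_hat: float  # per-base MLE rate
    n_bins: int

    def ecdf(self, x) -> np.ndarray:
        """Empirical CDF of the replicate KS statistics."""
        x = np.atleast_1d(x)
        srt = np.sort(self.statistics)
        return np.searchsorted(srt, x, side="right") / len(srt)


def ks_overdispersion(
    counts, bin_length: int, reps: int = 100, seed: int | None = None
) -> KSReport:
    """Constant-rate goodness-of-fit via repeated two-sample KS tests.

    Parameters
    ----------
    counts
        Observed per-bin pooled counts for one disease (n >= 2 bins).
    bin_length
        Training bin length in bp; the per-base MLE rate is
        ``sum(counts) / (n * bin_length)`` and each replicate draws n
        Poisson counts with mean ``rate * bin_length``.
    reps
        Number of simulation replicates (default 100).
    """
    y = np.asarray(counts, dtype=np.int64)
    if len(y) < 2:
        raise ValueError("need at least 2 bins")
    if y.sum() == 0:
        raise ValueError("all counts are zero")
    rng = np.random.default_rng(seed)
    lam_per_base = y.sum() / (len(y) * bin_length)
    mean_per_bin = lam_per_base * bin_length
    ks = np.empty(reps)
    for r in range(reps):
        sim = rng.poisson(mean_per_bin, size=len(y))
        ks[r] = stats.ks_2samp(y, sim).statistic
    return KSReport(statistics=ks, lambda_hat=lam_per_base, n_bins=len(y))


def qq_table(pvalues) -> np.ndarray:
    """Expected vs observed -log10 p for a Q-Q calibration plot.

    Returns an array of shape (n, 2): column 0 the expected uniform
    quantiles ``-log10(i/(n+1))``, column 1 the sorted observed values.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    expected = -np.log10(np.arange(1, n + 1) / (n + 1))
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return np.column_stack([expected, observed])
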