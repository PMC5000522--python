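"""Bayesian likelihood analysis of dimensionless parameters per regime.

For a dimensionless ratio lambda and a signaling regime (jkl), Bayes'
theorem gives the probability of the regime given the parameter value,

    P(jkl | lambda) = P(lambda | jkl) P(jkl) / P(lambda),

estimated per log10(lambda) bin from the scan records.  Because every
lambda is a signed product of 2 or 4 log-uniformly sampled parameters, the
prior P(lambda) is known exactly: log10(lambda) is a sum of independent
uniforms, i.e. a scaled Irwin-Hall (triangular for two factors,
piecewise-cubic for four), so no Monte-Carlo noise enters the denominator.
Curves are reported normalized by their maximum, L_jkl(lambda) =
P(jkl|lambda)/max P(jkl|lambda), with binomial errors propagated to first
order.

The same machinery drives the range-restriction study: each ratio is
restricted to the third of its support where the (smoothed) likelihood of a
target regime peaks, and the regime probabilities are recomputed on the
surviving subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial

import numpy as np
import pandas as pd

from .parameter_sampler import lambda_signs, lambda_support
from .regime_pipeline import REGIMES, aggregate_modes, regime_table

__all__ = [
    "LikelihoodCurve",
    "analytic_prior",
    "bayes_likelihood",
    "normalize_likelihood",
    "maximizing_interval",
    "auto_restrictions",
    "restriction_study",
]

#: default number of equal-width log10 bins over the analytic support
DEFAULT_BINS = 40
#: moving-average window used when locating likelihood maxima
SMOOTH_WINDOW = 3
#: bins with fewer scan records than this are flagged as unstable
LOW_COUNT = 10


@dataclass
class LikelihoodCurve:
    """Binned posterior P(jkl | lambda) for one ratio and one regime."""

    lambda_name: str
    regime: str
    edges: np.ndarray  # bin edges in log10 lambda
    prior: np.ndarray  # analytic P(lambda in bin)
    p_regime: float  # P(jkl)
    posterior: np.ndarray  # P(jkl | lambda) per bin
    errors: np.ndarray  # first-order standard errors of the posterior
    counts: np.ndarray  # regime records per bin
    L: np.ndarray = field(default=None)  # posterior / max posterior
    empty: bool = False

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def low_count(self) -> np.ndarray:
        return self.counts < LOW_COUNT

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda_name": self.lambda_name,
                "regime": self.regime,
                "bin_center": self.centers,
                "posterior": self.posterior,
                "L": self.L,
                "error": self.errors,
                "count": self.counts,
            }
        )


# ---------------------------------------------------------------------------
# analytic prior
# ---------------------------------------------------------------------------

def _irwin_hall_cdf(t, m: int):
    """CDF of the sum of m independent U(0,1) variables."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for k in range(m + 1):
        out += (-1) ** k * comb(m, k) * np.clip(t - k, 0.0, None) ** m
    return np.clip(out / factorial(m), 0.0, 1.0)


def analytic_prior(
    lambda_name: str,
    log10_range=(-2.0, 2.0),
    bins: int | np.ndarray = DEFAULT_BINS,
):
    """Exact per-bin prior mass of log10(lambda).

    log10(lambda) is a signed sum of m log-uniform draws, so its law is an
    m-fold convolution of uniforms: shifted and scaled Irwin-Hall.  Returns
    ``(edges, mass)`` where ``mass`` integrates to 1 over the support.
    """
    lo, hi = map(float, log10_range)
    signs = lambda_signs(lambda_name)
    m = len(signs)
    width = hi - lo
    offset = sum(lo if s > 0 else -hi for s in signs)
    support = lambda_support(lambda_name, log10_range)
    if np.isscalar(bins):
        edges = np.linspace(support[0], support[1], int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    cdf = _irwin_hall_cdf((edges - offset) / width, m)
    return edges, np.diff(cdf)


# ---------------------------------------------------------------------------
# Bayes posterior and normalization
# ---------------------------------------------------------------------------

def bayes_likelihood(
    log_lambda: pd.Series | np.ndarray,
    regimes: pd.Series | np.ndarray,
    lambda_name: str,
    regime: str,
    log10_range=(-2.0, 2.0),
    bins: int = DEFAULT_BINS,
) -> LikelihoodCurve:
    """Posterior P(jkl | lambda) per bin from scan records.

    ``log_lambda`` holds log10 of the ratio for every record and ``regimes``
    the (jkl) labels.  Hybrid regimes pool concrete ones via wildcards:
    "1k0" matches 100 and 110.  The prior in the denominator is analytic.
    """
    log_lambda = np.asarray(log_lambda, dtype=float)
    labels = np.asarray(regimes, dtype=str)
    edges, prior = analytic_prior(lambda_name, log10_range, bins)
    # wildcard regime match: non-0/1 characters (e.g. the k in "1k0") match
    # either digit, pooling the concrete regimes
    sel = np.ones(len(labels), dtype=bool)
    arr = labels.astype("U3")
    for pos, ch in enumerate(regime):
        if ch in "01":
            sel &= np.array([lab[pos] == ch for lab in arr])
    N = len(labels)
    N_r = int(sel.sum())
    if N_r == 0:
        z = np.zeros(len(prior))
        return LikelihoodCurve(
            lambda_name, regime, edges, prior, 0.0, z, z, z.astype(int),
            L=z, empty=True,
        )
    counts, _ = np.histogram(log_lambda[sel], bins=edges)
    p_regime = N_r / N
    with np.errstate(divide="ignore", invalid="ignore"):
        # (h/N_r) * (N_r/N) / prior = h / (N * prior)
        posterior = counts / (N * prior)
        posterior[prior == 0] = 0.0
        # first-order propagation: bin fraction and regime fraction binomial
        p1 = counts / N_r
        relvar = np.where(counts > 0, (1.0 - p1) / np.maximum(counts, 1), 0.0)
        relvar += (1.0 - p_regime) / N_r
        errors = posterior * np.sqrt(relvar)
        # empty bins: rule-of-three style upper bound
        upper = (3.0 / N_r) * p_regime / np.where(prior > 0, prior, np.inf)
        errors = np.where(counts == 0, upper, errors)
    return LikelihoodCurve(
        lambda_name, regime, edges, prior, p_regime, posterior, errors,
        counts,
    )


def normalize_likelihood(curve: LikelihoodCurve) -> LikelihoodCurve:
    """Attach L = posterior / max(posterior); flags all-zero curves."""
    peak = float(np.max(curve.posterior)) if len(curve.posterior) else 0.0
    if peak <= 0:
        curve.L = np.zeros_like(curve.posterior)
        curve.empty = True
    else:
        curve.L = curve.posterior / peak
    return curve


def _smooth(values: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def interval_cuts(
    lambda_name: str,
    log10_range=(-2.0, 2.0),
    k_intervals: int = 3,
    style: str = "width",
) -> np.ndarray:
    """Cut points splitting a ratio's log10 support into k intervals.

    ``style="width"`` gives equal log-width intervals (the low / medium /
    high vocabulary used when reporting directions); ``style="mass"`` gives
    equal analytic-prior-mass intervals, which is what the range-restriction
    study uses -- under the convolution-of-uniforms prior the outer
    equal-width thirds carry only ~1% of the mass each, so intersecting 18
    of them would leave an empty set at any feasible sample size.
    """
    lo, hi = lambda_support(lambda_name, log10_range)
    if style == "width":
        return np.linspace(lo, hi, k_intervals + 1)
    if style == "mass":
        edges, mass = analytic_prior(lambda_name, log10_range, bins=4000)
        cdf = np.concatenate([[0.0], np.cumsum(mass)])
        cuts = [lo]
        for q in range(1, k_intervals):
            cuts.append(float(np.interp(q / k_intervals, cdf, edges)))
        cuts.append(hi)
        return np.asarray(cuts)
    raise ValueError(f"unknown interval style {style!r}")


def maximizing_interval(
    curve: LikelihoodCurve,
    k_intervals: int = 3,
    smooth: bool = True,
    cuts: np.ndarray | None = None,
) -> int:
    """Index of the interval where the likelihood peaks.

    The support is split into ``k_intervals`` intervals (0 = low values,
    k-1 = high values; equal log-width unless explicit ``cuts`` are given)
    and the one with the largest mean (smoothed) normalized likelihood
    wins; ties go to the interval holding more posterior mass.
    """
    if curve.L is None:
        normalize_likelihood(curve)
    L = _smooth(curve.L) if smooth else curve.L
    centers = curve.centers
    if cuts is None:
        cuts = np.linspace(curve.edges[0], curve.edges[-1], k_intervals + 1)
    means, masses = [], []
    for i in range(k_intervals):
        mask = (centers >= cuts[i]) & (centers <= cuts[i + 1])
        means.append(float(L[mask].mean()) if mask.any() else 0.0)
        masses.append(float(curve.posterior[mask].sum()) if mask.any() else 0.0)
    best = np.lexsort((masses, means))[-1]
    return int(best)


INTERVAL_NAMES = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# range-restriction study
# ---------------------------------------------------------------------------

def auto_restrictions(
    ratios: pd.DataFrame,
    regimes: pd.Series,
    regime: str,
    log10_range=(-2.0, 2.0),
    bins: int = DEFAULT_BINS,
    k_intervals: int = 3,
    style: str = "mass",
) -> dict[str, int]:
    """Likelihood-maximizing interval per ratio for one regime."""
    out = {}
    for name in ratios.columns:
        curve = bayes_likelihood(
            ratios[name], regimes, name, regime, log10_range, bins
        )
        if curve.empty:
            continue
        cuts = interval_cuts(name, log10_range, k_intervals, style)
        out[name] = maximizing_interval(
            normalize_likelihood(curve), k_intervals, cuts=cuts
        )
    return out


def restriction_study(
    ratios: pd.DataFrame,
    regimes: pd.Series,
    restrictions: dict[str, int],
    log10_range=(-2.0, 2.0),
    k_intervals: int = 3,
    style: str = "mass",
) -> dict:
    """Regime probabilities after restricting ratios to chosen intervals.

    ``restrictions`` maps ratio names to interval indices (0 low .. k-1
    high) over each ratio's analytic support.  Returns the survival
    fraction, the restricted regime table (or None when nothing survives)
    and its mode aggregation.
    """
    mask = np.ones(len(ratios), dtype=bool)
    for name, interval in restrictions.items():
        cut = interval_cuts(name, log10_range, k_intervals, style)
        vals = ratios[name].to_numpy()
        mask &= (vals >= cut[interval]) & (vals <= cut[interval + 1])
    n_kept = int(mask.sum())
    out = {
        "survival_fraction": n_kept / len(ratios),
        "n_kept": n_kept,
        "table": None,
        "modes": None,
    }
    if n_kept:
        table = regime_table(pd.Series(np.asarray(regimes)[mask]))
        out["table"] = table
        out["modes"] = aggregate_modes(table)
    return out
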