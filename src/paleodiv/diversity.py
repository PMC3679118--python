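"""Rarefied richness and evenness on influx data.

Richness is estimated by individual-based rarefaction (Heck et al.): the
expected number of taxa E(T_n) in a random subsample of n individuals
drawn without replacement from a sample with per-taxon abundances N_i,

    E(T_n) = sum_i [ 1 - C(N - N_i, n) / C(N, n) ],      N = sum_i N_i.

Influx values are real numbers, so the binomial coefficients are
generalized to real arguments through the log-gamma function; a taxon with
N - N_i < n is guaranteed to appear in every subsample and contributes
exactly 1.

Because influx sums in low-count records are far below one particle
cm^-2 yr^-1, rarefying at the record's minimum influx sum n directly is
uninformative. Instead the influx matrix is rescaled so that its minimum
bin sum becomes n' and rarefied at n', for n' = 1..R (R = 500 by default);
per-bin medians and percentiles over the n' replicates summarize the
resulting E(T_n') surface. The rescaling leaves within-bin taxon
proportions untouched, so the whole ensemble is invariant to the overall
scale of the influxes.

Evenness is Hurlbert's probability of interspecific encounter,

    Delta_1 = N/(N - 1) * (1 - sum_i p_i^2),    p_i = N_i / N,

the probability that two individuals drawn at random belong to different
taxa, with a finite-sample correction evaluated at real-valued N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .timeseries_stats import minimax

logger = logging.getLogger(__name__)

DEFAULT_R = 500
DEFAULT_PERCENTILES = (5, 25, 75, 95)


@dataclass(frozen=True)
class RarefactionEnsemble:
    """E(T_n') surface over bins x n' replicates with summary series."""

    E: np.ndarray                 # (n_bins, R)
    n_prime_values: np.ndarray    # 1..R
    bin_ages: np.ndarray
    n: float                      # minimum influx sum of the record
    median_series: np.ndarray
    percentile_series: dict       # level -> series
    minimax_series: np.ndarray

    @property
    def R(self) -> int:
        return int(self.n_prime_values[-1]) if self.n_prime_values.size else 0


@dataclass(frozen=True)
class EvennessSeries:
    """Hurlbert PIE per bin, with the proportions it was computed from."""

    bin_ages: np.ndarray
    delta1: np.ndarray
    p: np.ndarray  # (n_bins, n_taxa) per-bin taxon proportions


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _expected_richness(abundances: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized E(T_n) for one abundance vector at many subsample sizes.

    ``n`` may be real-valued; each returned value is the sum over taxa of
    the probability that the taxon enters a subsample of that size.
    """
    a = abundances[abundances > 0]
    N = float(abundances.sum())
    n = np.asarray(n, dtype=float)
    n_col = n[:, None]  # (K, 1) against (S,)
    drawn_surely = (N - a)[None, :] < n_col
    with np.errstate(invalid="ignore", divide="ignore"):
        log_absent = (
            gammaln(N - a[None, :] + 1.0)
            - gammaln(N - a[None, :] - n_col + 1.0)
            - gammaln(N + 1.0)
            + gammaln(N - n_col + 1.0)
        )
        p_present = np.where(drawn_surely, 1.0, 1.0 - np.exp(log_absent))
    return p_present.sum(axis=1)


def heck_rarefaction(abundances, n, integer_counts: bool = False) -> float:
    """Expected taxonomic richness E(T_n) of a single sample.

    Parameters
    ----------
    abundances : array-like of non-negative numbers
        Per-taxon abundances (counts or influxes; need not be integers).
    n : positive number, <= sum(abundances)
        Subsample size.
    integer_counts : bool
        Round abundances to the nearest integers first (to mimic software
        that evaluates the factorials on integers only).
    """
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        raise ValueError("abundances must be one-dimensional")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    if integer_counts:
        a = np.round(a)
    N = a.sum()
    if N <= 0:
        raise ValueError("all-zero abundances: rarefaction undefined")
    if n <= 0:
        raise ValueError("subsample size n must be > 0")
    if n > N * (1 + 1e-12):
        raise ValueError(f"subsample size n = {n} exceeds total abundance N = {N}")
    return float(_expected_richness(a, np.array([min(float(n), float(N))]))[0])


def scale_to_nprime(influx_matrix, n_prime):
    """Rescale an influx matrix so its minimum bin (row) sum equals ``n_prime``.

    Pure multiplication by ``n_prime / n`` with n the current minimum row
    sum: within-bin taxon proportions are unchanged.
    """
    values = influx_matrix.to_numpy(dtype=float) if hasattr(influx_matrix, "to_numpy") \
        else np.asarray(influx_matrix, dtype=float)
    if n_prime <= 0:
        raise ValueError("n_prime must be >= 1")
    n = values.sum(axis=1).min()
    if n <= 0:
        raise ValueError(
            "minimum bin influx sum is 0; aggregate with find_min_window before rarefying"
        )
    scaled = values * (float(n_prime) / n)
    if hasattr(influx_matrix, "to_numpy"):
        return pd.DataFrame(scaled, index=influx_matrix.index, columns=influx_matrix.columns)
    return scaled


def rarefaction_ensemble(record, R: int = DEFAULT_R,
                         percentiles=DEFAULT_PERCENTILES) -> RarefactionEnsemble:
    """Replicated rarefaction over n' = 1..R on a resampled record.

    ``record`` may be a ResampledRecord or a bins x taxa influx matrix
    (DataFrame indexed by bin age, or plain array). For each n' the whole
    matrix is rescaled so its minimum bin sum equals n', then every bin is
    rarefied at subsample size n' (capped at the bin's scaled total, which
    only binds for the minimum bin itself).
    """
    if hasattr(record, "influx"):
        influx = record.influx
        bin_ages = np.asarray(record.bin_ages, dtype=float)
    elif isinstance(record, pd.DataFrame):
        influx = record
        bin_ages = np.asarray(record.index, dtype=float)
    else:
        influx = pd.DataFrame(np.asarray(record, dtype=float))
        bin_ages = np.arange(len(influx), dtype=float)
    if R < 1:
        raise ValueError("R must be >= 1")

    values = influx.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError(
            "bin with zero influx sum; aggregate with find_min_window before rarefying"
        )
    n = float(totals.min())
    n_prime = np.arange(1, R + 1, dtype=float)

    E = np.empty((values.shape[0], R))
    for b in range(values.shape[0]):
        # scaling by n'/n multiplies every abundance; fold it into the
        # abundance vector per n' and cap the subsample at the bin total
        scale = n_prime / n
        scaled_total = totals[b] * scale
        sub = np.minimum(n_prime, scaled_total)
        E[b] = _rarefy_scaled(values[b], scale, sub)

    median = np.median(E, axis=1)
    pct = {float(q): np.percentile(E, q, axis=1) for q in percentiles}
    if median.size and np.ptp(median) > 0:
        mm = minimax(median)
    else:
        mm = np.zeros_like(median)
    return RarefactionEnsemble(
        E=E,
        n_prime_values=np.arange(1, R + 1),
        bin_ages=bin_ages,
        n=n,
        median_series=median,
        percentile_series=pct,
        minimax_series=mm,
    )


def _rarefy_scaled(abund: np.ndarray, scale: np.ndarray, sub: np.ndarray) -> np.ndarray:
    """E(T) for one bin under many uniform scalings and subsample sizes."""
    a = abund[abund > 0]
    N0 = a.sum()
    A = a[None, :] * scale[:, None]          # (K, S)
    N = N0 * scale[:, None]                  # (K, 1)
    m = sub[:, None]
    drawn_surely = (N - A) < m
    with np.errstate(invalid="ignore", divide="ignore"):
        log_absent = (
            gammaln(N - A + 1.0)
            - gammaln(N - A - m + 1.0)
            - gammaln(N + 1.0)
            + gammaln(N - m + 1.0)
        )
        p_present = np.where(drawn_surely, 1.0, 1.0 - np.exp(log_absent))
    return p_present.sum(axis=1)


# ---------------------------------------------------------------------------
# Evenness
# ---------------------------------------------------------------------------

def hurlbert_pie(abundances) -> float:
    """Hurlbert's probability of interspecific encounter Delta_1.

    Evaluated with real-valued total N; when N <= 1 the finite-sample
    factor N/(N-1) is dropped (logged) because it is undefined or negative
    there.
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    N = a.sum()
    if N <= 0:
        raise ValueError("all-zero abundances: evenness undefined")
    p = a / N
    simpson = 1.0 - float(np.sum(p * p))
    if N <= 1:
        logger.info("total abundance N = %g <= 1; returning uncorrected 1 - sum(p^2)", N)
        return simpson
    return float(N / (N - 1.0) * simpson)


def evenness_series(record) -> EvennessSeries:
    """Per-bin Hurlbert PIE of a resampled record (or influx matrix)."""
    if hasattr(record, "influx"):
        influx = record.influx
        bin_ages = np.asarray(record.bin_ages, dtype=float)
    else:
        influx = record
        bin_ages = np.asarray(record.index, dtype=float)
    values = influx.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("bin with zero influx sum; evenness undefined there")
    p = values / totals[:, None]
    delta1 = np.array([hurlbert_pie(values[b]) for b in range(values.shape[0])])
    return EvennessSeries(bin_ages=bin_ages, delta1=delta1, p=p)


def group_percentages(counts, groups) -> pd.DataFrame:
    """Percent of tree / shrub / herb / other per sample (or bin).

    ``counts`` is a samples x taxa DataFrame, ``groups`` a taxon -> group
    Series. Rows with zero total are reported as missing (NaN), never 0/0.
    """
    from .record_io import GROUPS, SampleSeries

    if isinstance(counts, SampleSeries):
        groups = counts.groups
        counts = counts.counts
    if hasattr(counts, "influx"):  # ResampledRecord
        counts = counts.influx
    g = groups.reindex(counts.columns).fillna("other")
    sums = counts.T.groupby(g.values).sum().T
    sums = sums.reindex(columns=list(GROUPS), fill_value=0.0)
    total = sums.sum(axis=1)
    pct = sums.div(total, axis=0) * 100.0
    pct[total <= 0] = np.nan
    return pct
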