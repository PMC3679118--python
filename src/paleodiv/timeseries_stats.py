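"""Rescaling and window-wise comparison of diversity time series.

Long-term richness patterns are read off a minimax-rescaled series
((x - min) / range, mapping the series onto [0, 1]). Significance of
changes through time is assessed by grouping bins into adjacent fixed-width
time windows (1000 yr by default), comparing the windows with a
tie-corrected Kruskal-Wallis test, and — when that is significant —
running rank-based pairwise comparisons (the Conover procedure, the
nonparametric analogue of Fisher's LSD) summarized as a compact letter
display: two windows share a letter exactly when their pairwise p-value is
at or above alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_WIDTH = 1000.0
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class WindowComparison:
    """Fixed-width time-window comparison of a per-bin series."""

    window_starts: np.ndarray   # young edge of each non-empty window, cal BP
    width: float
    values: list                # per-window arrays of bin values
    medians: np.ndarray
    H: float
    p_value: float
    posthoc_p: np.ndarray | None  # k x k pairwise p matrix; None if KW n.s.
    letters: list
    alpha: float


def minimax(series) -> np.ndarray:
    """Rescale a series to [0, 1] by (x - min) / (max - min).

    A constant series maps to all zeros with a logged warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot minimax-rescale an empty series")
    rng = np.ptp(x)
    if rng == 0:
        logger.warning("constant series in minimax rescaling; returning zeros")
        return np.zeros_like(x)
    return (x - x.min()) / rng


def window_assign(bin_ages, values, width=DEFAULT_WINDOW_WIDTH):
    """Partition bins into adjacent half-open age windows ``[t, t + width)``.

    Windows tile from ``floor(min_age / width) * width`` upward (into the
    past); every bin falls in exactly one window; empty windows are
    dropped. Returns (window_starts, list of per-window value arrays).
    """
    ages = np.asarray(bin_ages, dtype=float)
    vals = np.asarray(values, dtype=float)
    if ages.size != vals.size:
        raise ValueError("bin_ages and values must have equal length")
    if ages.size == 0:
        return np.array([]), []
    idx = np.floor(ages / width).astype(int)
    starts = []
    grouped = []
    for k in np.unique(idx):
        starts.append(k * width)
        grouped.append(vals[idx == k])
    return np.asarray(starts, dtype=float), grouped


def kruskal_wallis(groups):
    """Tie-corrected Kruskal-Wallis H and chi-square p over >= 2 groups.

    When every observation is identical the statistic is 0 and p = 1
    (scipy refuses that degenerate case).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def posthoc_lsd(groups, alpha=DEFAULT_ALPHA):
    """Conover's rank-based pairwise comparisons after a Kruskal-Wallis test.

    t statistics are built from the pooled-rank means with the
    tie-corrected rank variance, referred to Student's t with N - k
    degrees of freedom; p-values are two-sided and unadjusted (single-level
    reporting at alpha). Returns (p_matrix, letters).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups for pairwise comparisons")
    sizes = np.array([len(g) for g in groups])
    if np.any(sizes == 0):
        raise ValueError("empty group in post-hoc comparison")
    N = int(sizes.sum())
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rank_means = np.array(
        [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]
    )

    H, _ = kruskal_wallis(groups)
    # tie-corrected total rank variance
    S2 = (np.sum(ranks ** 2) - N * (N + 1.0) ** 2 / 4.0) / (N - 1.0)
    df = N - k
    p = np.ones((k, k))
    if df > 0 and S2 > 0:
        factor = S2 * (N - 1.0 - H) / df
        factor = max(factor, 0.0)  # H can exceed N-1 only via rounding
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
                if se == 0:
                    pij = 1.0 if rank_means[i] == rank_means[j] else 0.0
                else:
                    t = (rank_means[i] - rank_means[j]) / se
                    pij = 2.0 * stats.t.sf(abs(t), df)
                p[i, j] = p[j, i] = min(pij, 1.0)
    letters = letter_display(p < alpha, order=np.argsort(-rank_means))
    return p, letters


def holm_adjust(p_matrix: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of the upper-triangle pairwise p-values."""
    p = np.array(p_matrix, dtype=float)
    iu = np.triu_indices_from(p, k=1)
    raw = p[iu]
    order = np.argsort(raw)
    m = raw.size
    adj = np.empty_like(raw)
    running = 0.0
    for rank, pos in enumerate(order):
        running = max(running, (m - rank) * raw[pos])
        adj[pos] = min(running, 1.0)
    p[iu] = adj
    p.T[iu] = adj
    return p


def letter_display(significant: np.ndarray, order=None) -> list:
    """Compact letter display from a boolean significance matrix.

    Insert-and-absorb construction: start from one class holding every
    group; for each significant pair split every class containing both;
    drop classes that became subsets of others. The result shares a letter
    between two groups if and only if their difference is not significant.
    ``order`` ranks groups for letter naming (default: input order).
    """
    sig = np.asarray(significant, dtype=bool)
    k = sig.shape[0]
    classes: list[set] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            nxt = []
            for c in classes:
                if i in c and j in c:
                    nxt.append(c - {i})
                    nxt.append(c - {j})
                else:
                    nxt.append(c)
            # absorb subsets / duplicates
            nxt.sort(key=len, reverse=True)
            kept: list[set] = []
            for c in nxt:
                if not any(c <= other for other in kept):
                    kept.append(c)
            classes = kept

    if order is None:
        order = np.arange(k)
    pos = {g: r for r, g in enumerate(order)}
    classes.sort(key=lambda c: min(pos[g] for g in c) if c else k)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = ["" for _ in range(k)]
    for ci, c in enumerate(classes):
        letter = alphabet[ci % len(alphabet)] * (ci // len(alphabet) + 1)
        for g in sorted(c):
            labels[g] += letter
    return ["".join(sorted(s)) for s in labels]


def compare_windows(bin_ages, values, width=DEFAULT_WINDOW_WIDTH,
                    alpha=DEFAULT_ALPHA, adjust=None) -> WindowComparison:
    """Full window comparison of a per-bin series.

    Groups bins into ``width``-yr windows, runs Kruskal-Wallis and, if
    significant at ``alpha``, the Conover pairwise procedure with a compact
    letter display; otherwise all windows share the single letter "a".
    ``adjust="holm"`` applies Holm correction to the pairwise p-values.
    """
    starts, grouped = window_assign(bin_ages, values, width)
    if len(grouped) == 0:
        raise ValueError("no bins to compare")
    medians = np.array([float(np.median(g)) for g in grouped])
    if len(grouped) == 1:
        return WindowComparison(starts, float(width), grouped, medians,
                                H=0.0, p_value=1.0, posthoc_p=None,
                                letters=["a"], alpha=alpha)
    H, p = kruskal_wallis(grouped)
    if p < alpha:
        p_mat, letters = posthoc_lsd(grouped, alpha=alpha)
        if adjust == "holm":
            p_mat = holm_adjust(p_mat)
            rank_means = np.array([np.median(g) for g in grouped])
            letters = letter_display(p_mat < alpha, order=np.argsort(-rank_means))
    else:
        p_mat = None
        letters = ["a"] * len(grouped)
    return WindowComparison(starts, float(width), grouped, medians,
                            H=H, p_value=p, posthoc_p=p_mat,
                            letters=letters, alpha=alpha)
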