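"""Rank-sum machinery behind the differential-expression module.

Large groups use the tie-corrected normal approximation (delegated to
:func:`scipy.stats.mannwhitneyu`, vectorised across genes). Small groups
(both sizes <= 8) use exact enumeration of every assignment of the observed
(possibly tied) ranks to the two groups, with the two-sided p defined as the
fraction of splits whose rank-sum deviates from its permutation mean at
least as much as the observed one. A seeded Monte-Carlo permutation variant
is available as an alternative test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm, rankdata

EXACT_MAX_GROUP = 8


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _tie_term(combined: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tie groups, per column."""
    n, g = combined.shape
    s = np.sort(combined, axis=0)
    starts = np.ones((n, g), dtype=bool)
    starts[1:] = s[1:] != s[:-1]
    run_id = np.cumsum(starts, axis=0, dtype=np.int64) - 1
    tie = np.empty(g)
    for j in range(g):
        t = np.bincount(run_id[:, j])
        tie[j] = (t.astype(np.float64) ** 3 - t).sum()
    return tie


def ranksum_p_asymptotic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (column): normal
    approximation with tie correction and continuity correction.

    Columns where every observation is identical have zero rank variance;
    their p is defined as 1.
    """
    x, y = _as_2d(x), _as_2d(y)
    n1, n2 = x.shape[0], y.shape[0]
    n = n1 + n2
    combined = np.vstack([x, y])
    ranks = rankdata(combined, axis=0)
    u1 = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    tie = _tie_term(combined)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    numer = np.abs(u1 - n1 * n2 / 2.0) - 0.5  # continuity correction
    p = np.ones_like(u1)
    ok = sigma2 > 0
    with np.errstate(invalid="ignore"):
        p[ok] = 2.0 * norm.sf(numer[ok] / np.sqrt(sigma2[ok]))
    return np.clip(p, 0.0, 1.0)


def ranksum_p_exact(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact permutation two-sided p per gene by full enumeration.

    p = #{splits with |W - mu| >= |W_obs - mu|} / C(n1+n2, n1), where W is
    the group-1 rank-sum and mu its permutation mean. Handles ties through
    midranks; feasible for small groups only.
    """
    x, y = _as_2d(x), _as_2d(y)
    n1, n2 = x.shape[0], y.shape[0]
    n = n1 + n2
    n_splits = math.comb(n, n1)
    if n_splits > 200_000:
        raise ValueError(f"exact enumeration infeasible for C({n},{n1}) splits")
    ranks = rankdata(np.vstack([x, y]), axis=0)  # (n, G)
    combs = np.array(list(itertools.combinations(range(n), n1)), dtype=np.intp)
    w_all = ranks[combs, :].sum(axis=1)  # (C, G)
    w_obs = ranks[:n1].sum(axis=0)  # (G,)
    mu = n1 * (n + 1) / 2.0
    dev_obs = np.abs(w_obs - mu)
    p = (np.abs(w_all - mu) >= dev_obs - 1e-9).mean(axis=0)
    return p


def ranksum_p_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 9999,
    seed: int = 0,
) -> np.ndarray:
    """Seeded Monte-Carlo permutation two-sided p (add-one corrected)."""
    x, y = _as_2d(x), _as_2d(y)
    n1 = x.shape[0]
    n = n1 + y.shape[0]
    ranks = rankdata(np.vstack([x, y]), axis=0)
    mu = n1 * (n + 1) / 2.0
    dev_obs = np.abs(ranks[:n1].sum(axis=0) - mu)
    rng = np.random.default_rng(seed)
    count = np.zeros(ranks.shape[1], dtype=np.int64)
    batch = max(1, min(n_permutations, 512))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :n1]
        w = ranks[idx, :].sum(axis=1)  # (b, G)
        count += (np.abs(w - mu) >= dev_obs - 1e-9).sum(axis=0)
        done += b
    return (count + 1) / (n_permutations + 1)


def ranksum_p(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "wilcoxon",
    n_permutations: int = 9999,
    seed: int = 0,
) -> np.ndarray:
    """Dispatch: exact enumeration when both groups are small, else the
    tie-corrected asymptotic Wilcoxon; or Monte-Carlo permutation."""
    if method == "permutation":
        return ranksum_p_permutation(x, y, n_permutations=n_permutations, seed=seed)
    if method != "wilcoxon":
        raise ValueError(f"unknown test {method!r}")
    x2, y2 = _as_2d(x), _as_2d(y)
    if x2.shape[0] <= EXACT_MAX_GROUP and y2.shape[0] <= EXACT_MAX_GROUP:
        return ranksum_p_exact(x2, y2)
    return ranksum_p_asymptotic(x2, y2)
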