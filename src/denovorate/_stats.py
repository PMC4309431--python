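"""Exact null distributions for the cohort-level site tests.

Both site tests are built directly on their known null distributions so the
expected fraction of good sites they reject (alpha_site) can be computed
rather than guessed:

* strand bias: conditional on the margins of the 2x2 (allele x strand) table,
  the forward-alt count is hypergeometric; the two-sided p-value sums the
  probabilities of all tables at most as probable as the observed one.
* read position: the rank-sum statistic of alt-read offsets against ref-read
  offsets; under a continuous null, the Mann-Whitney U distribution.

The strand test enumerates the hypergeometric support exactly when it has at
most ``_EXACT_SUPPORT`` states and otherwise switches to a continuity-
corrected normal approximation (the discrete distribution is then effectively
continuous).  The rank test uses an exact, cached null distribution computed
by the standard counting recurrence, with midranks for ties.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from scipy.stats import rankdata

_EXACT_SUPPORT = 256
# Relative tolerance when comparing table probabilities (fisher convention).
_REL_EPS = 1e-7


def strand_bias_pvalues(
    ref_fwd: np.ndarray, ref_rev: np.ndarray, alt_fwd: np.ndarray, alt_rev: np.ndarray
) -> np.ndarray:
    """Two-sided exact conditional p-values for 2x2 strand/allele tables.

    Vectorised over sites.  Degenerate tables (an empty margin) get p = 1.
    """
    a = np.asarray(alt_fwd, dtype=np.int64)
    b = np.asarray(alt_rev, dtype=np.int64)
    c = np.asarray(ref_fwd, dtype=np.int64)
    d = np.asarray(ref_rev, dtype=np.int64)
    n_tot = a + b + c + d
    k_alt = a + b  # draws of interest
    n_fwd = a + c
    lo = np.maximum(0, k_alt + n_fwd - n_tot)
    hi = np.minimum(k_alt, n_fwd)
    width = hi - lo + 1

    p = np.ones(a.shape, dtype=np.float64)
    degenerate = (k_alt == 0) | (k_alt == n_tot) | (n_fwd == 0) | (n_fwd == n_tot)

    exact = (~degenerate) & (width <= _EXACT_SUPPORT)
    if exact.any():
        p[exact] = _exact_two_sided(a[exact], n_tot[exact], k_alt[exact], n_fwd[exact],
                                    lo[exact], hi[exact])
    approx = (~degenerate) & (width > _EXACT_SUPPORT)
    if approx.any():
        p[approx] = _normal_two_sided(a[approx], n_tot[approx], k_alt[approx], n_fwd[approx])
    return p


def _log_hypergeom_pmf(k, N, K, n):
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def _exact_two_sided(a, N, K, n, lo, hi):
    # Pad every site's support to the same width and mask the tail.
    width = int((hi - lo).max()) + 1
    offs = np.arange(width)
    k = lo[:, None] + offs[None, :]
    valid = k <= hi[:, None]
    k = np.where(valid, k, lo[:, None])
    logpmf = _log_hypergeom_pmf(k, N[:, None], K[:, None], n[:, None])
    pmf = np.exp(logpmf)
    pmf[~valid] = 0.0
    obs = np.exp(_log_hypergeom_pmf(a, N, K, n))
    include = pmf <= obs[:, None] * (1.0 + _REL_EPS)
    return np.minimum(1.0, (pmf * include).sum(axis=1))


def _normal_two_sided(a, N, K, n):
    mean = K * n / N
    var = K * n * (N - K) * (N - n) / (N**2 * (N - 1.0))
    var = np.maximum(var, 1e-300)
    z = (np.abs(a - mean) - 0.5) / np.sqrt(var)
    z = np.maximum(z, 0.0)
    from scipy.stats import norm

    return np.minimum(1.0, 2.0 * norm.sf(z))


# ---- exact Mann-Whitney --------------------------------------------------------


@lru_cache(maxsize=4096)
def mann_whitney_null_cdf(n: int, m: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under the exact no-ties null.

    ``cdf[u] = P(U <= u)`` for ``u = 0 .. n*m``, from the standard counting
    recurrence ``f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u)`` over the number
    of rank arrangements of i alt and j ref observations.
    """
    if n == 0 or m == 0:
        return np.ones(1)
    max_u = n * m
    # f[j, u] for the current number of alt items i; counts fit exactly in
    # float64 for the subsampled list sizes used here (<= C(32,16) < 2^53).
    f = np.zeros((m + 1, max_u + 1), dtype=np.float64)
    f[:, 0] = 1.0
    for _ in range(1, n + 1):
        g = np.zeros_like(f)
        for j in range(m + 1):
            if j > 0:
                g[j] = g[j - 1].copy()
            else:
                g[j] = 0.0
            g[j, j:] += f[j, : max_u + 1 - j]
        f = g
    counts = f[m]
    total = counts.sum()
    return np.cumsum(counts) / total


def mann_whitney_u(alt_values: np.ndarray, ref_values: np.ndarray) -> float:
    """U statistic of alt vs ref with midranks for ties."""
    pooled = np.concatenate([alt_values, ref_values]).astype(np.float64)
    ranks = rankdata(pooled)
    n = len(alt_values)
    r_alt = ranks[:n].sum()
    return float(r_alt - n * (n + 1) / 2.0)


def mann_whitney_pvalue(alt_values, ref_values) -> float:
    """Two-sided exact Mann-Whitney p-value (no-ties null, midranks for ties)."""
    alt_values = np.asarray(alt_values)
    ref_values = np.asarray(ref_values)
    n, m = len(alt_values), len(ref_values)
    if n == 0 or m == 0:
        return 1.0
    u = mann_whitney_u(alt_values, ref_values)
    return _two_sided_from_u(u, n, m)


def _two_sided_from_u(u: float, n: int, m: int) -> float:
    if n * m > 10_000:  # exact table impractical; null is effectively normal
        from scipy.stats import norm

        mean = n * m / 2.0
        sd = np.sqrt(n * m * (n + m + 1) / 12.0)
        z = max(0.0, (abs(u - mean) - 0.5) / sd)
        return float(min(1.0, 2.0 * norm.sf(z)))
    cdf = mann_whitney_null_cdf(n, m)
    max_u = n * m
    u_low = min(u, max_u - u)
    k = int(np.floor(u_low + 1e-9))
    p_low = cdf[k] if k >= 0 else 0.0
    # symmetric null: P(U >= max_u - u_low) = P(U <= u_low)
    return float(min(1.0, 2.0 * p_low))


def mann_whitney_pvalues_batch(alt_lists, ref_lists) -> np.ndarray:
    """Vectorised two-sided p-values for many sites.

    ``alt_lists``/``ref_lists`` are sequences of 1-D int arrays (or None).
    Sites without both read-offset lists get p = 1.  Lists are padded to a
    matrix and ranked along the last axis (pads at +inf occupy only the top
    ranks), so the per-site midrank U statistics come out of one rankdata
    call; p-values are then looked up in the cached exact null CDFs grouped
    by (n, m).
    """
    n_sites = len(alt_lists)
    out = np.ones(n_sites, dtype=np.float64)
    ns = np.array([0 if a is None else len(a) for a in alt_lists])
    ms = np.array([0 if r is None else len(r) for r in ref_lists])
    usable = (ns > 0) & (ms > 0)
    if not usable.any():
        return out
    idx = np.nonzero(usable)[0]
    big = (ns[idx] * ms[idx] > 10_000)
    for i in idx[big]:  # rare: fall back to the scalar path (normal approx)
        out[i] = mann_whitney_pvalue(alt_lists[i], ref_lists[i])
    idx = idx[~big]
    if len(idx) == 0:
        return out
    na = int(ns[idx].max())
    nr = int(ms[idx].max())
    pooled = np.full((len(idx), na + nr), np.inf)
    for row, i in enumerate(idx):
        pooled[row, : ns[i]] = alt_lists[i]
        pooled[row, na : na + ms[i]] = ref_lists[i]
    ranks = rankdata(pooled, axis=1)
    alt_mask = np.zeros((len(idx), na + nr), dtype=bool)
    for row, i in enumerate(idx):
        alt_mask[row, : ns[i]] = True
    r_alt = np.where(alt_mask, ranks, 0.0).sum(axis=1)
    u = r_alt - ns[idx] * (ns[idx] + 1) / 2.0

    pvals = np.empty(len(idx))
    pairs = np.stack([ns[idx], ms[idx]], axis=1)
    for n_i, m_i in {tuple(p) for p in pairs.tolist()}:
        sel = (pairs[:, 0] == n_i) & (pairs[:, 1] == m_i)
        cdf = mann_whitney_null_cdf(int(n_i), int(m_i))
        max_u = n_i * m_i
        u_low = np.minimum(u[sel], max_u - u[sel])
        k = np.floor(u_low + 1e-9).astype(np.int64)
        pvals[sel] = np.minimum(1.0, 2.0 * cdf[np.clip(k, 0, max_u)])
    out[idx] = pvals
    return out
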