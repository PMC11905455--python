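"""Comparative statistics over lesion scores and sample-level measures.

Category-frequency differences between lesion types are tested with
pairwise Fisher exact tests on 2 x k sub-tables (the Freeman-Halton
extension, computed by full enumeration of tables with the observed
margins), Bonferroni-adjusted over pairs. Continuous per-lesion measures
(absolute overlap area) are compared with the Kruskal-Wallis test followed
by Dunn's post hoc z-tests with tie correction. Spearman rank correlation
covers the western-blot / mass-spectrometry concordance checks.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError

log = logging.getLogger(__name__)

#: Relative tolerance for counting a table probability as a tie with the
#: observed one in the exact test.
_TIE_RTOL = 1e-12


# ---------------------------------------------------------------------------
# Freeman-Halton exact test on 2 x k tables
# ---------------------------------------------------------------------------

def _log_table_prob(row1: np.ndarray, col_sums: np.ndarray,
                    n_total: int, r1: int) -> float:
    """log P(table | margins) for a 2 x k table given its first row."""
    lp = -(math.lgamma(n_total + 1) - math.lgamma(r1 + 1)
           - math.lgamma(n_total - r1 + 1))
    for a, c in zip(row1, col_sums):
        lp += (math.lgamma(c + 1) - math.lgamma(a + 1)
               - math.lgamma(c - a + 1))
    return lp


def _enumerate_first_rows(col_sums: np.ndarray, r1: int, r2: int):
    """Yield every feasible first row of a 2 x k table with the margins."""
    k = len(col_sums)

    def rec(j: int, remaining: int, prefix: tuple):
        if j == k - 1:
            last = remaining
            if 0 <= last <= col_sums[-1] and (col_sums[-1] - last) <= r2:
                yield prefix + (last,)
            return
        tail_cap = int(col_sums[j + 1:].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(col_sums[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + (a,))

    yield from rec(0, r1, ())


def fisher_exact_2xk(table: np.ndarray, max_enumeration: int = 2_000_000,
                     n_mc: int = 100_000, seed: int = 0) -> float:
    """Two-sided exact conditional p for a 2 x k contingency table.

    All tables with the observed margins are enumerated and the p-value is
    the total probability of tables no more probable than the observed one
    (ties counted, with a 1e-12 relative tolerance). Above
    ``max_enumeration`` candidate tables the p-value is estimated instead
    by seeded Monte-Carlo sampling of tables from the conditional
    (Patefield) distribution.
    """
    tbl = np.asarray(table, dtype=int)
    if tbl.shape[0] != 2 or tbl.ndim != 2:
        raise ConfigurationError("expected a 2 x k table")
    if (tbl < 0).any():
        raise ConfigurationError("counts must be non-negative")
    row_sums = tbl.sum(axis=1)
    col_sums = tbl.sum(axis=0)
    n_total = int(tbl.sum())
    if n_total == 0 or (row_sums == 0).any():
        raise ConfigurationError("each row needs at least one observation")
    keep = col_sums > 0
    tbl, col_sums = tbl[:, keep], col_sums[keep]
    r1, r2 = int(row_sums[0]), int(row_sums[1])

    lp_obs = _log_table_prob(tbl[0], col_sums, n_total, r1)
    # number of candidate tables is bounded by prod(col_sums + 1)
    n_candidates = np.prod(col_sums + 1.0)
    if n_candidates <= max_enumeration:
        total = 0.0
        for row1 in _enumerate_first_rows(col_sums, r1, r2):
            lp = _log_table_prob(np.asarray(row1), col_sums, n_total, r1)
            if lp <= lp_obs + _TIE_RTOL * abs(lp_obs) + 1e-300:
                total += math.exp(lp)
        return min(total, 1.0)

    rng = np.random.default_rng(seed)
    rvs = stats.random_table(row_sums, col_sums).rvs(n_mc, random_state=rng)
    lps = np.array([_log_table_prob(t[0], col_sums, n_total, r1)
                    for t in rvs.astype(int)])
    return float((lps <= lp_obs + _TIE_RTOL * abs(lp_obs) + 1e-300).mean())


def fisher_pairwise(tbl: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Pairwise Freeman-Halton tests between the rows of a count table.

    ``tbl`` has one row per lesion type and one column per category.
    Returns per pair the raw and Bonferroni-adjusted p (multiplier = the
    number of tested pairs, capped at 1). Pairs involving an all-zero row
    are skipped with a warning.
    """
    if len(tbl) < 2:
        raise ConfigurationError("need at least two lesion types")
    pairs = list(combinations(tbl.index, 2))
    rows = []
    for a, b in pairs:
        sub = tbl.loc[[a, b]].to_numpy(dtype=int)
        if (sub.sum(axis=1) == 0).any():
            log.warning("skipping pair (%s, %s): empty row", a, b)
            continue
        p = fisher_exact_2xk(sub, **kwargs)
        rows.append({"group1": a, "group2": b, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; (H, df, p).

    A degenerate input where every value is identical yields
    ``H = 0, p = 1`` rather than an error.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigurationError("need >=2 non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def dunn_posthoc(groups: list[np.ndarray], labels: list[str] | None = None,
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's (1964) post hoc pairwise z-tests on mean ranks.

    z uses the tie-corrected variance
    ``(N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)`` with
    ``T = sum(t^3 - t)`` over tied groups; two-sided normal p-values are
    Bonferroni-adjusted over pairs by default (``adjust=None`` disables).
    """
    if any(len(g) == 0 for g in groups):
        raise ConfigurationError("empty group")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrs]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))

    rows = []
    pairs = list(combinations(range(len(arrs)), 2))
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": labels[i], "group2": labels[j],
                     "z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(pairs), 1.0)
    elif adjust is None:
        out["p_adj"] = out["p"]
    else:
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    return out


def spearman_corr(x: np.ndarray, y: np.ndarray,
                  exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    ``rho = +-1`` returns ``p = 0`` by convention. With ``exact=True`` and
    ``n <= 9`` the p-value is instead computed by full enumeration of rank
    permutations (two-sided on |rho|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ConfigurationError("need equal-length vectors of size >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigurationError("rank correlation undefined for a "
                                 "constant vector")
    n = x.size
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-14:
        return float(np.sign(rho)), 0.0
    if exact:
        if n > 9:
            raise ConfigurationError("exact permutation limited to n <= 9")
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def biotinylation_ratio(pos_signal: float, pos_total: float,
                        neg_signal: float, neg_total: float) -> float:
    """Ratio of normalized biotinylation signal, probe-positive over
    probe-omitted: ``(pos/pos_total) / (neg/neg_total)``."""
    if pos_total <= 0 or neg_total <= 0 or neg_signal <= 0:
        raise ConfigurationError("totals and the negative signal must be "
                                 "positive")
    return (pos_signal / pos_total) / (neg_signal / neg_total)
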