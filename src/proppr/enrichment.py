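"""Gene-set overlap significance and over-representation analysis.

The overlap test is the upper-tail hypergeometric probability
``P(X >= x)`` for drawing ``x`` shared genes between two sets of sizes
``nA`` and ``nB`` from a universe of ``N`` genes. Observed overlaps in
proximity-proteomics concordance checks can be astronomically significant
(p-values far below 1e-300, underflowing double precision), so the whole
computation is carried out in log space with log-gamma binomial
coefficients and a log-sum-exp accumulation; results are exact in
``log10(p)`` even at |log10 p| > 500.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .datatypes import ConfigurationError, GeneSet
from .differential import adjust_bh

#: Search-database size used as the default universe when none is given.
DEFAULT_UNIVERSE = 20607


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass
class OverlapResult:
    x: int
    nA: int
    nB: int
    N: int
    log10_p: float
    fold: float

    @property
    def p(self) -> float:
        """Linear-scale p; underflows to 0 for extreme overlaps."""
        return float(10.0 ** self.log10_p)


def log_hypergeom_sf(x: int, nA: int, nB: int, N: int) -> float:
    """Natural log of ``P(X >= x)`` for X ~ Hypergeom(N, nA, nB).

    Computed entirely in log space: each term is
    ``C(nA, i) * C(N - nA, nB - i) / C(N, nB)`` summed over
    ``i = x .. min(nA, nB)`` via log-sum-exp.
    """
    if x <= 0:
        return 0.0
    hi = min(nA, nB)
    if x > hi:
        return -np.inf
    i = np.arange(x, hi + 1)
    terms = (_log_choose(nA, i) + _log_choose(N - nA, nB - i)
             - _log_choose(N, nB))
    return float(logsumexp(terms))


def hypergeom_overlap(x: int, nA: int, nB: int,
                      N: int = DEFAULT_UNIVERSE) -> OverlapResult:
    """Upper-tail hypergeometric overlap test, stable at extreme p.

    ``fold`` is the ratio of the observed overlap to its expectation
    ``nA * nB / N``.
    """
    if not (0 <= x <= min(nA, nB)):
        raise ConfigurationError(f"x={x} inconsistent with nA={nA}, nB={nB}")
    if nA > N or nB > N or min(nA, nB, N) < 0:
        raise ConfigurationError("set sizes must not exceed the universe")
    log_p = log_hypergeom_sf(x, nA, nB, N)
    expected = nA * nB / N
    fold = x / expected if expected > 0 else 0.0
    return OverlapResult(x=x, nA=nA, nB=nB, N=N,
                         log10_p=log_p / np.log(10.0), fold=fold)


def ora_enrich(query: GeneSet, universe: GeneSet,
               annotation: dict[str, set], min_size: int = 10,
               max_size: int = 500) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a query.

    Terms are restricted to the universe before size filtering; terms with
    fewer than ``min_size`` or more than ``max_size`` universe genes are
    not tested. The hit count ``k`` is tested against the upper tail and
    p-values are BH-adjusted over the tested terms.
    """
    if not universe.members:
        raise ConfigurationError("empty universe")
    if not annotation:
        raise ConfigurationError("empty annotation")
    extra = query.members - universe.members
    if extra:
        raise ConfigurationError(
            f"query genes outside the universe: {sorted(extra)[:5]}")
    N = len(universe)
    n = len(query)
    rows = []
    for term, genes in annotation.items():
        in_universe = frozenset(genes) & universe.members
        K = len(in_universe)
        if not min_size <= K <= max_size:
            continue
        k = len(in_universe & query.members)
        p = float(np.exp(log_hypergeom_sf(k, n, K, N)))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N,
                     "p": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "p",
                                     "p_adj"])
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)
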