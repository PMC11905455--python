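"""MiST-style association scoring of pulldown versus antibody-omission runs.

For every disease the AT8 pulldown replicates and their matched
antibody-omission controls are scored per protein on three [0,1] metrics:

* reproducibility ``R`` — normalized Shannon entropy of the protein's share
  across pulldown replicates (1 = perfectly even, 0 = seen in at most one
  replicate),
* abundance ``A`` — mean run-normalized quantity over pulldown replicates,
  rescaled by the per-disease maximum,
* specificity ``S`` — the pulldown's share of the summed mean abundance,
  ``A_pull / (A_pull + A_ctrl)``.

The composite score is a convex combination of the three, either with fixed
weights (default 0.30/0.08/0.62, the published MiST training weights) or
with weights derived from the first principal component of the metric
matrix. Proteins scoring at or above the cutoff (0.75 by default) form the
per-disease associated set.
"""

from __future__ import annotations

import logging
import warnings
from itertools import product

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, GeneSet, IntensityMatrix

log = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.30, 0.08, 0.62)   # (w_R, w_A, w_S)
DEFAULT_CUTOFF = 0.75


def normalize_runs(m: IntensityMatrix) -> IntensityMatrix:
    """Composition-normalize each sample: present values sum to 1.

    Missing values stay missing; zeros are retained. An all-missing (or
    all-zero) sample cannot be normalized and raises an error naming it.
    """
    sums = m.values.sum(axis=0, skipna=True)
    bad = [s for s in m.values.columns
           if not np.isfinite(sums[s]) or sums[s] <= 0]
    if bad:
        raise ConfigurationError(
            f"samples with no positive quantities cannot be normalized: {bad}")
    values = m.values / sums
    return IntensityMatrix(values=values, meta=m.meta,
                           gene_symbols=m.gene_symbols)


def _mean_over(values: pd.DataFrame, samples: list[str]) -> np.ndarray:
    """Mean across replicates with missing treated as zero signal."""
    return values[samples].fillna(0.0).to_numpy().mean(axis=1)


def compute_metrics(m: IntensityMatrix, disease: str) -> pd.DataFrame:
    """Per-protein (R, A, S) for one disease from run-normalized data.

    ``m`` must already be run-normalized (see :func:`normalize_runs`).
    """
    pull = m.samples(disease=disease, condition="pulldown")
    ctrl = m.samples(disease=disease, condition="control")
    if len(pull) < 2 or len(ctrl) < 2:
        raise ConfigurationError(
            f"{disease}: need >=2 pulldown and >=2 control replicates "
            f"(have {len(pull)}/{len(ctrl)})")

    x = m.values[pull].fillna(0.0).to_numpy()
    n = x.shape[1]
    totals = x.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals[:, None] > 0, x / totals[:, None], 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    r_metric = -plogp.sum(axis=1) / np.log(n)
    # detected in at most one replicate, or not at all -> R = 0
    r_metric[(x > 0).sum(axis=1) <= 1] = 0.0
    r_metric = np.clip(r_metric, 0.0, 1.0)

    a_pull_raw = _mean_over(m.values, pull)
    a_ctrl_raw = _mean_over(m.values, ctrl)
    a_max = a_pull_raw.max()
    abundance = a_pull_raw / a_max if a_max > 0 else np.zeros_like(a_pull_raw)

    denom = a_pull_raw + a_ctrl_raw
    with np.errstate(divide="ignore", invalid="ignore"):
        specificity = np.where(denom > 0, a_pull_raw / denom, 0.0)

    return pd.DataFrame({"R": r_metric, "A": abundance, "S": specificity},
                        index=m.values.index)


def composite_score(metrics: pd.DataFrame, mode: str = "fixed",
                    fixed_weights: tuple = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Combine (R, A, S) into a [0,1] composite score.

    ``fixed`` mode takes ``score = w_R*R + w_A*A + w_S*S`` with the supplied
    weights. ``pca`` mode min-max scales each metric over proteins, projects
    onto the first principal component, orients it so the specificity
    loading is non-negative, and uses the normalized absolute loadings as
    weights. A metric matrix with no variance in any metric falls back to
    fixed mode with a warning.
    """
    if mode not in ("fixed", "pca"):
        raise ConfigurationError(f"unknown scoring mode {mode!r}")
    mat = metrics[["R", "A", "S"]].to_numpy(dtype=float)

    if mode == "pca":
        if mat.shape[0] < 3:
            raise ConfigurationError("pca mode needs >=3 proteins")
        rng_col = mat.max(axis=0) - mat.min(axis=0)
        if np.all(rng_col == 0):
            warnings.warn("degenerate metric matrix; falling back to fixed "
                          "weights", stacklevel=2)
            mode = "fixed"
        else:
            safe = np.where(rng_col > 0, rng_col, 1.0)
            scaled = (mat - mat.min(axis=0)) / safe
            centered = scaled - scaled.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            loadings = vt[0]
            if loadings[2] < 0:
                loadings = -loadings
            weights = np.abs(loadings)
            if weights.sum() == 0:
                weights = np.ones(3)
            weights = weights / weights.sum()
            score = np.clip(scaled @ weights, 0.0, 1.0)

    if mode == "fixed":
        weights = np.asarray(fixed_weights, dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ConfigurationError("weights must be non-negative and sum "
                                     "to 1")
        score = np.clip(mat @ weights, 0.0, 1.0)

    out = metrics.copy()
    out["score"] = score
    out.attrs["weights_used"] = tuple(np.round(weights, 6))
    return out


def score_disease(m: IntensityMatrix, disease: str, mode: str = "fixed",
                  fixed_weights: tuple = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Run-normalize, compute metrics and the composite for one disease."""
    return composite_score(compute_metrics(normalize_runs(m), disease),
                           mode=mode, fixed_weights=fixed_weights)


def score_all(m: IntensityMatrix, mode: str = "fixed",
              fixed_weights: tuple = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Long-format MiST table over every disease in the matrix."""
    norm = normalize_runs(m)
    frames = []
    for d in norm.diseases:
        res = composite_score(compute_metrics(norm, d), mode=mode,
                              fixed_weights=fixed_weights)
        res = res.reset_index(names="protein")
        res.insert(0, "disease", d)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def select_associated(scores: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF,
                      name: str = "associated") -> GeneSet:
    """Proteins with composite score >= cutoff (inclusive boundary)."""
    members = scores.index[scores["score"] >= cutoff]
    return GeneSet(name=name, members=frozenset(members))


def set_overlaps(sets: list[GeneSet]) -> pd.DataFrame:
    """Venn-region counts for k sets.

    One row per non-empty membership pattern (2^k - 1 regions): boolean
    columns named after the sets, a ``count`` column, and ``union`` /
    per-set totals in ``DataFrame.attrs``. Region counts sum to the union
    cardinality.
    """
    if len(sets) < 2:
        raise ConfigurationError("need at least two sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ConfigurationError("set names must be unique")
    universe = frozenset().union(*(s.members for s in sets))
    rows = []
    for pattern in product([True, False], repeat=len(sets)):
        if not any(pattern):
            continue
        region = set(universe)
        for s, inside in zip(sets, pattern):
            region &= s.members if inside else (universe - s.members)
        rows.append(dict(zip(names, pattern)) | {"count": len(region)})
    out = pd.DataFrame(rows)
    out.attrs["union"] = len(universe)
    out.attrs["set_sizes"] = {s.name: len(s) for s in sets}
    return out


# ---------------------------------------------------------------------------
# re-counts from an externally supplied score table
# ---------------------------------------------------------------------------

def recount_score_table(table: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF,
                        ) -> dict:
    """Re-derive headline association counts from a long score table.

    ``table`` needs columns ``disease``, ``protein``, ``score`` and
    optionally ``gene``. Applies the inclusive score cutoff per disease and
    returns the per-disease set sizes, the overall number of associated
    proteins (union over diseases), the number of unique gene symbols, and
    the number of proteins common to all diseases. Accepts both synthetic
    score tables and published supplementary exports with this schema.
    """
    for col in ("disease", "protein", "score"):
        if col not in table.columns:
            raise ConfigurationError(f"score table lacks column {col!r}")
    hits = table[table["score"] >= cutoff]
    per_disease = {d: set(g["protein"]) for d, g in hits.groupby("disease")}
    union: set = set().union(*per_disease.values()) if per_disease else set()
    common = set.intersection(*per_disease.values()) if per_disease else set()
    result = {
        "n_total": len(union),
        "n_common_all": len(common),
        "per_disease": {d: len(s) for d, s in per_disease.items()},
    }
    if "gene" in table.columns:
        gene_of = table.drop_duplicates("protein").set_index("protein")["gene"]
        result["n_unique_genes"] = gene_of.loc[sorted(union)].nunique()
    return result
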