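"""Cross-disease differential association of pulldown intensities.

The stage mirrors a standard label-free differential-abundance workflow:
missing-value filtering, log2 transform with per-sample median centering,
left-censored Gaussian imputation (down-shifted normal, the Perseus
convention), and an empirical-Bayes moderated t-test in the style of
limma/Smyth (2004): per-protein variances are shrunk toward a common prior
variance whose degrees of freedom are estimated by matching the moments of
log sample variances via digamma/trigamma inversion. P-values are
Benjamini-Hochberg adjusted within each contrast.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma, psi
from statsmodels.stats.multitest import multipletests

from .datatypes import ConfigurationError, IntensityMatrix

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# filtering / normalization / imputation
# ---------------------------------------------------------------------------

def filter_missing(m: IntensityMatrix, min_frac: float = 1.0,
                   condition: str = "pulldown") -> IntensityMatrix:
    """Keep proteins sufficiently observed in at least one disease group.

    The default (``min_frac=1.0``) keeps a protein when it is present in
    every replicate of at least one disease's ``condition`` samples.
    """
    if not 0 < min_frac <= 1:
        raise ConfigurationError("min_frac must lie in (0, 1]")
    keep = np.zeros(len(m.values), dtype=bool)
    for d in m.diseases:
        cols = m.samples(disease=d, condition=condition)
        if not cols:
            continue
        frac = m.values[cols].notna().mean(axis=1).to_numpy()
        keep |= frac >= min_frac
    if not keep.any():
        raise ConfigurationError(
            "no protein passes the missingness filter; relax min_frac")
    return replace(m, values=m.values.loc[keep])


def normalize_log2(m: IntensityMatrix) -> IntensityMatrix:
    """log2 transform and per-sample median centering.

    Sample medians are computed over the proteins present in every sample
    (the shared complete rows) and subtracted, bringing every column to a
    common reference median of zero — a multiplicative global-scaling
    correction on the raw scale that any per-sample rescaling of the input
    cannot shift.
    """
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise ConfigurationError("non-positive intensities cannot be "
                                 "log-transformed")
    logv = np.log2(vals)
    complete = ~np.isnan(logv).any(axis=1)
    ref_rows = logv[complete] if complete.any() else logv
    with np.errstate(all="ignore"):
        med = np.nanmedian(ref_rows, axis=0)
    centered = logv - med
    return replace(m, values=pd.DataFrame(centered, index=m.values.index,
                                          columns=m.values.columns),
                   log_scale=True)


def impute_left_censored(m: IntensityMatrix, shift: float = 1.8,
                         width: float = 0.3, seed: int = 0
                         ) -> IntensityMatrix:
    """Draw missing log2 entries from a down-shifted sample distribution.

    Each missing value in sample ``s`` is drawn from
    ``Normal(mean_s - shift * sd_s, (width * sd_s)^2)`` with ``mean_s``,
    ``sd_s`` the sample's observed mean and standard deviation — the
    left-censoring model: absent proteins sit near the detection limit.
    """
    rng = np.random.default_rng(seed)
    vals = m.values.to_numpy(dtype=float).copy()
    for j, col in enumerate(m.values.columns):
        obs = vals[:, j][~np.isnan(vals[:, j])]
        if obs.size < 3:
            raise ConfigurationError(
                f"sample {col!r} has fewer than 3 observed values")
        miss = np.isnan(vals[:, j])
        if miss.any():
            mu, sd = obs.mean(), obs.std(ddof=1)
            vals[miss, j] = rng.normal(mu - shift * sd, width * sd,
                                       miss.sum())
    return replace(m, values=pd.DataFrame(vals, index=m.values.index,
                                          columns=m.values.columns))


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    # standard initialisation: trigamma(y) ~ 1/y for large y
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the prior (d0, s0^2).

    Under the hierarchical model ``s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_d/d``
    and ``1/sigma_g^2 ~ chi^2_{d0}/(d0 s0^2)``, the log sample variances
    have mean/variance expressible via digamma/trigamma; inverting the
    trigamma equation yields d0 (np.inf when the observed spread is no
    larger than expected under a single common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ConfigurationError("need >=2 positive sample variances")
    z = np.log(s2[ok])
    e = z - psi(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    excess = ((e - e_mean) ** 2).sum() / (n - 1) - polygamma(1, df / 2.0)
    if excess <= 0:
        # observed spread no larger than chi^2 sampling noise: a single
        # common variance; pooled mean is its maximum-likelihood estimate
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0_sq = float(np.exp(e_mean + psi(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_ttest(m: IntensityMatrix, contrast: tuple[str, str],
                    condition: str = "pulldown", alpha: float = DEFAULT_ALPHA,
                    prior_df: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test for one disease contrast.

    Positive ``log2fc`` means higher in the first-listed disease. Setting
    ``prior_df=np.inf`` forces complete shrinkage: every protein is tested
    against the common prior variance with a normal reference distribution.
    """
    a, b = contrast
    cols_a = m.samples(disease=a, condition=condition)
    cols_b = m.samples(disease=b, condition=condition)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ConfigurationError(f"contrast {contrast}: need >=2 samples "
                                 "per group")
    xa = m.values[cols_a].to_numpy(dtype=float)
    xb = m.values[cols_b].to_numpy(dtype=float)
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise ConfigurationError("missing values remain; impute first")
    na, nb = xa.shape[1], xb.shape[1]
    df_resid = na + nb - 2
    if df_resid <= 0:
        raise ConfigurationError("zero residual degrees of freedom")

    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) \
        + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    d0, s0_sq = estimate_prior_variance(s2, df_resid)
    forced = prior_df is not None
    if forced:
        d0 = float(prior_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        # estimated infinite prior: cap total df at the pooled df; a
        # forced infinite prior uses the exact normal limit
        df_total = np.inf if forced else float(len(s2) * df_resid)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = min(d0 + df_resid, float(len(s2) * df_resid))

    log2fc = mean_a - mean_b
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = adjust_bh(p)

    out = pd.DataFrame({
        "log2fc": log2fc, "t_mod": t_mod,
        "df": np.full_like(s2, df_total, dtype=float),
        "p": p, "p_adj": p_adj, "significant": p_adj < alpha,
    }, index=m.values.index)
    out.attrs["contrast"] = f"{a}_vs_{b}"
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def run_pairwise_contrasts(m: IntensityMatrix, alpha: float = DEFAULT_ALPHA,
                           min_frac: float = 1.0, shift: float = 1.8,
                           width: float = 0.3, seed: int = 0,
                           ) -> dict[str, pd.DataFrame]:
    """Full stage: filter, normalize, impute, then every pairwise contrast.

    Each contrast is BH-adjusted separately, matching per-comparison
    significance reporting. Returns ``{"A_vs_B": DifferentialTable, ...}``.
    """
    filt = filter_missing(m, min_frac=min_frac)
    pull_cols = filt.samples(condition="pulldown")
    filt = filt.subset(pull_cols)
    norm = normalize_log2(filt)
    complete = impute_left_censored(norm, shift=shift, width=width, seed=seed)
    diseases = complete.diseases
    results = {}
    for i, a in enumerate(diseases):
        for b in diseases[i + 1:]:
            res = moderated_ttest(complete, (a, b), alpha=alpha)
            results[f"{a}_vs_{b}"] = res
    return results
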