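"""Gamma-model significance testing of mean DASE, with BH FDR control.

The pooled per-observation DASE values act as the null-calibration
distribution and are modelled as gamma(k, theta).  A locus observed in n
heterozygous samples is summarized by its mean DASE; under the null model
the mean of n i.i.d. gamma(k, theta) draws is exactly gamma(n*k, theta/n),
so the default "tail" p-value is the upper-tail probability of that
distribution at the observed mean — one-sided by construction, since DASE
is a non-negative magnitude.  An alternative "glm" method fits an
intercept-only gamma regression with log link to the locus's DASE values
and Wald-tests the intercept against the null-pool mean; its p-value can
optionally be doubled for a two-sided report.  FDR is controlled by the
Benjamini-Hochberg step-up procedure, applied separately within each
result set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

_TINY = 1e-300  # p-values are reported in (0, 1]


@dataclass(frozen=True)
class GammaParams:
    """Maximum-likelihood gamma fit: shape ``k``, scale ``theta``."""

    shape: float
    scale: float
    n: int
    loglik: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def fit_gamma_mle(values) -> GammaParams:
    """Fit shape/scale of a gamma distribution by maximum likelihood.

    Solves the profile shape equation log(k) - digamma(k) = log(mean) -
    mean(log) by safeguarded Newton iteration from the Minka closed-form
    initial value; the scale is mean/k.  Requires at least 10 strictly
    positive values with nonzero spread.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 values to fit a gamma, got {x.size}")
    if (x <= 0).any():
        raise ValueError("gamma fit requires strictly positive values")
    mean = x.mean()
    mean_log = np.log(x).mean()
    s = np.log(mean) - mean_log
    if s <= 1e-10:  # log E[x] == E[log x] only for degenerate (constant) data
        raise ValueError("degenerate input: values have (numerically) no spread")

    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(200):
        f = np.log(k) - special.digamma(k) - s
        fprime = 1.0 / k - special.polygamma(1, k)
        step = f / fprime
        k_new = k - step
        if k_new <= 0:  # safeguard: bisect toward zero instead of jumping past it
            k_new = k / 2.0
        if abs(k_new - k) <= 1e-10 * k:
            k = k_new
            break
        k = k_new
    theta = mean / k
    loglik = float(np.sum(stats.gamma.logpdf(x, a=k, scale=theta)))
    return GammaParams(shape=float(k), scale=float(theta), n=int(x.size),
                       loglik=loglik)


def qq_gamma(values, params: GammaParams) -> pd.DataFrame:
    """Theoretical vs empirical quantiles at plotting positions (i-0.5)/n.

    For data genuinely drawn from the fitted gamma the points lie near the
    identity; heavy-tailed departures show as an upward bend in the upper
    tail.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.gamma.ppf(probs, a=params.shape, scale=params.scale)
    return pd.DataFrame({"theoretical": theo, "empirical": x})


def locus_pvalue(mean_dase: float, null_params: GammaParams, n_het: int,
                 method: str = "tail", values=None,
                 two_sided: bool = False) -> float:
    """P-value for one locus's mean DASE against the fitted null gamma.

    ``tail``: exact upper-tail probability of gamma(n*k, theta/n) at the
    observed mean (the sampling distribution of a mean of n independent
    null draws); one-sided, since the statistic is a magnitude.  ``glm``:
    intercept-only gamma regression on the locus's raw DASE ``values``
    (log link), Wald test of the intercept against log(null mean),
    optionally doubled when ``two_sided``.
    """
    if n_het < 1:
        raise ValueError("n_het must be >= 1")
    if method == "tail":
        p = float(stats.gamma.sf(
            mean_dase, a=n_het * null_params.shape,
            scale=null_params.scale / n_het))
    elif method == "glm":
        if values is None:
            raise ValueError("glm method needs the locus's DASE values")
        p = _glm_pvalue(np.asarray(values, dtype=float), null_params)
        if two_sided:
            p = min(1.0, 2.0 * p)
    else:
        raise ValueError(f"unknown p-value method: {method!r}")
    return min(1.0, max(p, _TINY))


def _glm_pvalue(values: np.ndarray, null_params: GammaParams) -> float:
    import statsmodels.api as sm

    values = np.maximum(values, _TINY)
    if values.size == 1 or np.ptp(values) == 0:
        # no within-locus dispersion to estimate; fall back to the null
        # model's own dispersion (1/k) for the Wald standard error
        mu = float(values.mean())
        se = np.sqrt(1.0 / (null_params.shape * values.size))
        z = (np.log(mu) - np.log(null_params.mean)) / se
        return float(stats.norm.sf(z))
    model = sm.GLM(values, np.ones((values.size, 1)),
                   family=sm.families.Gamma(link=sm.families.links.Log()))
    fit = model.fit()
    z = (fit.params[0] - np.log(null_params.mean)) / fit.bse[0]
    return float(stats.norm.sf(z))


def tail_pvalues(means, n_hets, null_params: GammaParams) -> np.ndarray:
    """Vectorized ``tail``-method p-values for many loci."""
    means = np.asarray(means, dtype=float)
    n_hets = np.asarray(n_hets, dtype=float)
    p = stats.gamma.sf(means, a=n_hets * null_params.shape,
                       scale=null_params.scale / n_hets)
    return np.clip(p, _TINY, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over sorted p_(j) >= p_(i) of m * p_(j) / j, capped at 1;
    input order is preserved in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_significance(table: pd.DataFrame, null_params: GammaParams,
                        method: str = "tail", two_sided: bool = False,
                        values_by_locus: dict | None = None) -> pd.DataFrame:
    """Add ``p_value`` and ``fdr`` columns to a locus-result table.

    The table needs ``mean_dase`` and ``n_het`` columns (and, for the glm
    method, a ``values_by_locus`` mapping locus id -> raw DASE values).
    FDR is computed within the given table, matching the convention of
    separate control per approach.
    """
    out = table.copy()
    if method == "tail":
        out["p_value"] = tail_pvalues(out["mean_dase"], out["n_het"], null_params)
    else:
        if values_by_locus is None:
            raise ValueError("glm method needs values_by_locus")
        out["p_value"] = [
            locus_pvalue(row.mean_dase, null_params, int(row.n_het),
                         method="glm", values=values_by_locus[row.locus_id],
                         two_sided=two_sided)
            for row in out.itertuples()
        ]
    out["fdr"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else np.nan
    return out
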