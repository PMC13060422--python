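"""Moderated differential testing of rMDS between response groups.

Repeated measures (three timepoints per patient) are handled with the
duplicate-correlation strategy: a single consensus intra-patient
correlation rho is estimated from per-bin one-way random-intercept
decompositions of OLS residuals, then every bin is fitted by generalized
least squares under block-equicorrelated errors (correlation rho within a
patient). Residual variances are squeezed toward a common prior by the
standard empirical-Bayes scheme — a scaled inverse chi-square prior
(d0, s0^2) fitted to the observed s^2 by matching moments of log s^2 —
giving moderated t statistics with d0 + d degrees of freedom. Multiple
testing is controlled with q-values (Storey by default, BH optional);
bins with q < 0.1 are conventionally called differential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DifferentialTable",
    "estimate_block_correlation",
    "fit_differential",
    "fdr_qvalues",
    "build_design",
]

RESPONSE_POSITIVE = "Responder"  # effect sign: responder minus non-responder


# ---------------------------------------------------------------------------
# design


def build_design(
    metadata: pd.DataFrame,
    covariates: list[str] = (),
    response: str = "response",
) -> tuple[np.ndarray, list[str]]:
    """Intercept + response indicator (+0.5/-0.5) + covariate columns.

    The response column is coded +1/2 for responders and -1/2 otherwise so
    the coefficient equals the responder-minus-non-responder difference.
    Numeric covariates enter centered; categorical ones one-hot with the
    first level as reference, levels carried by < 2 samples collapsed to
    'other' with a warning.
    """
    n = len(metadata)
    cols = [np.ones(n)]
    names = ["intercept"]
    resp = np.where(metadata[response].astype(str) == RESPONSE_POSITIVE, 0.5, -0.5)
    cols.append(resp)
    names.append("response")
    for cov in covariates:
        v = metadata[cov]
        if pd.api.types.is_numeric_dtype(v):
            x = v.to_numpy(dtype=float)
            cols.append(x - x.mean())
            names.append(cov)
        else:
            s = v.astype(str)
            counts = s.value_counts()
            rare = counts[counts < 2].index
            if len(rare):
                warnings.warn(
                    f"collapsing rare levels of {cov!r} to 'other': {sorted(rare)}"
                )
                s = s.where(~s.isin(rare), "other")
            levels = list(pd.unique(s))
            for lv in levels[1:]:
                cols.append((s == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# intra-patient correlation


def estimate_block_correlation(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    block: str = "patient_id",
    covariates: list[str] = (),
) -> float:
    """Consensus intra-block correlation rho from OLS residuals.

    Per bin, residuals from the fixed-effect OLS fit are decomposed by a
    one-way random-intercept ANOVA over blocks; the per-bin intraclass
    correlations are clipped to (-0.99, 0.99) and averaged on the Fisher-z
    scale. Returns 0 (with a warning) when no block has repeated measures.
    """
    meta = metadata.set_index("sample_id").loc[matrix.index].rename_axis("sample_id").reset_index()
    X, _ = build_design(meta, covariates=list(covariates))
    Y = matrix.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta

    blocks, binv = np.unique(meta[block].astype(str), return_inverse=True)
    sizes = np.bincount(binv)
    if (sizes < 2).all():
        warnings.warn("no repeated measures within blocks; rho set to 0")
        return 0.0
    N, g = len(meta), len(blocks)
    n0 = (N - (sizes**2).sum() / N) / (g - 1)

    sums = np.zeros((g, R.shape[1]))
    np.add.at(sums, binv, R)
    means = sums / sizes[:, None]
    grand = R.mean(axis=0)
    ssb = (sizes[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = ((R - means[binv]) ** 2).sum(axis=0)
    msb = ssb / (g - 1)
    msw = ssw / max(N - g, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msb - msw) / (msb + (n0 - 1) * msw)
    icc = np.clip(icc[np.isfinite(icc)], -0.99, 0.99)
    if icc.size == 0:
        warnings.warn("intra-block correlation undefined; rho set to 0")
        return 0.0
    return float(np.tanh(np.arctanh(icc).mean()))


# ---------------------------------------------------------------------------
# empirical Bayes squeeze (moment matching on log s^2)


def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x  # starting value, good for both tails
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Fit (d0, s0^2) to observed residual variances and return posteriors.

    Moment matching on z = log s^2: E z = log s0^2 + psi(d/2) - log(d/2)
    shifted by the prior terms, Var z = psi'(d/2) + psi'(d0/2). Returns
    (d0, s0^2, squeezed variances (d0 s0^2 + d s^2) / (d0 + d)).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    evar_excess = evar - float(special.polygamma(1, df / 2))
    if evar_excess <= 0:
        d0 = np.inf
        s0sq = float(np.exp(emean))
        post = np.full_like(s2, s0sq)
        post[~ok] = np.nan
        return d0, s0sq, post
    d0 = 2 * _trigamma_inverse(evar_excess)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    post = (d0 * s0sq + df * s2) / (d0 + df)
    post[~ok] = np.nan
    return float(d0), s0sq, post


# ---------------------------------------------------------------------------
# GLS fit


def _whiten_blocks(A: np.ndarray, binv: np.ndarray, rho: float) -> np.ndarray:
    """Apply Sigma^{-1/2} for block-equicorrelated errors, blockwise.

    For a block of size m, Sigma = (1-rho) I + rho J and
    Sigma^{-1/2} y = (y - ybar 1)/sqrt(1-rho) + ybar 1 / sqrt(1+(m-1) rho).
    rho = 0 leaves the data untouched (GLS reduces exactly to OLS).
    """
    if rho == 0:
        return A
    out = np.empty_like(A, dtype=float)
    for b in np.unique(binv):
        sel = binv == b
        m = int(sel.sum())
        blk = A[sel]
        mean = blk.mean(axis=0, keepdims=True)
        out[sel] = (blk - mean) / np.sqrt(1 - rho) + mean / np.sqrt(1 + (m - 1) * rho)
    return out


@dataclass
class DifferentialTable:
    """Per-bin moderated test results plus fitted model hyperparameters."""

    table: pd.DataFrame  # bin_id, effect, se, t, p, q
    rho: float
    d0: float
    s0sq: float
    n_tested: int
    n_flagged: int
    covariates: list[str] = field(default_factory=list)

    def significant(self, q_threshold: float = 0.1) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]

    def summary_json(self) -> dict:
        return {
            "rho": self.rho,
            "d0": self.d0 if np.isfinite(self.d0) else "inf",
            "s0sq": self.s0sq,
            "n_tested": self.n_tested,
            "n_flagged": self.n_flagged,
            "covariates": self.covariates,
        }


def fit_differential(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: list[str] = (),
    rho: float = 0.0,
    block: str = "patient_id",
    weights: np.ndarray | None = None,
    d0_override: float | None = None,
    fdr_method: str = "storey",
) -> DifferentialTable:
    """Per-bin GLS under block-equicorrelated errors with an EB-moderated t.

    ``rho`` is the consensus intra-block correlation (see
    :func:`estimate_block_correlation`). Optional per-sample ``weights``
    scale residual precision. ``d0_override`` forces the prior degrees of
    freedom (``np.inf`` reproduces a pooled-variance z-like test). Bins
    with non-finite fits are flagged and excluded from FDR.
    """
    meta = metadata.set_index("sample_id").loc[matrix.index].rename_axis("sample_id").reset_index()
    X, names = build_design(meta, covariates=list(covariates))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y = matrix.to_numpy(dtype=float)
    _, binv = np.unique(meta[block].astype(str), return_inverse=True)

    Xw = _whiten_blocks(X, binv, rho)
    Yw = _whiten_blocks(Y, binv, rho)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))[:, None]
        Xw = Xw * w
        Yw = Yw * w

    n, p = Xw.shape
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    beta = xtx_inv @ (Xw.T @ Yw)
    resid = Yw - Xw @ beta
    s2 = (resid**2).sum(axis=0) / df
    j = names.index("response")
    vjj = xtx_inv[j, j]
    effect = beta[j]

    if d0_override is not None:
        d0 = float(d0_override)
        e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
        if np.isinf(d0):
            # infinite prior df: all bins share the common prior variance
            s0sq = float(np.exp(e.mean()))
            post = np.full_like(s2, s0sq)
        else:
            s0sq = float(np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2)))
            post = (d0 * s0sq + df * s2) / (d0 + df)
    else:
        d0, s0sq, post = squeeze_variances(s2, df)

    se = np.sqrt(post * vjj)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    df_total = df + d0
    if np.isinf(df_total):
        pvals = 2 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2 * stats.t.sf(np.abs(t), df_total)

    finite = np.isfinite(t) & np.isfinite(pvals)
    n_flagged = int((~finite).sum())
    q = np.full(len(pvals), np.nan)
    if finite.any():
        q[finite] = fdr_qvalues(pvals[finite], method=fdr_method)

    table = pd.DataFrame(
        {
            "bin_id": matrix.columns,
            "effect": effect,
            "se": se,
            "t": t,
            "p": pvals,
            "q": q,
        }
    )
    return DifferentialTable(
        table=table,
        rho=float(rho),
        d0=float(d0),
        s0sq=float(s0sq),
        n_tested=int(finite.sum()),
        n_flagged=n_flagged,
        covariates=list(covariates),
    )


# ---------------------------------------------------------------------------
# FDR


def fdr_qvalues(pvalues: np.ndarray, method: str = "storey") -> np.ndarray:
    """q-values from p-values; Storey (default, pi0 from a lambda grid) or BH.

    Both are monotone non-decreasing in p and bounded by 1. Storey's pi0 is
    estimated on lambda = 0.05..0.95 with a cubic smoother evaluated at the
    largest lambda; with fewer than 100 p-values pi0 falls back to 1
    (making the result BH), since the grid estimate is unstable there.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown FDR method {method!r}")

    if method == "bh" or p.size < 100:
        pi0 = 1.0
    else:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.clip(np.polyval(coef, lam[-1]), 1e-8, 1.0))

    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * ranked * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0, 1)
    out = np.empty(n)
    out[order] = q
    return out


def storey_pi0(pvalues: np.ndarray) -> float:
    """Storey's pi0 estimate (fraction of true nulls), smoother evaluation."""
    p = np.asarray(pvalues, dtype=float)
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
    coef = np.polyfit(lam, pi0_lam, 3)
    return float(np.clip(np.polyval(coef, lam[-1]), 1e-8, 1.0))
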