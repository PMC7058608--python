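"""Core statistical primitives: Fisher transform, DerSimonian-Laird pooling,
Welch contrasts and Benjamini-Hochberg adjustment.

The meta-analysis treats each brain donor as a draw from a population of
brains: per-donor effect sizes (Fisher-z correlations or log2 fold changes)
are pooled with inverse-variance weights inflated by the moment estimate of
the between-donor variance tau^2, and the summary effect is tested against
zero with a t statistic on k-1 degrees of freedom (5 for six donors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_z",
    "inverse_fisher",
    "MetaResult",
    "meta_random_effects",
    "pool_effects",
    "bh_adjust",
    "welch_contrast",
]


def fisher_z(r):
    """Fisher transform z = arctanh(r); defined only for |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z undefined at |r| >= 1; exclude or clip upstream")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Back-transform a Fisher z to a correlation in (-1, 1)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MetaResult:
    """Random-effects summary of one effect across donors."""

    effect: float
    se: float
    tau2: float
    t: float
    p: float
    k: int

    @property
    def df(self) -> int:
        return self.k - 1


def pool_effects(effects: np.ndarray, variances: np.ndarray):
    """Vectorized DerSimonian-Laird pooling along the last axis.

    NaN entries mark donors without an estimate and are ignored; the
    per-row donor count k is reduced accordingly.  Returns
    (summary, se, tau2, t, p, k) arrays.
    """
    e = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if e.shape != v.shape:
        raise ValueError("effects and variances must have the same shape")
    valid = ~(np.isnan(e) | np.isnan(v))
    if np.any(v[valid] <= 0):
        raise ValueError("all sampling variances must be positive")
    k = valid.sum(axis=-1)
    if np.any(k == 0):
        raise ValueError("at least one effect is required per row")

    w = np.where(valid, 1.0 / np.where(valid, v, 1.0), 0.0)
    sw = w.sum(axis=-1)
    mean_fixed = np.nansum(np.where(valid, w * e, 0.0), axis=-1) / sw
    q = np.nansum(np.where(valid, w * (e - mean_fixed[..., None]) ** 2, 0.0), axis=-1)
    denom = sw - (w**2).sum(axis=-1) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(denom > 0, (q - (k - 1)) / np.where(denom > 0, denom, 1.0), 0.0)
    tau2 = np.maximum(tau2, 0.0)

    w_star = np.where(valid, 1.0 / (np.where(valid, v, 1.0) + tau2[..., None]), 0.0)
    sw_star = w_star.sum(axis=-1)
    summary = (w_star * np.where(valid, e, 0.0)).sum(axis=-1) / sw_star
    se = np.sqrt(1.0 / sw_star)
    t = summary / se
    df = np.maximum(k - 1, 1)
    p = np.where(k > 1, 2.0 * sps.t.sf(np.abs(t), df), np.nan)
    return summary, se, tau2, t, p, k


def meta_random_effects(
    effects: Sequence[float], variances: Sequence[float]
) -> MetaResult:
    """DerSimonian-Laird random-effects meta-analysis of k donor effects.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed
    weights w_i = 1/v_i; the summary uses weights 1/(v_i + tau^2) and is
    tested with a two-sided t-test at k-1 degrees of freedom.
    """
    e = np.asarray(list(effects), dtype=float)
    v = np.asarray(list(variances), dtype=float)
    if e.size == 0:
        raise ValueError("at least one effect is required")
    if e.ndim != 1 or v.shape != e.shape:
        raise ValueError("effects and variances must be equal-length 1-d sequences")
    summary, se, tau2, t, p, k = pool_effects(e, v)
    return MetaResult(
        effect=float(summary), se=float(se), tau2=float(tau2),
        t=float(t), p=float(p), k=int(k),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_contrast(a: np.ndarray, b: np.ndarray):
    """Two-sided unpaired Welch t-test row-wise: difference of means b - a.

    ``a`` and ``b`` are 2-d (genes x samples).  Returns (fc, var_fc, p) where
    fc is mean(b) - mean(a) (a log2 fold change for log2 inputs) and
    var_fc = s_a^2/n_a + s_b^2/n_b, the non-pooled variance of the difference.
    Degenerate rows with var_fc == 0 get p = 1 when fc == 0, else p = 0.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    fc = b.mean(axis=1) - a.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    var_fc = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / np.sqrt(var_fc)
        df = var_fc**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p = 2.0 * sps.t.sf(np.abs(t), df)
    zero = var_fc == 0
    p[zero] = np.where(fc[zero] == 0, 1.0, 0.0)
    return fc, var_fc, p
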