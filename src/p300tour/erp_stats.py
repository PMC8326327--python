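"""Condition-averaged ERPs and per-timepoint permutation statistics.

The target/nontarget contrast at one channel is tested per timepoint with a
permutation test whose statistic is the two-sample (pooled-variance) t; the
p-value uses +1 smoothing, p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm),
so it can never be exactly zero. Multiple-testing control is
Benjamini-Yekutieli step-up FDR, valid under arbitrary dependence across
timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import EpochSet


@dataclass
class ErpStatResult:
    times_ms: np.ndarray
    target_mean: np.ndarray
    target_se: np.ndarray
    nontarget_mean: np.ndarray
    nontarget_se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray        # boolean mask after BY FDR
    n_permutations: int = 10_000
    alpha: float = 0.05
    q: float = 0.05
    channel: str = "Cz"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "target_mean_uV": self.target_mean,
                "target_se_uV": self.target_se,
                "nontarget_mean_uV": self.nontarget_mean,
                "nontarget_se_uV": self.nontarget_se,
                "t": self.t_values,
                "p": self.p_values,
                "significant": self.significant,
            }
        )


def _channel_index(epochs: EpochSet, channel: str) -> int:
    try:
        return epochs.channel_names.index(channel)
    except ValueError:
        raise ValueError(
            f"unknown channel {channel!r}; have {', '.join(epochs.channel_names)}"
        ) from None


def average_erp(epochs: EpochSet, channel: str = "Cz"):
    """Pointwise (mean, SE) per condition at one channel.

    Returns ``(times_ms, (target_mean, target_se), (nontarget_mean,
    nontarget_se))``. SE is SD/sqrt(n) with ddof=1; a single-epoch
    condition gets an all-zero SE curve by convention.
    """
    ci = _channel_index(epochs, channel)
    out = []
    for cond in (1, 0):
        x = epochs.data[epochs.labels == cond, ci, :]
        if x.shape[0] == 0:
            raise ValueError(f"condition {cond} has no epochs")
        mean = x.mean(axis=0)
        if x.shape[0] < 2:
            se = np.zeros_like(mean)
        else:
            se = x.std(axis=0, ddof=1) / np.sqrt(x.shape[0])
        out.append((mean, se))
    return epochs.times_ms, out[0], out[1]


def _pooled_t(sum_a, sumsq_a, na, sum_b, sumsq_b, nb):
    """Two-sample pooled-variance t from per-group sums, vectorized."""
    mean_a, mean_b = sum_a / na, sum_b / nb
    ss_a = sumsq_a - na * mean_a**2
    ss_b = sumsq_b - nb * mean_b**2
    df = na + nb - 2
    sp2 = (ss_a + ss_b) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    return t, denom


def permutation_ttest(
    target: np.ndarray,
    nontarget: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint permutation test with a two-sided t statistic.

    ``target`` and ``nontarget`` are (epochs, timepoints) arrays from one
    channel. Condition labels are randomly reassigned ``n_perm`` times and
    the observed |t| compared against the permutation distribution.
    Timepoints with zero pooled variance get p = 1 with a warning.
    """
    a = np.atleast_2d(np.asarray(target, dtype=float))
    b = np.atleast_2d(np.asarray(nontarget, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions disagree on the number of timepoints")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 epochs per condition")
    rng = np.random.default_rng(seed)

    X = np.vstack([a, b])            # (n, T)
    X2 = X**2
    n = na + nb
    tot, tot2 = X.sum(axis=0), X2.sum(axis=0)

    s_a, sq_a = a.sum(axis=0), (a**2).sum(axis=0)
    t_obs, denom = _pooled_t(s_a, sq_a, na, tot - s_a, tot2 - sq_a, nb)
    zero_var = ~np.isfinite(t_obs) | (denom == 0)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} timepoint(s) have zero pooled variance; "
            "their p is set to 1",
            stacklevel=2,
        )
        t_obs = np.where(zero_var, 0.0, t_obs)

    # 0/1 assignment matrix: each row one random relabelling with na "targets".
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :na]
    G = np.zeros((n_perm, n))
    np.put_along_axis(G, picks, 1.0, axis=1)
    S, SQ = G @ X, G @ X2
    t_perm, _ = _pooled_t(S, SQ, na, tot - S, tot2 - SQ, nb)
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=0.0, neginf=0.0)

    exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(zero_var, 1.0, p)
    return t_obs, p


def parametric_ttest(
    target: np.ndarray, nontarget: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Plain per-timepoint two-sided two-sample t-test (pooled variance)."""
    res = stats.ttest_ind(
        np.atleast_2d(target), np.atleast_2d(nontarget), axis=0, equal_var=True
    )
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def fdr_by(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Yekutieli step-up rejection mask at level ``q``.

    Uses the harmonic-sum correction factor c(m) = sum_{i<=m} 1/i, valid
    under arbitrary dependence among the tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(p, alpha=q, method="fdr_by")
    return reject


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg mask (less conservative; BY is a subset of it)."""
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.asarray(p_values, float), alpha=q, method="fdr_bh")
    return reject


def erp_statistics(
    epochs: EpochSet,
    channel: str = "Cz",
    n_perm: int = 10_000,
    alpha: float = 0.05,
    q: float = 0.05,
    seed: int | None = None,
    method: str = "permutation",
) -> ErpStatResult:
    """Full channel analysis: condition curves, tests, and the BY mask."""
    ci = _channel_index(epochs, channel)
    times, (tm, tse), (nm, nse) = average_erp(epochs, channel)
    a = epochs.data[epochs.labels == 1, ci, :]
    b = epochs.data[epochs.labels == 0, ci, :]
    if method == "permutation":
        t_vals, p_vals = permutation_ttest(a, b, n_perm=n_perm, seed=seed)
    elif method == "parametric":
        t_vals, p_vals = parametric_ttest(a, b)
        p_vals = np.clip(p_vals, np.finfo(float).tiny, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ErpStatResult(
        times_ms=times,
        target_mean=tm,
        target_se=tse,
        nontarget_mean=nm,
        nontarget_se=nse,
        t_values=t_vals,
        p_values=p_vals,
        significant=fdr_by(p_vals, q),
        n_permutations=n_perm,
        alpha=alpha,
        q=q,
        channel=channel,
    )
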