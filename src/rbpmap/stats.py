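"""Statistical enrichment filter: per-protein two-group tests with optional
empirical-Bayes variance moderation and Benjamini-Hochberg correction.

This is the alternative to the pairwise-ROC filter.  Reporter values are
log2-transformed; each protein is tested for enrichment of the experimental
channels over pooled negative-control channels with a two-sample t-test.
With moderation enabled, per-protein variances are shrunk toward a pooled
prior fitted across proteins (Smyth-style empirical Bayes, prior degrees of
freedom estimated by method of moments on the log residual variances), which
stabilizes the test when each group has only 2-3 replicates.  A protein is
called enriched when its BH-adjusted p-value falls below alpha and its
linear-scale fold change exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .quant_io import QuantTable, ValidationError


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, returned in the original order.

    q_(i) = p_(i) * m / i on the ascending sort, with monotonicity enforced
    from the largest rank downward and values capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (monotone decreasing)
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene residual variances toward a fitted prior.

    Fits a scaled inverse-chi-square prior (s0^2 on d0 d.f.) to the observed
    variances by method of moments on log(s2), then returns the posterior
    variances (d0*s0^2 + df*s2) / (d0 + df) along with (d0, s0^2).  With too
    little between-gene spread the prior d.f. is infinite and every variance
    collapses to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.nanmean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df[ok] / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s2_0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))) \
            if np.isfinite(d0) else float(np.exp(e_mean))
    else:
        d0, s2_0 = np.inf, float(np.exp(e_mean))
    if np.isfinite(d0):
        post = (d0 * s2_0 + df * s2) / (d0 + df)
    else:
        post = np.full_like(s2, s2_0)
    post = np.where(ok, post, np.nan)
    return post, d0, s2_0


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    """Per-gene effect sizes, (moderated) t statistics and BH-adjusted p-values.

    ``table`` columns: effect (log2 difference), fold_change (linear), t,
    p_value, adj_p, enriched, tested.  Untestable genes (fewer than two
    observations in a group) carry tested=False and are excluded from the
    multiple-testing correction.
    """

    table: pd.DataFrame
    alpha: float
    fc_threshold: float
    d0: float | None = None
    s2_prior: float | None = None

    def enriched_set(self) -> set:
        return set(self.table.index[self.table["enriched"]])


def _log2_groups(table: QuantTable, labels: list[str]) -> np.ndarray:
    df = table.data.set_index("gene_symbol")
    vals = df[list(labels)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, np.nan)), np.nan)
    return out


def _finalize(genes, effect, fc, tstat, pval, alpha, fc_threshold, d0=None, s2_0=None):
    tested = np.isfinite(pval)
    adj = np.full_like(pval, np.nan)
    if tested.any():
        adj[tested] = bh_adjust(np.clip(pval[tested], np.nextafter(0, 1), 1.0))
    enriched = tested & (adj < alpha) & (fc > fc_threshold)
    table = pd.DataFrame({
        "effect": effect, "fold_change": fc, "t": tstat,
        "p_value": pval, "adj_p": adj, "enriched": enriched, "tested": tested,
    }, index=pd.Index(genes, name="gene_symbol"))
    return StatResult(table, alpha, fc_threshold, d0, s2_0)


def test_enrichment(table: QuantTable, exp_channels: list[str], ctrl_channels: list[str],
                    *, moderation: bool = True, alpha: float = 0.05,
                    fc_threshold: float = 1.0) -> StatResult:
    """Test each protein for enrichment of experimental over control channels.

    Log2-scale two-sample t-test per protein.  With ``moderation`` the pooled
    per-gene variance is shrunk by empirical Bayes and the t-test gains the
    prior degrees of freedom; without it, an ordinary Welch t-test is used.
    The fold change is the ratio of linear-scale group means.  p-values are
    two-sided; direction is enforced by the fold-change threshold.
    """
    X = _log2_groups(table, exp_channels)
    Y = _log2_groups(table, ctrl_channels)
    genes = table.gene_symbols
    n1 = np.isfinite(X).sum(axis=1)
    n2 = np.isfinite(Y).sum(axis=1)
    with np.errstate(invalid="ignore"):
        m1, m2 = np.nanmean(X, axis=1), np.nanmean(Y, axis=1)
        v1 = _nanvar(X, n1)
        v2 = _nanvar(Y, n2)
    effect = m1 - m2
    lin = table.data.set_index("gene_symbol")
    fc = (lin[list(exp_channels)].mean(axis=1, skipna=True)
          / lin[list(ctrl_channels)].mean(axis=1, skipna=True)).to_numpy(dtype=float)
    testable = (n1 >= 2) & (n2 >= 2)

    tstat = np.full(len(genes), np.nan)
    pval = np.full(len(genes), np.nan)
    d0 = s2_0 = None
    if moderation:
        df_resid = np.where(testable, n1 + n2 - 2, np.nan)
        s2 = np.where(testable,
                      ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1),
                      np.nan)
        s2_post, d0, s2_0 = moderate_variances(s2, df_resid)
        se = np.sqrt(s2_post * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
        df_total = df_resid + d0        # infinite prior d.f. -> normal tail
        idx = testable & np.isfinite(se)
        tstat[idx] = _safe_t(effect[idx], se[idx])
        pval[idx] = 2.0 * sps.t.sf(np.abs(tstat[idx]), df_total[idx])
    else:
        idx = testable
        se = np.sqrt(v1 / np.maximum(n1, 1) + v2 / np.maximum(n2, 1))
        tstat[idx] = _safe_t(effect[idx], se[idx])
        num = (v1 / n1 + v2 / n2) ** 2
        den = (v1 / n1) ** 2 / np.maximum(n1 - 1, 1) + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            df_w = np.where(den > 0, num / den, n1 + n2 - 2)
        pval[idx] = np.where(
            np.isfinite(tstat[idx]),
            2.0 * sps.t.sf(np.abs(tstat[idx]), df_w[idx]),
            0.0,
        )
        pval[idx & (tstat == 0)] = 1.0
    return _finalize(genes, effect, fc, tstat, pval, alpha, fc_threshold, d0, s2_0)


def reference_contrast(table: QuantTable,
                       target_channels: list[str], target_ctrl_channels: list[str],
                       ref_channels: list[str], ref_ctrl_channels: list[str],
                       *, moderation: bool = True, alpha: float = 0.05,
                       fc_threshold: float = 1.0) -> StatResult:
    """Contrast of enrichments: (target - target controls) - (reference - reference controls).

    Estimates, per protein, the log2 enrichment specific to the target
    construct beyond what the spatial-reference construct already shows; a
    protein equally enriched by both has effect ~ 0.  Linear model with a
    single pooled residual variance over the four groups, moderated as in
    :func:`test_enrichment`.
    """
    groups = [_log2_groups(table, ch) for ch in
              (target_channels, target_ctrl_channels, ref_channels, ref_ctrl_channels)]
    genes = table.gene_symbols
    ns = [np.isfinite(G).sum(axis=1) for G in groups]
    with np.errstate(invalid="ignore"):
        means = [np.nanmean(G, axis=1) for G in groups]
        vs = [_nanvar(G, n) for G, n in zip(groups, ns)]
    effect = (means[0] - means[1]) - (means[2] - means[3])
    lin = table.data.set_index("gene_symbol")

    def lin_mean(ch):
        return lin[list(ch)].mean(axis=1, skipna=True).to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = ((lin_mean(target_channels) / lin_mean(target_ctrl_channels))
              / (lin_mean(ref_channels) / lin_mean(ref_ctrl_channels)))
    testable = np.all([n >= 2 for n in ns], axis=0)
    df_resid = np.where(testable, sum(ns) - 4, np.nan)
    s2 = np.where(testable,
                  sum((n - 1) * v for n, v in zip(ns, vs)) / np.maximum(sum(ns) - 4, 1),
                  np.nan)
    tstat = np.full(len(genes), np.nan)
    pval = np.full(len(genes), np.nan)
    d0 = s2_0 = None
    if moderation:
        s2_use, d0, s2_0 = moderate_variances(s2, df_resid)
        df_total = df_resid + d0        # infinite prior d.f. -> normal tail
    else:
        s2_use, df_total = s2, df_resid
    se = np.sqrt(s2_use * sum(1.0 / np.maximum(n, 1) for n in ns))
    idx = testable & np.isfinite(se)
    tstat[idx] = _safe_t(effect[idx], se[idx])
    pval[idx] = np.where(np.isfinite(tstat[idx]),
                         2.0 * sps.t.sf(np.abs(tstat[idx]), df_total[idx]),
                         0.0)
    pval[idx & (tstat == 0)] = 1.0
    return _finalize(genes, effect, fc, tstat, pval, alpha, fc_threshold, d0, s2_0)


def _nanvar(G: np.ndarray, n: np.ndarray) -> np.ndarray:
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)   # rows with <2 values
        v = np.nanvar(G, axis=1, ddof=1)
    return np.where(n >= 2, v, np.nan)


def _safe_t(effect: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se,
                     np.where(effect == 0, 0.0, np.sign(effect) * np.inf))
    return t
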