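"""Differential junction expression (DJE).

Pipeline: filter junctions by mean read count, transform to logCPM,
estimate observation-level precision weights from the mean-variance
trend, fit a weighted two-group linear model per junction, moderate the
residual variances with an empirical-Bayes prior, and report two
statistics per junction:

* absolute log2 fold change (``logFC_abs``) — the change in the
  junction's own normalized expression; and
* relative log2 fold change (``logFC_rel``, junction *usage*) — the
  junction's logFC minus the mean logFC of the other retained junctions
  of the same gene, a diffSplice-style contrast that isolates splicing
  changes from whole-gene expression shifts.

Both are tested with moderated t-statistics (residual variance shrunk
toward a pooled prior with df ``d0`` and value ``s0^2`` estimated by
method-of-moments on log s^2) and Benjamini-Hochberg adjusted
separately. A junction is called up (down) only when its |logFC_abs|
exceeds the cutoff AND both FDRs fall below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .junctions import ANNOTATED, JunctionTable

__all__ = [
    "ModerationParams",
    "DJEResult",
    "filter_junctions",
    "logcpm",
    "variance_weights",
    "moderated_fit",
    "fit_dje",
    "bh_fdr",
    "export_spliceplot",
]

_D0_CAP = 1e6  # finite stand-in for an infinite prior df


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes variance prior: df d0 and prior variance s0^2."""

    d0: float
    s0_sq: float
    residual_df: float


@dataclass
class DJEResult:
    """Per-junction DJE statistics plus the moderation parameters used."""

    table: pd.DataFrame
    moderation: ModerationParams
    cutoff: float
    alpha: float
    contrast: str


# ---------------------------------------------------------------------------

def filter_junctions(table: JunctionTable, min_mean: float = 10.0
                     ) -> JunctionTable:
    """Retain junctions whose across-sample mean count is >= ``min_mean``.

    Library sizes are left untouched (they reflect total mapped reads,
    not the filtered junction set).
    """
    means = table.counts.mean(axis=1)
    keep = means[means >= min_mean].index
    return table.subset(list(keep))


def logcpm(table: JunctionTable) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + 0.5)/(libsize + 1) * 1e6)."""
    libs = table.library_sizes.to_numpy()
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    y = (table.counts.to_numpy(dtype=float) + 0.5) / (libs + 1.0) * 1e6
    return pd.DataFrame(np.log2(y), index=table.counts.index,
                        columns=table.counts.columns)


# ---------------------------------------------------------------------------
# Observation-level weights (voom-style mean-variance trend)
# ---------------------------------------------------------------------------

def _two_group_design(groups: pd.Series | np.ndarray) -> tuple[np.ndarray, str]:
    groups = pd.Series(list(groups))
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    # the first-appearing level is the condition of interest, the second
    # the reference: logFC > 0 means higher in the first group
    x = (groups == levels[0]).to_numpy(dtype=float)
    return np.column_stack([np.ones_like(x), x]), f"{levels[0]}-{levels[1]}"


def _rowwise_wls(y: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Weighted least squares of each row of y on design [1, x].

    Returns (beta0, beta1, sigma2, se1_unscaled, fitted) where sigma2 is
    the weighted residual variance on n-2 df and se1_unscaled the
    standard-error factor of beta1 (multiply by sigma to get the SE).
    """
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swxy = (w * x * y).sum(axis=1)
    denom = sw * swxx - swx ** 2
    beta1 = (sw * swxy - swx * swy) / denom
    beta0 = (swy - swx * beta1) / sw
    fitted = beta0[:, None] + beta1[:, None] * x
    resid = y - fitted
    df = y.shape[1] - 2
    sigma2 = (w * resid ** 2).sum(axis=1) / df
    se1_unscaled = np.sqrt(sw / denom)
    return beta0, beta1, sigma2, se1_unscaled, fitted


def variance_weights(logcpm_mat: pd.DataFrame,
                     groups: pd.Series | np.ndarray,
                     span: float = 0.5) -> pd.DataFrame:
    """Inverse-variance observation weights from the mean-variance trend.

    A lowess curve of sqrt(residual sd) versus mean logCPM is fitted
    across junctions and evaluated at each observation's fitted logCPM;
    the weight is the predicted sqrt-sd to the power -4 (an inverse
    variance). With fewer than five junctions the trend is degenerate
    and unit weights are returned.
    """
    design, _ = _two_group_design(groups)
    y = logcpm_mat.to_numpy(dtype=float)
    n_j, n_s = y.shape
    if n_s < design.shape[1] + 1:
        raise ValueError("fewer samples than design df + 1")
    if n_j < 5:
        return pd.DataFrame(np.ones_like(y), index=logcpm_mat.index,
                            columns=logcpm_mat.columns)
    x = design[:, 1]
    ones = np.ones_like(y)
    _, _, sigma2, _, fitted = _rowwise_wls(y, x, ones)
    sqrt_sd = np.sqrt(np.sqrt(np.maximum(sigma2, 1e-12)))
    mean_lcpm = y.mean(axis=1)

    from statsmodels.nonparametric.smoothers_lowess import lowess

    fit = lowess(sqrt_sd, mean_lcpm, frac=span, it=3, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    xs, idx = np.unique(xs, return_index=True)
    ys = ys[idx]
    pred = np.interp(fitted, xs, ys)  # constant extrapolation at the edges
    pred = np.maximum(pred, 1e-6)
    w = pred ** -4
    return pd.DataFrame(w, index=logcpm_mat.index, columns=logcpm_mat.columns)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation (method-of-moments on log s^2)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return _D0_CAP * 2
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed variances.

    Returns (d0, s0_sq); d0 is capped at 1e6 when the excess spread of
    log s^2 over its sampling variability is non-positive (effectively
    an infinite prior).
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    if n < 2:
        return _D0_CAP, float(np.exp(emean))
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return _D0_CAP, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    d0 = min(d0, _D0_CAP)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderated_fit(y: pd.DataFrame, groups, weights: pd.DataFrame | None = None,
                  d0: float | None = None) -> tuple[pd.DataFrame, ModerationParams]:
    """Weighted two-group fit with empirical-Bayes moderated t per row.

    ``d0=0`` disables moderation (ordinary weighted t-statistics);
    ``d0=None`` estimates the prior from the data. Returns the per-row
    statistics and the moderation parameters.
    """
    design, contrast = _two_group_design(groups)
    x = design[:, 1]
    n1 = int((x == 0).sum())
    n2 = int((x == 1).sum())
    if min(n1, n2) < 2:
        raise ValueError("both groups need >= 2 samples")
    ym = y.to_numpy(dtype=float)
    w = (np.ones_like(ym) if weights is None
         else weights.reindex(index=y.index, columns=y.columns).to_numpy(float))
    _, beta1, sigma2, se1_unscaled, _ = _rowwise_wls(ym, x, w)
    df_resid = ym.shape[1] - 2
    if d0 is None:
        d0_est, s0_sq = _fit_f_dist(sigma2, df_resid)
    else:
        d0_est = float(d0)
        s0_sq = float(np.exp(np.mean(np.log(np.maximum(sigma2, 1e-300))))) \
            if d0_est > 0 else float("nan")
    if d0_est > 0:
        s2_post = (d0_est * s0_sq + df_resid * sigma2) / (d0_est + df_resid)
    else:
        s2_post = sigma2.copy()
    df_total = min(df_resid + d0_est, df_resid * len(sigma2))
    t = beta1 / (se1_unscaled * np.sqrt(s2_post))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame({
        "logFC": beta1, "t": t, "p": p, "s2": sigma2, "s2_post": s2_post,
        "se_unscaled": se1_unscaled,
    }, index=y.index)
    params = ModerationParams(d0=d0_est, s0_sq=s0_sq, residual_df=df_resid)
    out.attrs["df_total"] = df_total
    out.attrs["contrast"] = contrast
    return out, params


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The full DJE fit
# ---------------------------------------------------------------------------

def fit_dje(table: JunctionTable, groups, statuses: pd.DataFrame,
            weights: pd.DataFrame | None = None, cutoff: float = 1.0,
            alpha: float = 0.05, d0: float | None = None,
            compute_weights: bool = True) -> DJEResult:
    """Differential junction expression with absolute and relative statistics.

    Parameters
    ----------
    table : filtered JunctionTable
    groups : per-sample two-level labels; the contrast is level2 - level1
        in order of first appearance.
    statuses : output of :func:`djsplice.junctions.annotate_junctions`
        (gene assignment + annotation class), used for the relative
        (usage) contrast and carried into the result.
    weights : optional observation weights; computed from the
        mean-variance trend when omitted and ``compute_weights`` is true.
    cutoff : |logFC_abs| call threshold (1.0 for tumor/normal-style
        contrasts, 0.5 for condition contrasts).
    d0 : override for the prior df (0 = unmoderated; None = estimate).
    """
    y = logcpm(table)
    if weights is None and compute_weights:
        weights = variance_weights(y, groups)
    fit, params = moderated_fit(y, groups, weights=weights, d0=d0)
    df_total = fit.attrs["df_total"]

    res = pd.DataFrame(index=y.index)
    res["gene_id"] = statuses.reindex(y.index)["gene_id"]
    res["status"] = statuses.reindex(y.index)["status"]
    res["logFC_abs"] = fit["logFC"]
    res["t_abs"] = fit["t"]
    res["p_abs"] = fit["p"]
    res["FDR_abs"] = bh_fdr(fit["p"].to_numpy())

    # Relative logFC (usage): junction logFC minus the mean logFC of the
    # gene's other retained junctions; SE combines the moderated
    # variances assuming independent junction fits.
    var_hat = (fit["se_unscaled"] ** 2 * fit["s2_post"]).to_numpy()
    lfc = fit["logFC"].to_numpy()
    logfc_rel = np.full(len(res), np.nan)
    t_rel = np.full(len(res), np.nan)
    pos = {k: i for i, k in enumerate(y.index)}
    for gene, members in res.groupby("gene_id").groups.items():
        idx = [pos[k] for k in members]
        if len(idx) < 2:
            continue
        idx = np.array(idx)
        tot = lfc[idx].sum()
        vtot = var_hat[idx].sum()
        m = len(idx) - 1
        for i in idx:
            other_mean = (tot - lfc[i]) / m
            logfc_rel[i] = lfc[i] - other_mean
            v_rel = var_hat[i] + (vtot - var_hat[i]) / m ** 2
            t_rel[i] = logfc_rel[i] / np.sqrt(v_rel)
    res["logFC_rel"] = logfc_rel
    res["t_rel"] = t_rel
    res["p_rel"] = 2.0 * stats.t.sf(np.abs(t_rel), df_total)
    res["rel_tested"] = ~np.isnan(logfc_rel)
    res["FDR_rel"] = np.nan
    tested = res["rel_tested"].to_numpy()
    if tested.any():
        res.loc[tested, "FDR_rel"] = bh_fdr(res.loc[tested, "p_rel"].to_numpy())

    sig = (res["FDR_abs"] < alpha) & (res["FDR_rel"] < alpha) & tested
    res["class"] = "ns"
    res.loc[sig & (res["logFC_abs"] > cutoff), "class"] = "up"
    res.loc[sig & (res["logFC_abs"] < -cutoff), "class"] = "down"
    return DJEResult(res, params, cutoff, alpha, fit.attrs["contrast"])


_CLASS_COLORS = {"up": "red", "down": "blue", "ns": "black"}


def export_spliceplot(result: DJEResult, statuses: pd.DataFrame,
                      gene: str) -> dict:
    """Gene-wise splice-plot data records.

    One record per retained junction of ``gene``: transcript-order index
    (ascending along transcription; reverse-strand genes run
    right-to-left genomically), logFC_abs, class color (red=up,
    blue=down, black=ns) and a novel flag. ``labeled_indices`` marks the
    first, last and differentially expressed junctions.
    """
    res = result.table
    members = res.index[res["gene_id"] == gene]
    if len(members) == 0:
        raise KeyError(f"gene {gene!r} not present in the DJE result")
    recs = []
    for k in members:
        txn = statuses.at[k, "txn_index"]
        recs.append({
            "junction": k,
            "txn_index": int(txn) if pd.notna(txn) else None,
            "logFC_abs": float(res.at[k, "logFC_abs"]),
            "logFC_rel": (float(res.at[k, "logFC_rel"])
                          if pd.notna(res.at[k, "logFC_rel"]) else None),
            "FDR_abs": float(res.at[k, "FDR_abs"]),
            "class": res.at[k, "class"],
            "color": _CLASS_COLORS[res.at[k, "class"]],
            "novel": res.at[k, "status"] != ANNOTATED,
        })
    recs.sort(key=lambda r: (r["txn_index"] is None, r["txn_index"]))
    indices = [r["txn_index"] for r in recs if r["txn_index"] is not None]
    labeled = set()
    if indices:
        labeled.update((min(indices), max(indices)))
    labeled.update(r["txn_index"] for r in recs
                   if r["class"] != "ns" and r["txn_index"] is not None)
    return {
        "gene": gene,
        "cutoff": result.cutoff,
        "alpha": result.alpha,
        "contrast": result.contrast,
        "junctions": recs,
        "labeled_indices": sorted(labeled),
    }
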