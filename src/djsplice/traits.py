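"""Trait association via biweight midcorrelation and set over-representation.

Junction or event profiles are correlated against continuous sample
traits (drug-response AUC, CRISPR gene-effect scores) with the biweight
midcorrelation (bicor) — a robust correlation built on medians and MADs
with Tukey-biweight outlier down-weighting (tuning constant 9). P-values
use the Student-t approximation on n-2 df; pairs are BH-adjusted and
ranked by |rho|. A radar-chart export keeps pairs with FDR < alpha and
|rho| > rho_min on a radial axis spanning -0.5..0.5.

Ranked correlates can be tested for gene-set over-representation with a
hypergeometric tail test against a user-supplied universe.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dje import bh_fdr

__all__ = ["bicor", "associate", "radar_export", "overrepresent",
           "read_gmt", "write_gmt"]


def _biweights(x: np.ndarray, c: float = 9.0) -> tuple[np.ndarray, bool]:
    """Tukey biweights around the median; Pearson fallback flag on MAD=0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.ones_like(x), True
    u = (x - med) / (c * mad)
    w = (1 - u ** 2) ** 2
    w[np.abs(u) >= 1] = 0.0
    return w, False


def bicor(x, y, c: float = 9.0) -> float:
    """Biweight midcorrelation of two paired vectors.

    Falls back to the Pearson correlation (with a warning) for a vector
    whose MAD is zero, where the biweight standardization is undefined.
    Requires >= 3 paired finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("bicor needs >= 3 paired finite values")
    wx, fall_x = _biweights(x, c)
    wy, fall_y = _biweights(y, c)
    if fall_x or fall_y:
        warnings.warn("zero MAD: falling back to Pearson correlation",
                      RuntimeWarning, stacklevel=2)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])
    xc = (x - np.median(x)) * wx
    yc = (y - np.median(y)) * wy
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def _bicor_p(rho: float, n: int) -> float:
    """Two-sided p from the Student-t approximation on n-2 df."""
    if not np.isfinite(rho) or n < 3:
        return float("nan")
    rho = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def associate(features: pd.DataFrame, traits: pd.DataFrame,
              alpha: float = 0.05, rho_min: float = 0.2,
              min_samples: int = 3) -> pd.DataFrame:
    """bicor of every (feature, trait) pair on pairwise-complete samples.

    ``features`` and ``traits`` are row-per-variable, column-per-sample
    frames; only shared sample columns are used. Returns records
    (feature, trait, rho, p, FDR, n_used, pass_gates) ranked by |rho|.
    """
    shared = [s for s in features.columns if s in set(traits.columns)]
    if len(shared) < min_samples:
        raise ValueError("fewer than 3 overlapping samples")
    rows = []
    for f in features.index:
        x_all = features.loc[f, shared].to_numpy(dtype=float)
        for t in traits.index:
            y_all = traits.loc[t, shared].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            n = int(ok.sum())
            if n < min_samples:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rho = bicor(x_all[ok], y_all[ok])
            rows.append({"feature": f, "trait": t, "rho": rho,
                         "p": _bicor_p(rho, n), "n_used": n})
    if not rows:
        raise ValueError("no testable (feature, trait) pairs")
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["FDR"] = np.nan
    if ok.any():
        out.loc[ok, "FDR"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["pass_gates"] = (out["FDR"] < alpha) & (out["rho"].abs() > rho_min)
    out = out.reindex(out["rho"].abs().sort_values(ascending=False).index)
    return out.reset_index(drop=True)


def radar_export(assoc: pd.DataFrame, alpha: float = 0.05,
                 rho_min: float = 0.2,
                 axis_range: tuple[float, float] = (-0.5, 0.5)) -> dict:
    """Radar-chart data: gated top-ranked correlations on a -0.5..0.5 axis."""
    kept = assoc[(assoc["FDR"] < alpha) & (assoc["rho"].abs() > rho_min)]
    return {
        "axis_range": list(axis_range),
        "alpha": alpha,
        "rho_min": rho_min,
        "spokes": [
            {"feature": r.feature, "trait": r.trait,
             "rho": float(np.clip(r.rho, *axis_range)), "FDR": float(r.FDR)}
            for r in kept.itertuples()
        ],
    }


def overrepresent(selection: Sequence[str],
                  gene_sets: Mapping[str, Sequence[str]],
                  universe: Sequence[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selection`` in each set.

    ``selection`` is a ranked/gated gene list (e.g. top correlates);
    all sets must be subsets of ``universe``. Per set the upper
    hypergeometric tail P(X >= overlap) is computed and BH-adjusted.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uniset = set(uni)
    sel = [g for g in dict.fromkeys(selection) if g in uniset]
    rows = []
    for name, members in gene_sets.items():
        mem = set(members)
        if not mem <= uniset:
            raise ValueError(f"gene set {name!r} not a subset of the universe")
        k = len(mem & set(sel))
        # P(X >= k) for X ~ Hypergeom(M=len(uni), K=len(mem), n=len(sel))
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(mem), len(sel)))
        rows.append({"set": name, "overlap": k, "set_size": len(mem),
                     "selection_size": len(sel), "universe_size": len(uni),
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["FDR"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
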