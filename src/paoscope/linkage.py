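"""Ecosystem-functioning linkage.

Derived field quantities (%OM from loss-on-ignition, GPP from flux balance)
and the correlation screens used to connect PAO community metrics with
ecosystem function and with each other (the complexity-begets-stability
screen).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["percent_om", "gpp", "correlation_screen"]


def percent_om(loi):
    """Convert % loss-on-ignition to % soil organic matter: 0.7*LOI - 0.23.

    Values that come out negative (only possible for LOI < ~0.33%) are
    floored at zero with a warning.
    """
    arr = np.asarray(loi, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("%LOI must lie in [0, 100]")
    om = arr * 0.7 - 0.23
    if np.any(om < 0):
        warnings.warn("negative %OM floored at 0")
        om = np.maximum(om, 0.0)
    return float(om) if np.isscalar(loi) else om


def gpp(nee, er):
    """Gross primary production estimated as ER - NEE."""
    out = np.asarray(er, dtype=float) - np.asarray(nee, dtype=float)
    return float(out) if np.isscalar(nee) and np.isscalar(er) else out


def correlation_screen(
    x: pd.DataFrame,
    y: pd.DataFrame,
    r_min: float = 0.6,
    alpha: float = 0.05,
    method: str = "pearson",
    bh_adjust: bool = False,
) -> tuple[pd.DataFrame, int]:
    """All-pairs correlation screen between columns of ``x`` and ``y``.

    Computes the correlation (Pearson or Spearman) of every x-column with
    every y-column over matched rows and flags pairs with |r| >= ``r_min``
    and p < ``alpha`` (the conjunction, on raw p-values by default; set
    ``bh_adjust`` for Benjamini-Hochberg). Constant columns are excluded with
    a warning. Returns (pair table, number of flagged pairs); the pair table
    carries signed r, p, sign and the flag.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have matched rows")
    if len(x) < 4:
        raise ValueError("need >= 4 observations")
    if method not in {"pearson", "spearman"}:
        raise ValueError("method must be 'pearson' or 'spearman'")

    def _usable(df: pd.DataFrame) -> list[str]:
        cols = []
        for c in df.columns:
            v = df[c].to_numpy(dtype=float)
            if np.all(np.isfinite(v)) and np.std(v) > 0:
                cols.append(c)
            else:
                warnings.warn(f"column {c!r} constant or non-finite; excluded")
        return cols

    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for cx in _usable(x):
        for cy in _usable(y):
            res = corr(x[cx].to_numpy(dtype=float), y[cy].to_numpy(dtype=float))
            r, p = float(res.statistic), float(res.pvalue)
            rows.append({"x": cx, "y": cy, "r": r, "p": p, "sign": int(np.sign(r))})
    pairs = pd.DataFrame(rows, columns=["x", "y", "r", "p", "sign"])
    if len(pairs) == 0:
        return pairs.assign(flagged=pd.Series(dtype=bool)), 0
    pcol = pairs["p"].to_numpy()
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        pcol = multipletests(pcol, method="fdr_bh")[1]
        pairs["p_adj"] = pcol
    pairs["flagged"] = (pairs["r"].abs() >= r_min) & (pcol < alpha)
    return pairs, int(pairs["flagged"].sum())
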