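"""Diversity and treatment-effect statistics.

Shannon diversity (taxonomic OTUs or phenotypic OPUs), functional redundancy,
linear mixed-effects treatment models with renormalized effect sizes, and the
linear-versus-logarithmic functionality-biodiversity fit comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "shannon",
    "shannon_mm",
    "functional_redundancy",
    "fit_lmm",
    "renormalize_effects",
    "compare_fits",
    "EffectSize",
    "FitComparison",
]


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i of a nonnegative abundance vector.

    Zero entries contribute nothing; the vector is normalized internally.
    Natural log by default (ecology convention); pass ``base`` to change it.

    Raises
    ------
    ValueError
        If no entry is positive or any entry is negative.
    """
    a = np.asarray(abundances, dtype=float).ravel()
    if a.size == 0 or np.all(a == 0):
        raise ValueError("Shannon diversity needs at least one positive abundance")
    if np.any(a < 0):
        raise ValueError("abundances must be nonnegative")
    p = a[a > 0]
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def shannon_mm(counts) -> float:
    """Miller-Madow bias-corrected Shannon diversity of a count vector.

    The plug-in estimator underestimates H by ~(K-1)/(2N) for K observed
    categories in N counts; the correction matters for small samples such as
    100-cell OPU compositions.
    """
    c = np.asarray(counts, dtype=float).ravel()
    n = c.sum()
    if n <= 0:
        raise ValueError("need positive total count")
    k = int((c > 0).sum())
    return shannon(c) + (k - 1) / (2.0 * n)


def functional_redundancy(
    contributions: pd.DataFrame, per_category: bool = False
):
    """Functional redundancy FR = (sum_i f_i) / S per function category.

    ``contributions`` is a taxa x categories table of nonnegative functional
    contributions f_i (e.g. per-taxon KO-pathway contributions). For each
    category, the sum of contributions of all contributing taxa is divided by
    S, the number of unique taxa with a positive contribution to that
    category. Categories with no contributor are dropped. The scalar FR is the
    unweighted mean across categories (the per-category table is available via
    ``per_category=True``).
    """
    f = np.asarray(contributions, dtype=float)
    if f.ndim == 1:
        f = f[:, None]
    if np.any(f < 0):
        raise ValueError("functional contributions must be nonnegative")
    contributing = f > 0
    s = contributing.sum(axis=0)
    keep = s > 0
    if not keep.any():
        raise ValueError("no taxon contributes to any function category")
    fr = f[:, keep].sum(axis=0) / s[keep]
    if per_category:
        if isinstance(contributions, pd.DataFrame):
            idx = contributions.columns[keep]
        else:
            idx = np.flatnonzero(keep)
        return pd.Series(fr, index=idx, name="FR")
    return float(fr.mean())


@dataclass
class EffectSize:
    """One fixed-effect estimate from the treatment model."""

    term: str
    beta: float
    se: float
    p: float
    beta_norm: float = field(default=np.nan)

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "beta_norm": self.beta_norm,
        }


def _design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    x = pd.DataFrame(
        {
            "warming": design["warming"].astype(float).to_numpy(),
            "clipping": design["clipping"].astype(float).to_numpy(),
        },
        index=design.index,
    )
    x["warming:clipping"] = x["warming"] * x["clipping"]
    return x


def fit_lmm(
    response,
    design: pd.DataFrame,
    pvalues: str = "t",
    renormalize: bool = True,
) -> list[EffectSize]:
    """Fit Y ~ warming * clipping + (1 | block) and return per-term effects.

    The model is the standard warming x clipping factorial with a random
    block intercept, fitted by REML. Wald p-values use a t reference with
    between-within residual degrees of freedom ``n - p - (n_blocks - 1)`` by
    default (``pvalues="normal"`` switches to the large-sample z
    approximation). If the block variance collapses to ~0 or the mixed fit
    fails, the model falls back to OLS with a logged note.

    Returns EffectSize entries for warming, clipping and their interaction,
    with ``beta_norm`` filled by :func:`renormalize_effects` across the three
    terms unless ``renormalize=False``.
    """
    y = np.asarray(response, dtype=float).ravel()
    if len(y) != len(design):
        raise ValueError("response length does not match design")
    if "block" not in design.columns:
        raise ValueError("design must carry block labels")
    x = _design_matrix(design)
    xmat = sm.add_constant(x.to_numpy())
    rank = np.linalg.matrix_rank(xmat)
    if rank < xmat.shape[1]:
        raise ValueError(
            "rank-deficient design: warming/clipping/interaction are aliased"
        )
    counts = design.groupby(["warming", "clipping"]).size()
    if len(counts) < 4 or counts.min() < 2:
        raise ValueError("need >= 2 samples in each of the four treatments")

    if np.ptp(y) == 0:  # constant response: no effects, nothing to test
        effects = [EffectSize(t, 0.0, 0.0, 1.0, 0.0) for t in
                   ["warming", "clipping", "warming:clipping"]]
        return effects

    groups = design["block"].to_numpy()
    n_groups = len(np.unique(groups))
    n, p = xmat.shape
    terms = ["warming", "clipping", "warming:clipping"]

    use_ols = False
    params = bse = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = sm.MixedLM(y, xmat, groups=groups)
            mfit = md.fit(reml=True)
            var_block = float(np.asarray(mfit.cov_re)[0, 0])
            var_resid = float(mfit.scale)
            if not np.isfinite(var_block) or var_block <= 1e-8 * max(var_resid, 1e-12):
                use_ols = True
            else:
                params = np.asarray(mfit.params)[: p]
                bse = np.asarray(mfit.bse)[: p]
        except Exception:
            use_ols = True

    if use_ols or params is None or not np.all(np.isfinite(bse)):
        ofit = sm.OLS(y, xmat).fit()
        params = np.asarray(ofit.params)
        bse = np.asarray(ofit.bse)
        ddof = max(n - p, 1)
    else:
        ddof = max(n - p - (n_groups - 1), 1)

    effects = []
    for i, term in enumerate(terms, start=1):
        beta, se = float(params[i]), float(bse[i])
        if se == 0 or not np.isfinite(se):
            pval = 1.0
        elif pvalues == "normal":
            pval = 2 * stats.norm.sf(abs(beta / se))
        else:
            pval = 2 * stats.t.sf(abs(beta / se), df=ddof)
        effects.append(EffectSize(term, beta, se, float(pval)))

    if renormalize:
        norms = renormalize_effects([e.beta for e in effects])
        for e, bn in zip(effects, norms):
            e.beta_norm = bn
    return effects


def renormalize_effects(betas) -> np.ndarray:
    """Rescale a panel of effect sizes into [-1, 1] by the max |beta|.

    Sign-preserving; an all-zero panel maps to all zeros.
    """
    b = np.asarray(list(betas), dtype=float)
    if b.size == 0:
        raise ValueError("empty effect-size panel")
    m = np.max(np.abs(b))
    if m == 0:
        return np.zeros_like(b)
    return b / m


@dataclass
class FitComparison:
    """Linear vs logarithmic fit of functional on taxonomic diversity."""

    r2_linear: float
    r2_log: float
    p_linear: float
    p_log: float
    winner: str

    def as_dict(self) -> dict:
        return {
            "r2_linear": self.r2_linear,
            "r2_log": self.r2_log,
            "p_linear": self.p_linear,
            "p_log": self.p_log,
            "winner": self.winner,
        }


def compare_fits(h_tax, h_fun) -> FitComparison:
    """OLS of functional diversity on taxonomic diversity, linear vs log x.

    A saturating (logarithmic) relation beating the linear one is the
    functional-redundancy signature: function accrues more slowly than
    taxonomic richness once redundant taxa pile up.
    """
    x = np.asarray(h_tax, dtype=float).ravel()
    y = np.asarray(h_fun, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need matched vectors of length >= 4")
    if np.any(x <= 0):
        raise ValueError("taxonomic diversity must be positive for the log fit")
    lin = stats.linregress(x, y)
    log = stats.linregress(np.log(x), y)
    r2l, r2g = float(lin.rvalue**2), float(log.rvalue**2)
    return FitComparison(
        r2_linear=r2l,
        r2_log=r2g,
        p_linear=float(lin.pvalue),
        p_log=float(log.pvalue),
        winner="log" if r2g > r2l else "linear",
    )
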