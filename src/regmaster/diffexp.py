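"""Case-vs-control differential expression with empirical-Bayes moderation.

Per-gene two-group linear model on log2 expression: the fold change is the
case-minus-control mean difference, and the pooled per-gene variance is
shrunk toward a global prior fitted by the method of moments on the
log-variances (scaled inverse-chi-square prior).  The moderated t-statistic
uses the shrunk variance with augmented degrees of freedom ``d0 + d``; as
the prior degrees of freedom ``d0 -> 0`` the ordinary two-sample t is
recovered.  P-values are BH-adjusted across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = ["fit_differential", "select_degs", "fit_variance_prior"]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) for the inverse-chi-square prior.

    Works on z = log(s^2): the excess variance of z over trigamma(df/2)
    identifies d0; the adjusted mean identifies s0^2.  Returns
    (inf, exp(adjusted mean)) when the observed spread is no larger than
    the sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e_mean = float(np.mean(z)) - float(special.digamma(df / 2)) + np.log(df / 2)
    e_var = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var <= 0:
        # no excess spread over sampling noise: infinitely strong prior at
        # the plain average variance
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(
        e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def fit_differential(
    expr: ExpressionMatrix,
    case_label: str = "tumor",
    control_label: str = "normal",
    study_id: str = "",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression table for a labelled matrix.

    Returns a DataFrame indexed by gene with columns ``logFC`` (case minus
    control, log2 units), ``t``, ``p``, ``fdr`` and ``zero_variance``.
    ``prior_df`` overrides the fitted prior degrees of freedom (0 gives the
    ordinary t-test).
    """
    if expr.sample_groups is None:
        raise ValueError("expression matrix has no sample group labels")
    groups = np.asarray(expr.sample_groups)
    case = expr.values[:, groups == case_label]
    ctrl = expr.values[:, groups == control_label]
    n1, n2 = case.shape[1], ctrl.shape[1]
    if min(n1, n2) < 3:
        raise ValueError("both groups need at least 3 samples")

    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid
    zero_var = s2 == 0

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2[~zero_var], df_resid)
    else:
        d0 = prior_df
        s0_sq = fit_variance_prior(s2[~zero_var], df_resid)[1] if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df_resid
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    # augmented df cannot exceed the pooled df of the genes that informed
    # the prior
    df_total = min(df_total, float((~zero_var).sum()) * df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # a gene flat in both groups carries no evidence
    p[zero_var] = 1.0
    t = np.where(zero_var, 0.0, t)

    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p, "fdr": fdr, "zero_variance": zero_var},
        index=pd.Index(expr.gene_ids, name="gene"),
    )
    out.attrs["study_id"] = study_id
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def select_degs(
    table: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 1.0
) -> pd.Series:
    """Differentially expressed genes: fdr < fdr_max AND |logFC| > lfc_min.

    Both inequalities are strict.  Returns a Series mapping gene -> "up" /
    "down" by the sign of logFC.
    """
    mask = (table["fdr"] < fdr_max) & (table["logFC"].abs() > lfc_min)
    sel = table.loc[mask, "logFC"]
    return sel.map(lambda v: "up" if v > 0 else "down").rename("direction")
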