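"""Regulon-activity survival modelling.

Per study, a multivariable Cox proportional-hazards model relates a
regulon's per-sample activity score to time-to-event, adjusted for clinical
covariates; covariates violating proportional hazards (scaled Schoenfeld
test, p < .05) are refit as strata when categorical.  Across studies a
regulon is a survival consensus MR when it is significant in at least half
of the studies with a consistent coefficient sign.  For Kaplan-Meier
display, per-study scores are z-standardized, merged, and discretized at
the merged quartiles (low = lower quartile, mid = IQR, high = upper
quartile); group risk differences use the log-rank test.  Cox fits,
Schoenfeld tests, Kaplan-Meier estimates and log-rank statistics delegate
to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

log = logging.getLogger("regmaster")

__all__ = [
    "CoxResult",
    "fit_cox_regulon",
    "survival_consensus",
    "merge_and_discretize",
    "km_logrank",
    "per_gene_cox",
]

PH_ALPHA = 0.05


@dataclass
class CoxResult:
    """One adjusted Cox fit for a score (regulon activity or gene expression)."""

    study: str
    unit: str  # regulon or gene id
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    covariates: list[str] = field(default_factory=list)
    strata: list[str] = field(default_factory=list)
    ph_pvalues: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    note: str = ""


def _prepare(scores: pd.Series, clinical: pd.DataFrame,
             covariates: list[str]) -> pd.DataFrame:
    df = clinical.set_index("sample_id").loc[scores.index].copy()
    df["score"] = scores.to_numpy(dtype=float)
    return df[["time", "event", "score", *covariates]]


def fit_cox_regulon(
    scores: pd.Series,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
    study: str = "",
    unit: str = "",
) -> CoxResult:
    """Adjusted Cox PH fit of one activity score (Efron tie handling).

    Categorical covariates failing the scaled Schoenfeld PH test at .05 are
    moved into strata and the model is refit.  Non-convergence yields a
    flagged result (``converged=False``) that downstream consensus ignores.
    """
    covariates = list(covariates or [])
    df = _prepare(scores, clinical, covariates)
    if int(df["event"].sum()) < 10:
        raise ValueError("need at least 10 events")
    categorical = [c for c in covariates if not pd.api.types.is_numeric_dtype(df[c])]
    numeric = [c for c in covariates if c not in categorical]

    def _fit(strata: list[str]):
        model_df = df.copy()
        dummies = [c for c in categorical if c not in strata]
        if dummies:
            model_df = pd.get_dummies(model_df, columns=dummies, drop_first=True)
        cph = CoxPHFitter()
        cph.fit(model_df, duration_col="time", event_col="event",
                strata=strata or None)
        return cph

    strata: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = _fit(strata)
            ph = proportional_hazard_test(cph, _fit_df(df, categorical, strata),
                                          time_transform="rank")
            ph_p = ph.summary["p"].groupby(_base_name(ph.summary.index,
                                                      categorical)).min().to_dict()
            bad = [c for c in categorical if ph_p.get(c, 1.0) < PH_ALPHA]
            if bad:
                strata = bad
                log.info("stratifying %s on %s (PH violated)", unit, bad)
                cph = _fit(strata)
    except Exception as exc:  # noqa: BLE001 - non-convergence is data-driven
        return CoxResult(study, unit, np.nan, np.nan, np.nan, np.nan, np.nan,
                         int(df["event"].sum()), covariates, strata, {},
                         converged=False, note=str(exc))

    s = cph.summary.loc["score"]
    ph_pvalues = ph_p
    return CoxResult(
        study=study, unit=unit,
        coef=float(s["coef"]), hr=float(np.exp(s["coef"])),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]), n_events=int(df["event"].sum()),
        covariates=covariates, strata=strata, ph_pvalues=ph_pvalues,
    )


def _fit_df(df: pd.DataFrame, categorical: list[str],
            strata: list[str]) -> pd.DataFrame:
    dummies = [c for c in categorical if c not in strata]
    out = df.copy()
    if dummies:
        out = pd.get_dummies(out, columns=dummies, drop_first=True)
    return out


def _base_name(index: pd.Index, categorical: list[str]) -> list[str]:
    """Map dummy-encoded covariate names back to their source column."""
    names = []
    for name in index:
        base = name
        for c in categorical:
            if str(name).startswith(f"{c}_"):
                base = c
                break
        names.append(base)
    return names


def survival_consensus(
    results: list[CoxResult],
    min_frac: float = 0.5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Cross-study consensus per unit: significance count and HR direction.

    Direction is the sign of the log-hazard coefficient among significant
    studies; disagreement marks the unit ``inconsistent`` and blocks
    consensus regardless of the count.
    """
    rows = []
    df = pd.DataFrame([{
        "unit": r.unit, "study": r.study, "coef": r.coef, "p": r.p,
        "converged": r.converged,
    } for r in results])
    n_studies = df["study"].nunique()
    if n_studies < 2:
        raise ValueError("survival consensus needs at least 2 studies")
    for unit, sub in df.groupby("unit"):
        ok = sub[sub["converged"]]
        sig = ok[ok["p"] < p_max]
        signs = set(np.sign(sig["coef"]).astype(int))
        if len(sig) == 0:
            direction = "none"
        elif signs == {1}:
            direction = "risk"
        elif signs == {-1}:
            direction = "protective"
        else:
            direction = "inconsistent"
        frac = len(sig) / n_studies
        rows.append({
            "unit": unit,
            "n_studies_significant": len(sig),
            "n_studies": n_studies,
            "fraction": frac,
            "hr_direction": direction,
            "consensus": bool(frac >= min_frac
                              and direction in ("risk", "protective")),
        })
    return pd.DataFrame(rows).set_index("unit").sort_index()


def merge_and_discretize(
    scores_per_study: dict[str, pd.Series],
) -> pd.Series:
    """Z-standardize per study, merge, and cut at the merged quartiles.

    Returns a Series over all samples with values low/mid/high: low below
    the merged Q1, high above the merged Q3 (linear-interpolation sample
    quantiles), mid within the IQR inclusive.  Zero-variance studies are
    excluded with a warning.
    """
    if len(scores_per_study) < 2:
        raise ValueError("need at least 2 studies to merge")
    pieces = []
    for study, s in scores_per_study.items():
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"study {study} has zero score variance; excluded",
                          stacklevel=2)
            continue
        pieces.append((s - s.mean()) / sd)
    merged = pd.concat(pieces)
    q1, q3 = np.quantile(merged.to_numpy(), [0.25, 0.75])
    group = pd.Series("mid", index=merged.index, name="group")
    group[merged < q1] = "low"
    group[merged > q3] = "high"
    group.attrs["merged_scores"] = merged
    return group


def km_logrank(
    groups: pd.Series,
    clinical: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curve per group plus k-sample log-rank chi2 and p."""
    df = clinical.set_index("sample_id").loc[groups.index]
    present = [g for g in ("low", "mid", "high") if (groups == g).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty groups")
    curves: dict[str, pd.DataFrame] = {}
    for g in present:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask.to_numpy(), "time"], df.loc[mask.to_numpy(), "event"],
                label=g)
        curves[g] = kmf.survival_function_.rename(columns={g: "survival"})
    res = multivariate_logrank_test(df["time"], groups.to_numpy(), df["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def per_gene_cox(
    expr_per_study: dict[str, "object"],
    clinical_per_study: dict[str, pd.DataFrame],
    genes: list[str],
    covariates: list[str] | None = None,
    min_frac: float = 0.5,
    p_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjusted Cox fit per target gene per study plus the cross-study count.

    Constant-expression genes are excluded with a zero-variance flag.
    Returns (per-fit table, per-gene consensus table) where the consensus
    table counts studies with p < .05 as in ``survival_consensus``.
    """
    results: list[CoxResult] = []
    flags = []
    for study, expr in expr_per_study.items():
        clin = clinical_per_study[study]
        gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
        for gene in genes:
            row = expr.values[gene_index[gene]]
            if np.ptp(row) == 0:
                flags.append({"study": study, "gene": gene,
                              "flag": "zero_variance"})
                continue
            scores = pd.Series(row, index=expr.sample_ids)
            results.append(fit_cox_regulon(scores, clin, covariates,
                                           study=study, unit=gene))
    fits = pd.DataFrame([{
        "study": r.study, "gene": r.unit, "coef": r.coef, "HR": r.hr,
        "p": r.p, "converged": r.converged,
    } for r in results])
    consensus = survival_consensus(results, min_frac=min_frac, p_max=p_max)
    if flags:
        fits.attrs["flags"] = pd.DataFrame(flags)
    return fits, consensus
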