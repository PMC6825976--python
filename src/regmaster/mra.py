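"""Master regulator analysis (MRA) and its cross-study consensus.

A regulon is enriched in a case-control study when its overlap with that
study's differentially expressed genes is hypergeometrically improbable
(one-sided upper tail) after BH adjustment across regulons.  A regulon is a
*common* master regulator of one reference network when its reference-
network size exceeds 50 and it is enriched in at least 80% of the queried
case-control studies; the *consensus* master regulators are the
intersection of the common lists of the two reference networks.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import Regulon

__all__ = [
    "mra_enrichment",
    "mra_study",
    "study_consensus",
    "network_consensus",
]


def mra_enrichment(
    regulon: Regulon, degs: set[str], universe: set[str]
) -> tuple[int, float]:
    """Hypergeometric overrepresentation of DEGs in one regulon.

    The regulon is intersected with the universe before testing; DEGs must
    already be a subset of the universe.  Returns (overlap, upper-tail p of
    seeing at least the observed overlap).
    """
    if not set(degs) <= set(universe):
        raise ValueError("DEGs must be a subset of the universe")
    members = set(regulon.members) & set(universe)
    if not members:
        return 0, 1.0
    overlap = len(members & set(degs))
    M, n, N = len(universe), len(degs), len(members)
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    return overlap, min(p, 1.0)


def mra_study(
    regulons: list[Regulon],
    degs: set[str],
    universe: set[str],
    study_id: str = "",
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Per-study MRA table with BH adjustment across regulons."""
    rows = []
    for reg in regulons:
        overlap, p = mra_enrichment(reg, degs, universe)
        rows.append({
            "study": study_id,
            "regulon": reg.tf_id,
            "regulon_size": reg.size,
            "universe_size": len(universe),
            "deg_count": len(degs),
            "overlap": overlap,
            "p_hyper": p,
        })
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_hyper"], method="fdr_bh")[1]
    out["enriched"] = out["fdr"] < fdr_max
    return out


def study_consensus(
    results: pd.DataFrame,
    min_frac: float = 0.8,
    min_size: int = 51,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Common-MR table for one reference network across case-control studies.

    A regulon is a common MR iff its reference-network size is at least
    ``min_size`` (i.e. strictly above 50 at the default) and it is enriched
    (fdr < fdr_max) in at least ``min_frac`` of the studies.
    """
    n_studies = results["study"].nunique()
    if n_studies < 2:
        raise ValueError("study consensus needs at least 2 studies")
    res = results.copy()
    res["enriched"] = res["fdr"] < fdr_max
    grouped = res.groupby("regulon").agg(
        regulon_size=("regulon_size", "first"),
        n_studies_enriched=("enriched", "sum"),
    )
    grouped["n_studies"] = n_studies
    grouped["fraction"] = grouped["n_studies_enriched"] / n_studies
    grouped["passes_size"] = grouped["regulon_size"] >= min_size
    grouped["common_MR"] = grouped["passes_size"] & (grouped["fraction"] >= min_frac)
    return grouped.sort_index()


def network_consensus(common_a: list[str], common_b: list[str]) -> list[str]:
    """Consensus MRs: alphabetical intersection of two common-MR lists."""
    consensus = sorted(set(common_a) & set(common_b))
    if not consensus:
        warnings.warn("no consensus MRs: common-MR lists are disjoint",
                      stacklevel=2)
    return consensus
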