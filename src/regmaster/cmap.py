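"""Module-oriented connectivity-map drug repositioning.

A query is built by merging the member genes of a chosen group of regulons
and splitting them into up/down tags by the study's log fold changes.  Each
drug in the perturbation reference ranks the gene universe by its
differential statistic; the connectivity score is the classic rank-based
KS composite: ``(KS_up - KS_down) / 2`` when the two one-sided statistics
disagree in sign, otherwise 0.  A negative score means the drug's
signature opposes the query.  Permutation p-values come from random tag
sets of matched sizes, BH-adjusted across drugs; a *reverter* must have
score < 0 with fdr < .05 in every queried study, and the final candidate
list intersects the reverter lists across the query presets and reference
networks.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import _ks_from_hits
from .network import Regulon

log = logging.getLogger("regmaster")

__all__ = [
    "build_query",
    "connectivity_score",
    "score_reference",
    "repositioning_consensus",
]

MIN_TAGS = 10


def build_query(
    regulons: list[Regulon],
    deg_table: pd.DataFrame,
    min_tags: int = MIN_TAGS,
) -> tuple[list[str], list[str]]:
    """Merged up/down tag lists from a group of regulons and one DEG table.

    Member genes are unioned and deduplicated; genes with positive logFC
    become up tags, negative logFC down tags, zero logFC are dropped.
    """
    members = sorted({g for reg in regulons for g in reg.members})
    missing = [g for g in members if g not in deg_table.index]
    if missing:
        raise ValueError(f"{len(missing)} regulon genes absent from DEG table "
                         f"(e.g. {missing[:3]})")
    lfc = deg_table.loc[members, "logFC"]
    up = sorted(lfc.index[lfc > 0])
    down = sorted(lfc.index[lfc < 0])
    for name, tags in (("up", up), ("down", down)):
        if len(tags) < min_tags:
            raise ValueError(f"only {len(tags)} {name} tags (< {min_tags})")
    return up, down


def _ks_signed(pos: np.ndarray, n_genes: int) -> np.ndarray:
    """Unweighted signed KS statistic for batched tag positions.

    Deviations are rationals with denominator m*(n-m); comparing integer
    numerators makes the max/min and the tie-break (ties resolve positive)
    exact.
    """
    pos = np.sort(pos, axis=1)
    m = pos.shape[1]
    n_miss = n_genes - m
    if n_miss == 0:
        return np.ones(pos.shape[0])
    k = np.arange(m)[None, :]
    # numerators of dev_after(k) and dev_before(k) over m*(n-m)
    after = (k + 1) * n_miss - m * (pos - k)
    before = k * n_miss - m * (pos - k)
    maxdev = np.maximum(after.max(axis=1), 0)
    mindev = np.minimum(before.min(axis=1), 0)
    out = np.where(maxdev >= -mindev, maxdev, mindev)
    return out / float(m * n_miss)


def _composite(ks_up: np.ndarray, ks_down: np.ndarray) -> np.ndarray:
    opposite = np.sign(ks_up) != np.sign(ks_down)
    return np.where(opposite, (ks_up - ks_down) / 2.0, 0.0)


def connectivity_score(
    up: list[str], down: list[str], drug_ranking: list[str],
    min_tags: int = MIN_TAGS,
) -> float:
    """Connectivity of one up/down query with one drug's gene ranking.

    +1 means perfect concordance (up tags at the top, down tags at the
    bottom), -1 a perfect reverter; antisymmetric under swapping the tag
    lists.
    """
    index = {g: i for i, g in enumerate(drug_ranking)}
    pos_up = np.array(sorted(index[g] for g in up if g in index))
    pos_down = np.array(sorted(index[g] for g in down if g in index))
    if len(pos_up) < min_tags or len(pos_down) < min_tags:
        raise ValueError("fewer than min_tags tags intersect the drug ranking")
    n = len(drug_ranking)
    ks_up = _ks_signed(pos_up[None, :], n)[0]
    ks_down = _ks_signed(pos_down[None, :], n)[0]
    return float(_composite(np.array([ks_up]), np.array([ks_down]))[0])


def score_reference(
    up: list[str],
    down: list[str],
    reference: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    study: str = "",
    query: str = "",
    min_tags: int = MIN_TAGS,
) -> pd.DataFrame:
    """Connectivity score, permutation p and BH fdr for every drug.

    ``reference`` is drug-by-gene; each drug ranks genes by its statistic,
    descending.  The null rescales random tag sets of the same sizes drawn
    from the reference genes; p is two-sided on |score|.  Drugs whose
    ranking drops a tag below ``MIN_TAGS`` per side are skipped with a flag.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p-values", stacklevel=2)
    genes = list(reference.columns)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    up_idx = np.array(sorted(index[g] for g in up if g in index))
    down_idx = np.array(sorted(index[g] for g in down if g in index))
    if len(up_idx) < min_tags or len(down_idx) < min_tags:
        raise ValueError("query tags barely intersect the reference universe")

    stats = reference.to_numpy(dtype=float)
    # position of each gene in each drug's descending ranking
    order = np.argsort(-stats, axis=1, kind="stable")
    position = np.empty_like(order)
    np.put_along_axis(position, order,
                      np.arange(n)[None, :], axis=1)

    ks_up = _ks_signed(position[:, up_idx], n)
    ks_down = _ks_signed(position[:, down_idx], n)
    scores = _composite(ks_up, ks_down)

    rng = np.random.default_rng(seed)
    mu, md = len(up_idx), len(down_idx)
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :mu + md]
    # null scores are drug-independent: random tags on the identity ranking
    null_up = _ks_signed(np.sort(picks[:, :mu], axis=1), n)
    null_down = _ks_signed(np.sort(picks[:, mu:], axis=1), n)
    null = _composite(null_up, null_down)
    null_abs = np.sort(np.abs(null))
    n_ge = n_perm - np.searchsorted(null_abs, np.abs(scores), side="left")
    p = (1.0 + n_ge) / (1.0 + n_perm)

    out = pd.DataFrame({
        "study": study, "query": query,
        "drug": reference.index,
        "score": scores, "p": p,
    })
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def repositioning_consensus(
    results: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Reverter lists per (network, query) and their final intersection.

    ``results`` concatenates ``score_reference`` outputs with ``study``,
    ``query`` and (optionally) ``network`` columns.  A drug is a reverter
    for one (network, query) when score < 0 and fdr < .05 in ALL of that
    combination's studies; the final list intersects the reverter sets
    across every (network, query) combination.
    """
    df = results.copy()
    if "network" not in df.columns:
        df["network"] = "TN"
    per_combo: list[dict] = []
    reverter_sets: list[set[str]] = []
    for (network, query), sub in df.groupby(["network", "query"]):
        n_studies = sub["study"].nunique()
        ok = sub[(sub["score"] < 0) & (sub["fdr"] < 0.05)]
        counts = ok.groupby("drug")["study"].nunique()
        reverters = set(counts.index[counts == n_studies])
        reverter_sets.append(reverters)
        per_combo.append({
            "network": network, "query": query, "n_studies": n_studies,
            "reverters": sorted(reverters),
            "n_reverters": len(reverters),
        })
    final = sorted(set.intersection(*reverter_sets)) if reverter_sets else []
    return pd.DataFrame(per_combo), final
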