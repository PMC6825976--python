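"""Regulon activity scoring: two-tailed GSEA calls and GSVA sample scores.

Two-tailed GSEA splits a signed regulon into its positive-mode (A) and
negative-mode (B) target subsets, scores each on the study's differential
ranking with the weighted Kolmogorov-Smirnov enrichment statistic, and
tests the differential enrichment dES = ES_A - ES_B against a null of
random membership-preserving relabellings.  dES > 0 with fdr < .05 calls
the regulon *activated* in cases; dES < 0, *repressed*.

GSVA turns expression into per-sample regulon activity without labels:
each gene's expression is mapped through a Gaussian-kernel-smoothed
empirical CDF across samples, genes are ranked per sample by that
statistic, and a weighted KS random walk over the ranking yields the
score (max positive deviation minus max negative deviation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .network import Regulon

log = logging.getLogger("regmaster")

__all__ = [
    "gsea_es",
    "two_tailed_gsea",
    "gsea2_study",
    "gsva_scores",
    "GSEA2Result",
]


# ---------------------------------------------------------------------------
# weighted KS enrichment score


def _ks_from_hits(pos: np.ndarray, hit_w: np.ndarray, n_genes: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Extremes of the KS running sum for batched hit positions.

    ``pos``: (batch, m) 0-indexed hit positions (any order); ``hit_w``:
    matching positive weights.  Hits step up by w/sum(w), misses step down
    by 1/(n_genes - m).  Returns (max positive deviation, min negative
    deviation) per row; both include the start value 0.
    """
    order = np.argsort(pos, axis=1, kind="stable")
    pos = np.take_along_axis(pos, order, axis=1)
    w = np.take_along_axis(hit_w, order, axis=1).astype(float)
    m = pos.shape[1]
    wsum = w.sum(axis=1, keepdims=True)
    if np.any(wsum <= 0):
        raise ValueError("hit weights must sum to a positive value")
    cum = np.cumsum(w, axis=1) / wsum
    n_miss = n_genes - m
    k = np.arange(m)[None, :]
    miss = (pos - k) / n_miss if n_miss > 0 else np.zeros_like(pos, dtype=float)
    dev_after = cum - miss
    dev_before = np.concatenate(
        [np.zeros((pos.shape[0], 1)), cum[:, :-1]], axis=1) - miss
    maxdev = np.maximum(dev_after.max(axis=1), 0.0)
    mindev = np.minimum(dev_before.min(axis=1), 0.0)
    return maxdev, mindev


def gsea_es(
    ranking: list[str] | np.ndarray,
    metric: np.ndarray | None,
    gene_set: set[str] | list[str],
    weight_exp: float = 1.0,
) -> float:
    """Classic weighted-KS enrichment score of a gene set on a ranking.

    ``ranking`` is the gene list ordered best-to-worst; ``metric`` the
    aligned ranking statistic (ignored when ``weight_exp`` is 0).  Hit
    weights are ``|metric|**weight_exp``.  The ES is the running-sum
    deviation of largest magnitude, in [-1, 1]; a tie in magnitude
    resolves to the positive deviation.
    """
    ranking = list(ranking)
    index = {g: i for i, g in enumerate(ranking)}
    pos = np.array(sorted(index[g] for g in gene_set if g in index))
    if len(pos) == 0:
        raise ValueError("gene set does not intersect the ranking")
    if weight_exp == 0 or metric is None:
        w = np.ones(len(pos))
    else:
        metric = np.asarray(metric, dtype=float)
        w = np.abs(metric[pos]) ** weight_exp
        if w.sum() == 0:  # all-zero weights degrade to the unweighted walk
            w = np.ones(len(pos))
    maxdev, mindev = _ks_from_hits(pos[None, :], w[None, :], len(ranking))
    return float(_pick_extreme(maxdev, mindev)[0])


# ---------------------------------------------------------------------------
# two-tailed GSEA


@dataclass
class GSEA2Result:
    regulon: str
    es_a: float | None
    es_b: float | None
    des: float
    p: float
    fdr: float = np.nan
    call: str = "ns"
    one_sided_subset: bool = False


def _pick_extreme(maxdev: np.ndarray, mindev: np.ndarray) -> np.ndarray:
    # ties in magnitude resolve positive; the tolerance absorbs float
    # accumulation error on exactly tied running sums
    return np.where(maxdev >= -mindev - 1e-12, maxdev, mindev)


def _signed_es_batch(pos: np.ndarray, w: np.ndarray, n_genes: int) -> np.ndarray:
    maxdev, mindev = _ks_from_hits(pos, w, n_genes)
    return _pick_extreme(maxdev, mindev)


def two_tailed_gsea(
    regulon: Regulon,
    deg_table: pd.DataFrame,
    n_perm: int = 1000,
    rank_by: str = "logFC",
    weight_exp: float = 1.0,
    seed: int | None = None,
) -> GSEA2Result:
    """Differential enrichment of a signed regulon on one study's ranking.

    Genes are ranked by ``rank_by`` (descending).  The null permutes which
    genes carry the A/B labels, preserving subset sizes; the two-sided
    empirical p compares |dES| to the null.  When one mode subset is absent
    from the ranking, dES falls back to the other subset's ES (flagged).
    """
    metric = deg_table[rank_by]
    order = np.argsort(-metric.to_numpy(), kind="stable")
    ranking = list(metric.index[order])
    weights = np.abs(metric.to_numpy()[order]) ** weight_exp
    index = {g: i for i, g in enumerate(ranking)}
    pos_a = np.array(sorted(index[g] for g in regulon.subset(1) if g in index))
    pos_b = np.array(sorted(index[g] for g in regulon.subset(-1) if g in index))
    if len(pos_a) == 0 and len(pos_b) == 0:
        raise ValueError(f"regulon {regulon.tf_id} absent from the ranking")

    n = len(ranking)

    def _es(pos: np.ndarray) -> float:
        w = weights[pos]
        if w.sum() == 0:
            w = np.ones(len(pos))
        return float(_signed_es_batch(pos[None, :], w[None, :], n)[0])

    es_a = _es(pos_a) if len(pos_a) else None
    es_b = _es(pos_b) if len(pos_b) else None
    one_sided = es_a is None or es_b is None
    des = (es_a or 0.0) - (es_b or 0.0)

    rng = np.random.default_rng(seed)
    ma, mb = len(pos_a), len(pos_b)
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :ma + mb]
    null = np.zeros(n_perm)
    if ma:
        pa = picks[:, :ma]
        wa = weights[pa]
        wa[wa.sum(axis=1) == 0] = 1.0
        null += _signed_es_batch(pa, wa, n)
    if mb:
        pb = picks[:, ma:]
        wb = weights[pb]
        wb[wb.sum(axis=1) == 0] = 1.0
        null -= _signed_es_batch(pb, wb, n)
    p = float((1.0 + np.sum(np.abs(null) >= abs(des))) / (1.0 + n_perm))
    return GSEA2Result(regulon.tf_id, es_a, es_b, des, p,
                       one_sided_subset=one_sided)


def gsea2_study(
    regulons: list[Regulon],
    deg_table: pd.DataFrame,
    n_perm: int = 1000,
    rank_by: str = "logFC",
    weight_exp: float = 1.0,
    fdr_max: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-tailed GSEA for every regulon with BH adjustment and calls."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(len(regulons))
    results = [
        two_tailed_gsea(reg, deg_table, n_perm=n_perm, rank_by=rank_by,
                        weight_exp=weight_exp, seed=child)
        for reg, child in zip(regulons, children)
    ]
    out = pd.DataFrame([{
        "regulon": r.regulon, "ES_A": r.es_a, "ES_B": r.es_b,
        "dES": r.des, "p": r.p,
    } for r in results])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["call"] = "ns"
    out.loc[(out["dES"] > 0) & (out["fdr"] < fdr_max), "call"] = "activated"
    out.loc[(out["dES"] < 0) & (out["fdr"] < fdr_max), "call"] = "repressed"
    return out


# ---------------------------------------------------------------------------
# GSVA


def _kcdf(values: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Gaussian-kernel-smoothed empirical CDF per gene across samples.

    Bandwidth is the per-gene sample SD divided by 4; constant genes map to
    0.5 everywhere.
    """
    n_genes, n_samples = values.shape
    out = np.empty_like(values, dtype=float)
    sd = values.std(axis=1, ddof=1)
    for lo in range(0, n_genes, chunk):
        hi = min(lo + chunk, n_genes)
        block = values[lo:hi]
        h = sd[lo:hi, None, None]
        diff = block[:, :, None] - block[:, None, :]  # (g, eval, ref)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(h > 0, diff / h, 0.0)
        cdf = ndtr(z).mean(axis=2)
        cdf[sd[lo:hi] == 0] = 0.5
        out[lo:hi] = cdf
    return out


def gsva_scores(
    expr: ExpressionMatrix,
    regulons: list[Regulon],
    mode_handling: str = "whole",
    weight_exp: float = 1.0,
) -> pd.DataFrame:
    """Per-sample regulon activity (regulon-by-sample DataFrame).

    Genes are ranked per sample by the kernel-CDF statistic; the hit weight
    of the gene at rank r (1-based) is ``|n_genes/2 - r| ** weight_exp``.
    The score is the max positive minus the max negative deviation of the
    weighted KS walk.  ``mode_handling='signed_diff'`` scores the positive-
    and negative-mode subsets separately and returns their difference.
    Regulons with fewer than 2 genes in the matrix are dropped with a flag.
    """
    if len(expr.sample_ids) < 10:
        raise ValueError("GSVA needs at least 10 samples")
    if mode_handling not in ("whole", "signed_diff"):
        raise ValueError(f"unknown mode_handling {mode_handling!r}")
    stat = _kcdf(expr.values)
    n_genes, n_samples = stat.shape
    # position (0-based rank) of each gene in each sample's descending ordering
    order = np.argsort(-stat, axis=0, kind="stable")
    position = np.empty_like(order)
    np.put_along_axis(position, order, np.arange(n_genes)[:, None], axis=0)
    rank_stat = np.abs(n_genes / 2.0 - (position + 1.0)) ** weight_exp

    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}

    def _walk(rows: np.ndarray) -> np.ndarray:
        """Scores across samples for one member-row subset."""
        pos = position[rows].T  # (samples, m)
        w = rank_stat[rows].T
        zero = w.sum(axis=1) == 0
        if zero.any():
            w = w.copy()
            w[zero] = 1.0
        maxdev, mindev = _ks_from_hits(pos, w, n_genes)
        return maxdev + mindev

    rows_out = {}
    for reg in regulons:
        members = [g for g in reg.members if g in gene_index]
        if len(members) < 2:
            log.warning("GSVA: regulon %s has <2 genes in the matrix; skipped",
                        reg.tf_id)
            continue
        if mode_handling == "whole":
            rows = np.array([gene_index[g] for g in members])
            rows_out[reg.tf_id] = _walk(rows)
        else:
            pos_m = [gene_index[g] for g in members if reg.members[g] > 0]
            neg_m = [gene_index[g] for g in members if reg.members[g] < 0]
            score = np.zeros(n_samples)
            if pos_m:
                score += _walk(np.array(pos_m))
            if neg_m:
                score -= _walk(np.array(neg_m))
            rows_out[reg.tf_id] = score
    out = pd.DataFrame(rows_out, index=expr.sample_ids).T
    out.index.name = "regulon"
    out.attrs["method"] = f"gsva/{mode_handling}"
    return out
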