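"""TF-centric transcriptional network reconstruction.

The reference network is inferred ARACNe-style from a healthy-tissue
cohort: mutual information (MI) between every TF and every other gene, an
empirical permutation null with a Benjamini-Hochberg-adjusted p-value
cutoff, a bootstrap consensus over resampled cohorts, data-processing-
inequality (DPI) pruning of indirect edges, and finally a signed mode of
action per surviving edge from the Pearson correlation on the reference
cohort.

The MI estimator is deterministic: rank-transform each profile, bin the
ranks into equal-frequency bins (``clamp(floor(sqrt(n/5)), 2, 10)`` by
default), take the plug-in MI of the joint histogram and apply the
Miller-Madow small-sample bias correction, clamping at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SignedGeneSet

log = logging.getLogger("regmaster")

__all__ = [
    "Edge",
    "TranscriptionalNetwork",
    "Regulon",
    "mutual_information",
    "infer_edges",
    "apply_dpi",
    "assign_modes",
    "auto_bins",
]


@dataclass(frozen=True)
class Edge:
    tf: str
    target: str
    mi: float
    mode: int = 0  # +1 / -1 once assigned, 0 before
    support: float = 1.0  # bootstrap support fraction

    def __post_init__(self) -> None:
        if self.mi < 0:
            raise ValueError("MI must be non-negative")
        if self.tf == self.target:
            raise ValueError("self-edges are not allowed")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("bootstrap support must lie in [0, 1]")


@dataclass
class TranscriptionalNetwork:
    """Inferred TF->target edges plus provenance."""

    tf_ids: list[str]
    edges: list[Edge]
    cohort_id: str = ""
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.edges}

    def targets_of(self, tf: str) -> dict[str, Edge]:
        return {e.target: e for e in self.edges if e.tf == tf}


@dataclass
class Regulon:
    """A TF with its inferred targets and per-target mode of action."""

    tf_id: str
    members: dict[str, int]  # gene -> +-1

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("regulon must have at least one member")

    @property
    def size(self) -> int:
        return len(self.members)

    def subset(self, mode: int) -> list[str]:
        return [g for g, m in self.members.items() if m == mode]

    def to_gene_set(self) -> SignedGeneSet:
        return SignedGeneSet(self.tf_id, dict(self.members))


# ---------------------------------------------------------------------------
# mutual information


def auto_bins(n: int) -> int:
    # sqrt(n/5) equal-frequency bins; the ceiling caps the cell count so the
    # Miller-Madow correction stays small relative to the plug-in estimate
    return int(np.clip(int(np.sqrt(n / 5)), 2, 16))


def _bin_labels(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin labels of the rank transform (ordinal ranks)."""
    order = np.argsort(x, kind="stable")
    labels = np.empty(len(x), dtype=np.int64)
    labels[order] = np.arange(len(x)) * bins // len(x)
    return labels


def _bin_matrix(values: np.ndarray, bins: int) -> np.ndarray:
    """Row-wise equal-frequency bin labels for a gene-by-sample matrix."""
    n = values.shape[1]
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n)[None, :], axis=1)
    return ranks * bins // n


def _mi_from_joint(joint: np.ndarray, n: int, bins: int) -> np.ndarray:
    """Miller-Madow-corrected MI from batched joint counts.

    ``joint`` has shape (batch, bins, bins) and each slice sums to ``n``.
    """
    joint = joint.astype(float)
    px = joint.sum(axis=2)
    py = joint.sum(axis=1)

    def _ent(counts: np.ndarray) -> np.ndarray:
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        return -terms.sum(axis=-1)

    hx = _ent(px)
    hy = _ent(py)
    hxy = _ent(joint.reshape(joint.shape[0], -1))
    kx = (px > 0).sum(axis=-1)
    ky = (py > 0).sum(axis=-1)
    kxy = (joint > 0).sum(axis=(1, 2))
    # Miller-Madow: H_mm = H + (K-1)/(2n) per entropy term
    mi = (hx + hy - hxy) + ((kx - 1) + (ky - 1) - (kxy - 1)) / (2.0 * n)
    return np.maximum(mi, 0.0)


def mutual_information(x: np.ndarray, y: np.ndarray,
                       bins: int | None = None) -> float:
    """MI in nats between two sample vectors (binned-rank estimator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.debug("constant vector: MI undefined, returning 0")
        return 0.0
    b = bins if bins is not None else auto_bins(n)
    bx = _bin_labels(x, b)
    by = _bin_labels(y, b)
    joint = np.bincount(bx * b + by, minlength=b * b).reshape(1, b, b)
    return float(_mi_from_joint(joint, n, b)[0])


def _pair_mi(tf_bins: np.ndarray, gene_bins: np.ndarray, bins: int,
             chunk: int = 20000) -> np.ndarray:
    """MI for row-aligned pairs: tf_bins[i] vs gene_bins[i]."""
    n = tf_bins.shape[1]
    m = tf_bins.shape[0]
    out = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        code = tf_bins[lo:hi] * bins + gene_bins[lo:hi]
        rows = hi - lo
        flat = (np.arange(rows)[:, None] * (bins * bins) + code).ravel()
        joint = np.bincount(flat, minlength=rows * bins * bins)
        joint = joint.reshape(rows, bins, bins)
        out[lo:hi] = _mi_from_joint(joint, n, bins)
    return out


def _mi_tf_by_gene(tf_bins: np.ndarray, gene_bins: np.ndarray,
                   bins: int) -> np.ndarray:
    """Full TF-by-gene MI matrix from bin-label matrices."""
    n = tf_bins.shape[1]
    n_genes = gene_bins.shape[0]
    out = np.empty((tf_bins.shape[0], n_genes))
    for i in range(tf_bins.shape[0]):
        code = tf_bins[i][None, :] * bins + gene_bins
        flat = (np.arange(n_genes)[:, None] * (bins * bins) + code).ravel()
        joint = np.bincount(flat, minlength=n_genes * bins * bins)
        joint = joint.reshape(n_genes, bins, bins)
        out[i] = _mi_from_joint(joint, n, bins)
    return out


# ---------------------------------------------------------------------------
# permutation / bootstrap consensus


def infer_edges(
    expr: ExpressionMatrix,
    tfs: list[str],
    n_perm: int = 1000,
    p_cut: float = 0.001,
    n_boot: int = 100,
    support_min: float = 0.95,
    seed: int | None = None,
    null_pairs_per_perm: int = 200,
    bins: int | None = None,
) -> TranscriptionalNetwork:
    """Pre-DPI consensus network: permutation threshold + bootstrap support.

    The permutation null pools MI values between each sampled TF profile and
    an independently permuted gene profile (``null_pairs_per_perm`` pairs
    per permutation); pair p-values against the pooled null are BH-adjusted
    across all TF-gene pairs and thresholded at ``p_cut``.  Surviving pairs
    are rescored on ``n_boot`` bootstrap resamples of the cohort; support is
    the fraction of resamples whose MI clears the permutation MI threshold.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 (the null is undefined otherwise)")
    missing = [t for t in tfs if t not in expr.gene_ids]
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {missing}")
    if len(expr.sample_ids) < 20:
        raise ValueError("need at least 20 samples for network inference")

    # canonical sample order: inference is invariant to input column order
    col_order = np.argsort(np.asarray(expr.sample_ids, dtype=object), kind="stable")
    values = expr.values[:, col_order]
    n = values.shape[1]
    b = bins if bins is not None else auto_bins(n)
    rng = np.random.default_rng(seed)

    genes = expr.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    tf_rows = np.array([gene_index[t] for t in tfs])
    all_bins = _bin_matrix(values, b)
    tf_bins = all_bins[tf_rows]

    # observed MI for every TF x gene pair (self excluded later)
    mi_obs = _mi_tf_by_gene(tf_bins, all_bins, b)

    # pooled permutation null: sorted labels destroy the joint structure but
    # keep the marginals; sorting makes the null invariant to sample order
    sorted_bins = np.sort(all_bins, axis=1)
    sorted_tf_bins = np.sort(tf_bins, axis=1)
    null_vals = np.empty(n_perm * null_pairs_per_perm)
    for p in range(n_perm):
        tf_pick = rng.integers(0, len(tfs), null_pairs_per_perm)
        gene_pick = rng.integers(0, len(genes), null_pairs_per_perm)
        permuted = rng.permuted(
            np.broadcast_to(np.arange(n), (null_pairs_per_perm, n)), axis=1)
        g_shuf = np.take_along_axis(sorted_bins[gene_pick], permuted, axis=1)
        null_vals[p * null_pairs_per_perm:(p + 1) * null_pairs_per_perm] = (
            _pair_mi(sorted_tf_bins[tf_pick], g_shuf, b))
    null_sorted = np.sort(null_vals)
    n_null = len(null_sorted)

    # empirical p per pair against the pooled null
    pair_tf, pair_gene = [], []
    for i, trow in enumerate(tf_rows):
        for j in range(len(genes)):
            if j == trow:
                continue
            pair_tf.append(i)
            pair_gene.append(j)
    pair_tf = np.array(pair_tf)
    pair_gene = np.array(pair_gene)
    obs = mi_obs[pair_tf, pair_gene]
    n_ge = n_null - np.searchsorted(null_sorted, obs, side="left")
    pvals = (1.0 + n_ge) / (1.0 + n_null)
    # keep pairs whose BH-adjusted p is strictly below the cutoff
    padj = multipletests(pvals, method="fdr_bh")[1]
    keep = padj < p_cut

    if not keep.any():
        warnings.warn("no edges survive the permutation threshold", stacklevel=2)
        return TranscriptionalNetwork(list(tfs), [], params=_params_dict(
            n_perm, p_cut, n_boot, support_min, b), seed=seed)

    # MI threshold equivalent to the largest raw p that passed BH
    raw_cut = float(pvals[keep].max())
    k_allowed = int(np.floor(raw_cut * (1 + n_null))) - 1  # max #null >= thr
    k_allowed = max(k_allowed, 0)
    mi_thr = null_sorted[n_null - 1 - k_allowed] if k_allowed < n_null else 0.0

    kept_tf = pair_tf[keep]
    kept_gene = pair_gene[keep]
    kept_obs = obs[keep]

    # bootstrap support for surviving pairs
    support = np.zeros(len(kept_tf))
    needed_rows = np.unique(np.concatenate([tf_rows[kept_tf], kept_gene]))
    row_pos = {r: i for i, r in enumerate(needed_rows)}
    sub_values = values[needed_rows]
    bt_tf = np.array([row_pos[r] for r in tf_rows[kept_tf]])
    bt_gene = np.array([row_pos[r] for r in kept_gene])
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot_bins = _bin_matrix(sub_values[:, idx], b)
        mi_b = _pair_mi(boot_bins[bt_tf], boot_bins[bt_gene], b)
        support += mi_b >= mi_thr
    support /= n_boot

    final = support >= support_min
    edges = [
        Edge(tf=tfs[kept_tf[i]], target=genes[kept_gene[i]],
             mi=float(kept_obs[i]), support=float(support[i]))
        for i in np.nonzero(final)[0]
    ]
    log.info("infer_edges: %d/%d pairs pass permutation, %d pass bootstrap",
             int(keep.sum()), len(obs), len(edges))
    return TranscriptionalNetwork(
        list(tfs), edges, cohort_id="", seed=seed,
        params=_params_dict(n_perm, p_cut, n_boot, support_min, b),
    )


def _params_dict(n_perm, p_cut, n_boot, support_min, bins) -> dict:
    return {"n_perm": n_perm, "p_cut": p_cut, "n_boot": n_boot,
            "support_min": support_min, "bins": bins}


# ---------------------------------------------------------------------------
# DPI


def apply_dpi(net: TranscriptionalNetwork,
              tolerance: float = 0.0) -> TranscriptionalNetwork:
    """Remove the weakest edge of every TF1-TF2-target triangle.

    Only triangles whose two regulators are TFs are considered (the network
    is TF-centric).  All comparisons use the original MI values in a single
    order-independent pass; with tolerance 0 the strict minimum is removed,
    a tolerance of 1 removes nothing.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    mi = {(e.tf, e.target): e.mi for e in net.edges}
    targets = {tf: net.targets_of(tf) for tf in net.tf_ids}
    tf_set = set(net.tf_ids)
    to_remove: set[tuple[str, str]] = set()
    for tf1 in net.tf_ids:
        for tf2 in targets[tf1]:
            if tf2 not in tf_set or tf2 == tf1:
                continue
            shared = targets[tf1].keys() & targets.get(tf2, {}).keys()
            for g in shared:
                tri = [((tf1, tf2), mi[(tf1, tf2)]),
                       ((tf1, g), mi[(tf1, g)]),
                       ((tf2, g), mi[(tf2, g)])]
                tri.sort(key=lambda kv: kv[1])
                if tri[0][1] < (1.0 - tolerance) * tri[1][1]:
                    to_remove.add(tri[0][0])
    edges = [e for e in net.edges if (e.tf, e.target) not in to_remove]
    log.info("DPI removed %d of %d edges", len(net.edges) - len(edges),
             len(net.edges))
    return TranscriptionalNetwork(net.tf_ids, edges, net.cohort_id,
                                  dict(net.params, dpi_tolerance=tolerance),
                                  net.seed)


# ---------------------------------------------------------------------------
# modes of action


def assign_modes(net: TranscriptionalNetwork,
                 expr: ExpressionMatrix) -> list[Regulon]:
    """Sign each edge by the TF-target Pearson correlation; build regulons.

    A correlation of exactly zero defaults to +1 (flagged in the log).  TFs
    with no surviving targets yield no regulon.
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    X = expr.values
    regulons: list[Regulon] = []
    for tf in net.tf_ids:
        edges = net.targets_of(tf)
        if not edges:
            continue
        xi = X[gene_index[tf]]
        members: dict[str, int] = {}
        for target in edges:
            yj = X[gene_index[target]]
            r = _pearson(xi, yj)
            if r == 0.0:
                log.debug("zero correlation %s-%s: mode defaults to +1", tf, target)
                members[target] = 1
            else:
                members[target] = 1 if r > 0 else -1
        regulons.append(Regulon(tf, members))
    return regulons


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float(xc @ yc / denom)
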