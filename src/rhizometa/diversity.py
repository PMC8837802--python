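"""Rarefaction, alpha diversity, Bray-Curtis ordination and PERMANOVA.

Conventions: Shannon H is in natural log units so that Pielou J = H / ln(S)
is exact; Faith PD includes the path from the observed tips to the root by
default (switchable); rarefaction is a single seed-controlled draw without
replacement, and samples below the target depth are dropped, not resampled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

logger = logging.getLogger("rhizometa")


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(counts: pd.DataFrame, depth: int, seed: int | np.random.Generator = 0
           ) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (and logged); a sample
    at exactly ``depth`` passes through unchanged.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = counts.index[~keep].tolist()
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, ", ".join(dropped))
    rows = []
    for sid in counts.index[keep]:
        row = counts.loc[sid].to_numpy(dtype=np.int64)
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = pd.DataFrame(np.array(rows, dtype=np.int64), index=counts.index[keep],
                       columns=counts.columns)
    return out


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(row: np.ndarray) -> float:
    """Shannon entropy in nats of one sample's counts."""
    total = row.sum()
    if total == 0:
        return 0.0
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


class _TreeIndex:
    """Per-tip root paths for fast Faith PD over many samples of one tree."""

    def __init__(self, tree: TreeNode, taxa: list[str]):
        tips = {t.name: t for t in tree.tips()}
        missing = [t for t in taxa if t not in tips]
        if missing:
            raise ValueError(f"taxa absent from tree: {missing[:10]}"
                             + (" ..." if len(missing) > 10 else ""))
        node_id: dict[int, int] = {}
        lengths: list[float] = []
        for i, node in enumerate(tree.traverse(include_self=True)):
            node_id[id(node)] = i
            lengths.append(node.length or 0.0)
        self.lengths = np.asarray(lengths)
        self.paths = []
        self.root_id = node_id[id(tree)]
        for t in taxa:
            path = []
            node = tips[t]
            while node is not tree:
                path.append(node_id[id(node)])
                node = node.parent
            self.paths.append(np.asarray(path, dtype=np.intp))
        self.n_nodes = len(lengths)

    def pd(self, present: np.ndarray, include_root: bool = True) -> float:
        observed = np.flatnonzero(present)
        if observed.size == 0:
            return 0.0
        hits = np.zeros(self.n_nodes, dtype=np.int64)
        for i in observed:
            hits[self.paths[i]] += 1
        edges = hits > 0
        if not include_root:
            # edges ancestral to every observed tip lie on the root chain
            edges &= hits < observed.size
        return float(self.lengths[edges].sum())


def faith_pd(counts: pd.DataFrame, tree: TreeNode, include_root: bool = True
             ) -> pd.Series:
    """Faith's phylogenetic diversity per sample (branch-length units)."""
    index = _TreeIndex(tree, list(counts.columns))
    values = [index.pd(counts.loc[s].to_numpy() > 0, include_root)
              for s in counts.index]
    return pd.Series(values, index=counts.index, name="faith_pd")


def alpha_diversity(counts: pd.DataFrame, tree: TreeNode | None = None,
                    include_root: bool = True) -> pd.DataFrame:
    """Observed richness, Shannon H (nats), Pielou J, and Faith PD per sample.

    J is undefined (NaN) when richness <= 1. Faith PD is included only when a
    tree is supplied; every taxon with a nonzero count must be a tip of it.
    """
    mat = counts.to_numpy()
    richness = (mat > 0).sum(axis=1)
    h = np.array([shannon(row) for row in mat])
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(richness > 1, h / np.log(np.maximum(richness, 2)), np.nan)
    out = pd.DataFrame({
        "richness": richness.astype(float),
        "shannon": h,
        "pielou": j,
    }, index=counts.index)
    if tree is not None:
        observed = counts.loc[:, (mat > 0).any(axis=0)]
        out["faith_pd"] = faith_pd(observed, tree, include_root)
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities on counts: sum|a-b| / sum(a+b)."""
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = counts.index[totals == 0].tolist()
        raise ValueError(f"all-zero samples have undefined dissimilarity: {bad}")
    d = squareform(pdist(counts.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


def pcoa(distance: pd.DataFrame, k: int = 2) -> dict:
    """Classical scaling (principal coordinates) of a distance matrix.

    Negative eigenvalues of the double-centred matrix are reported as is,
    never silently corrected; the requested ``k`` is truncated (with a
    warning) when it exceeds the number of positive eigenvalues.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    d2 = distance.to_numpy() ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int((eigvals > 1e-10).sum())
    if k > n_pos:
        logger.warning("pcoa: requested %d axes but only %d positive eigenvalues", k, n_pos)
        k = max(n_pos, 1)
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    total = eigvals[eigvals > 0].sum()
    return {
        "coordinates": pd.DataFrame(coords, index=distance.index,
                                    columns=[f"PC{i + 1}" for i in range(k)]),
        "eigenvalues": eigvals,
        "proportion_explained": np.maximum(eigvals, 0.0) / total if total > 0 else eigvals * 0,
    }


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_stats(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray
                     ) -> tuple[float, float, float]:
    """(pseudo-F, SS_total, SS_within) for one labelling."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(uniq)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_total, ss_within


def permanova(distance: pd.DataFrame, groups, n_perm: int = 999,
              seed: int | np.random.Generator = 0, strata=None) -> dict:
    """Permutational MANOVA (Anderson's pseudo-F) on a distance matrix.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``. When ``strata`` is given
    (e.g. study ids in a multi-study design) labels are permuted only within
    each stratum.
    """
    labels = np.asarray(pd.Series(groups, index=distance.index)
                        if not isinstance(groups, pd.Series) else groups.loc[distance.index])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {bad}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d2 = distance.to_numpy() ** 2
    f_obs, ss_total, ss_within = _permanova_stats(d2, labels, uniq)
    r2 = 1.0 - ss_within / ss_total

    if strata is not None:
        strata_arr = np.asarray(pd.Series(strata, index=distance.index)
                                if not isinstance(strata, pd.Series)
                                else strata.loc[distance.index])
        strata_groups = [np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)]
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(labels)
        else:
            perm = labels.copy()
            for idx in strata_groups:
                perm[idx] = labels[idx][rng.permutation(len(idx))]
        if _permanova_stats(d2, perm, uniq)[0] >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return {"pseudo_f": f_obs, "r2": r2, "p_value": p, "n_permutations": n_perm}
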