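"""Compositional differential abundance between rhizosphere and bulk groups.

Zeros are resolved by a Dirichlet(counts + 0.5) Monte-Carlo layer; each
instance is CLR-transformed; per-taxon Wilcoxon rank-sum p-values are averaged
over instances, then corrected across taxa with Benjamini-Hochberg. The
standardized effect size is the median over instances of a random
between-group CLR difference scaled by the larger of the two within-group
dispersions, so it is scale-free and antisymmetric under group swap.
A Welch t-test is available in place of Wilcoxon by flag.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)


def clr_transform(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centered log-ratio: ln(x_i) minus the mean of ln(x) along ``axis``."""
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("CLR requires strictly positive entries; resolve zeros "
                         "upstream (e.g. via the Dirichlet prior)")
    logx = np.log(x)
    return logx - logx.mean(axis=axis, keepdims=True)


def dirichlet_instances(counts: pd.DataFrame, n_mc: int = 128,
                        seed: int | np.random.Generator = 0,
                        prior: float = 0.5) -> np.ndarray:
    """CLR-transformed Dirichlet(counts + prior) draws.

    Returns an array of shape ``(n_mc, n_samples, n_taxa)`` in natural-log
    units; each sample's CLR vector sums to zero.
    """
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    alpha = counts.to_numpy(dtype=float) + prior
    n_samples, n_taxa = alpha.shape
    out = np.empty((n_mc, n_samples, n_taxa))
    for s in range(n_samples):
        draws = rng.dirichlet(alpha[s], size=n_mc)
        out[:, s, :] = clr_transform(draws, axis=-1)
    return out


def _group_rng(sample_ids, seed: int) -> np.random.Generator:
    """Deterministic per-group stream keyed on the group's own sample ids,
    so pair draws do not depend on which group is called treatment."""
    key = zlib.crc32("\t".join(sorted(map(str, sample_ids))).encode())
    return np.random.default_rng((int(seed) * 2654435761 + key) % (2 ** 31))


def test_differential(instances: np.ndarray, labels, sample_ids=None,
                      treatment: str = "rhizosphere", control: str = "bulk",
                      fdr_threshold: float = 0.05, test: str = "wilcoxon",
                      seed: int = 0, taxa=None) -> pd.DataFrame:
    """Per-taxon differential abundance between two groups of CLR instances.

    ``instances`` has shape (n_mc, n_samples, n_taxa); ``labels`` assigns each
    sample to ``treatment`` or ``control``. Returns a DataFrame with the median
    CLR difference (log2 units), standardized effect size, mean Wilcoxon p, BH
    q, and the enrichment call at ``q < fdr_threshold``.
    """
    labels = np.asarray(labels)
    n_mc, n_samples, n_taxa = instances.shape
    if labels.shape[0] != n_samples:
        raise ValueError("labels length does not match instances")
    idx_t = np.flatnonzero(labels == treatment)
    idx_c = np.flatnonzero(labels == control)
    if len(idx_t) < 2 or len(idx_c) < 2:
        raise ValueError("each group needs at least 2 samples")
    if sample_ids is None:
        sample_ids = np.arange(n_samples)
    sample_ids = np.asarray(sample_ids)

    block_t = instances[:, idx_t, :]     # (n_mc, n_t, taxa)
    block_c = instances[:, idx_c, :]

    if test == "wilcoxon":
        res = stats.mannwhitneyu(block_t, block_c, axis=1, alternative="two-sided")
        p_inst = res.pvalue                     # (n_mc, taxa)
    elif test == "t":
        res = stats.ttest_ind(block_t, block_c, axis=1, equal_var=False)
        p_inst = res.pvalue
    else:
        raise ValueError(f"unknown test {test!r}; use 'wilcoxon' or 't'")
    p_mean = p_inst.mean(axis=0)

    # random-pair effect size: draws keyed per group, independent of role
    rng_t = _group_rng(sample_ids[idx_t], seed)
    rng_c = _group_rng(sample_ids[idx_c], seed)
    pick_t = rng_t.integers(0, len(idx_t), size=n_mc)
    pair_t = np.array([rng_t.choice(len(idx_t), size=2, replace=False)
                       for _ in range(n_mc)])
    pick_c = rng_c.integers(0, len(idx_c), size=n_mc)
    pair_c = np.array([rng_c.choice(len(idx_c), size=2, replace=False)
                       for _ in range(n_mc)])
    inst = np.arange(n_mc)
    btw = block_t[inst, pick_t, :] - block_c[inst, pick_c, :]        # (n_mc, taxa)
    win_t = np.abs(block_t[inst, pair_t[:, 0], :] - block_t[inst, pair_t[:, 1], :])
    win_c = np.abs(block_c[inst, pair_c[:, 0], :] - block_c[inst, pair_c[:, 1], :])
    dispersion = np.maximum(np.maximum(win_t, win_c), 1e-12)
    effect = np.median(btw / dispersion, axis=0)
    median_diff = np.median(btw, axis=0) / LN2                       # log2 units

    reject, q, _, _ = multipletests(p_mean, alpha=fdr_threshold, method="fdr_bh")
    label = np.where(~reject, "none",
                     np.where(median_diff > 0, treatment, control))
    index = pd.Index(taxa if taxa is not None else range(n_taxa), name="taxon_id")
    return pd.DataFrame({
        "median_diff_log2": median_diff,
        "effect": effect,
        "p": p_mean,
        "q": q,
        "enriched_in": label,
    }, index=index)


def aggregate_to_rank(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                      rank: str) -> pd.DataFrame:
    """Sum counts over taxa sharing a taxonomy label at ``rank``.

    Taxa missing from the taxonomy, or with an empty label, are pooled into
    an ``Unassigned`` column; column sums are conserved.
    """
    from .io import RANKS
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
    labels = taxonomy[rank].reindex(counts.columns)
    labels = labels.where(labels.notna() & (labels != ""), "Unassigned")
    out = counts.T.groupby(labels.values).sum().T
    out.columns.name = rank
    return out
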