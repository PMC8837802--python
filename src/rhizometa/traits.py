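"""Community-weighted traits and rule-based function abundances.

The per-taxon trait table (rRNA operon copies, toxin-antitoxin and sporulation
gene counts, NSTI) is consumed in the shape that gene-content prediction
tools emit; this module implements the community-level aggregation on top of
it: an NSTI quality filter, the community-weighted mean (CWM) rRNA operon
copy number as a copiotrophy proxy, per-read-weighted dormancy gene
abundances, and taxonomy-rule function abundances.

Copy-number correction (dividing read counts by per-taxon operon copies
before normalising) defaults ON for dormancy and function abundances and OFF
for the operon CWM itself, which would otherwise be partially
self-referential; both are switchable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("rhizometa")

DORMANCY_SYSTEMS = {
    "toxin_antitoxin": "toxin_antitoxin_genes",
    "sporulation": "sporulation_genes",
}


def nsti_filter(counts: pd.DataFrame, traits: pd.DataFrame,
                cutoff: float = 2.0) -> pd.DataFrame:
    """Remove taxa with NSTI strictly above ``cutoff`` (2.0 retained).

    Taxa absent from the trait table are also excluded, with a warning; the
    removed fraction is logged.
    """
    if cutoff < 0:
        raise ValueError(f"NSTI cutoff must be non-negative, got {cutoff}")
    known = counts.columns.intersection(traits.index)
    missing = counts.columns.difference(traits.index)
    if len(missing):
        logger.warning("nsti_filter: %d taxa missing from traits excluded: %s",
                       len(missing), ", ".join(missing[:10]))
    keep = known[traits.loc[known, "nsti"] <= cutoff]
    removed = counts.shape[1] - len(keep)
    if removed:
        logger.info("nsti_filter: removed %d/%d taxa (NSTI > %.2f or missing)",
                    removed, counts.shape[1], cutoff)
    return counts.loc[:, keep]


def _relative_abundance(counts: pd.DataFrame, traits: pd.DataFrame | None,
                        correct_copy_number: bool) -> pd.DataFrame:
    mat = counts.astype(float)
    if correct_copy_number:
        if traits is None:
            raise ValueError("copy-number correction requires a trait table")
        copies = traits["operon_copies"].reindex(counts.columns)
        if copies.isna().any():
            missing = counts.columns[copies.isna()].tolist()
            raise ValueError(f"taxa missing operon copies for correction: {missing[:10]}")
        mat = mat.div(copies, axis=1)
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        empty = counts.index[totals == 0].tolist()
        raise ValueError(f"samples with no retained reads: {empty}")
    return mat.div(totals, axis=0)


def weighted_mean_operon(counts: pd.DataFrame, traits: pd.DataFrame,
                         correct_copy_number: bool = False) -> pd.Series:
    """Community-weighted mean rRNA operon copy number per sample."""
    shared = counts.columns.intersection(traits.index)
    if len(shared) == 0:
        raise ValueError("no taxa shared between counts and traits")
    rel = _relative_abundance(counts[shared], traits, correct_copy_number)
    values = rel @ traits.loc[shared, "operon_copies"]
    return values.rename("operon_cwm")


def dormancy_abundance(counts: pd.DataFrame, traits: pd.DataFrame,
                       system: str, correct_copy_number: bool = True) -> pd.Series:
    """Read-weighted mean per-genome gene count of a dormancy system per sample."""
    if system not in DORMANCY_SYSTEMS:
        raise ValueError(f"unknown dormancy system {system!r}; "
                         f"valid: {sorted(DORMANCY_SYSTEMS)}")
    column = DORMANCY_SYSTEMS[system]
    shared = counts.columns.intersection(traits.index)
    if len(shared) == 0:
        raise ValueError("no taxa shared between counts and traits")
    rel = _relative_abundance(counts[shared], traits, correct_copy_number)
    values = rel @ traits.loc[shared, column]
    return values.rename(system)


def match_function_rules(taxonomy: pd.DataFrame, rules: dict) -> pd.Series:
    """Boolean mask over the taxonomy index: inclusion hit and no exclusion hit."""
    include = pd.Series(False, index=taxonomy.index)
    for rank, value in rules["include"]:
        include |= taxonomy[rank] == value
    for rank, value in rules.get("exclude", []):
        include &= taxonomy[rank] != value
    return include


def function_abundance(counts: pd.DataFrame, taxonomy: pd.DataFrame, fmap: dict,
                       traits: pd.DataFrame | None = None,
                       correct_copy_number: bool = True) -> pd.DataFrame:
    """Per-sample relative abundance of every function in the map.

    A taxon matches a function when any inclusion rule matches its lineage and
    no exclusion rule does; taxa may match several functions. Copy-number
    correction is applied when a trait table is supplied.
    """
    missing_tax = counts.columns.difference(taxonomy.index)
    if len(missing_tax):
        raise ValueError(f"taxa missing from taxonomy: {missing_tax[:10].tolist()}")
    if not fmap:
        return pd.DataFrame(index=counts.index)
    rel = _relative_abundance(counts, traits,
                              correct_copy_number and traits is not None)
    out = {}
    tax = taxonomy.reindex(counts.columns)
    for name, rules in fmap.items():
        mask = match_function_rules(tax, rules)
        out[name] = rel.loc[:, mask.to_numpy()].sum(axis=1)
    return pd.DataFrame(out, index=counts.index)


def community_trait_table(counts: pd.DataFrame, traits: pd.DataFrame,
                          taxonomy: pd.DataFrame | None = None,
                          fmap: dict | None = None,
                          nsti_cutoff: float = 2.0) -> pd.DataFrame:
    """One-stop per-sample table: operon CWM, dormancy abundances, functions."""
    filtered = nsti_filter(counts, traits, nsti_cutoff)
    out = pd.DataFrame({
        "operon_cwm": weighted_mean_operon(filtered, traits),
        "toxin_antitoxin": dormancy_abundance(filtered, traits, "toxin_antitoxin"),
        "sporulation": dormancy_abundance(filtered, traits, "sporulation"),
    })
    if fmap and taxonomy is not None:
        fn = function_abundance(filtered, taxonomy, fmap, traits=traits)
        fn.columns = [f"fn_{c}" for c in fn.columns]
        out = out.join(fn)
    return out
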