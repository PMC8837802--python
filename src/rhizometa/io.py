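"""Readers, writers and validation for the tabular and tree formats shared by all stages.

All tables are tab-separated UTF-8 text with ``#`` comment lines. Counts are kept as
strict integers; relative abundances are always derived on the fly, never stored.
The phylogeny is newick with branch lengths, handled through scikit-bio's
:class:`~skbio.TreeNode`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("rhizometa")

COMPARTMENTS = ("rhizosphere", "bulk")
RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")
#: ranks that must be present in a taxonomy table (Species is optional)
REQUIRED_RANKS = RANKS[:6]

TRAIT_COLUMNS = ("operon_copies", "toxin_antitoxin_genes", "sporulation_genes", "nsti")


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# count table
# ---------------------------------------------------------------------------

def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dup}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxon ids: {dup}")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError(
            f"count table needs at least 2 samples and 2 taxa, got {counts.shape}"
        )
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count table contains non-numeric cells")
    if np.isnan(values.astype(float)).any():
        rows = counts.index[np.isnan(values.astype(float)).any(axis=1)].tolist()
        raise ValidationError(f"missing values in count rows: {rows}")
    if (values < 0).any():
        rows = counts.index[(values < 0).any(axis=1)].tolist()
        raise ValidationError(f"negative counts in rows: {rows}")
    if not np.allclose(values, np.round(values)):
        rows = counts.index[(~np.isclose(values, np.round(values))).any(axis=1)].tolist()
        raise ValidationError(f"non-integer counts in rows: {rows}")
    return counts.astype(np.int64)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x taxa integer count table (TSV, first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_count_table(df)


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"study_id", "compartment"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing required columns: {sorted(missing)}")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dup}")
    bad = ~meta["compartment"].isin(COMPARTMENTS)
    if bad.any():
        offending = meta.loc[bad, "compartment"].to_dict()
        raise ValidationError(
            f"compartment must be one of {COMPARTMENTS}; offending rows: {offending}"
        )
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, study_id, compartment, covariates)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def validate_taxonomy(tax: pd.DataFrame) -> pd.DataFrame:
    if tax.index.has_duplicates:
        dup = tax.index[tax.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxon ids in taxonomy: {dup}")
    missing = [r for r in REQUIRED_RANKS if r not in tax.columns]
    if missing:
        raise ValidationError(f"taxonomy missing rank columns: {missing}")
    order = [r for r in RANKS if r in tax.columns]
    return tax[order].fillna("")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxon_id -> 7-rank lineage table; unassigned ranks are empty strings."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    return validate_taxonomy(df)


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen, dup = set(), set()
        for t in tips:
            (dup if t in seen else seen).add(t)
        raise ValidationError(f"duplicate tip labels in tree: {sorted(dup)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} above node {node.name!r}"
            )
    return tree


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree whose tips are taxon ids."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValidationError(f"malformed newick in {path}: {exc}") from exc
    return validate_tree(tree)


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRAIT_COLUMNS) - set(traits.columns)
    if missing:
        raise ValidationError(f"trait table missing columns: {sorted(missing)}")
    if traits.index.has_duplicates:
        dup = traits.index[traits.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxon ids in traits: {dup}")
    if (traits["operon_copies"] < 1).any():
        rows = traits.index[traits["operon_copies"] < 1].tolist()
        raise ValidationError(f"operon_copies must be >= 1; offending taxa: {rows}")
    for col in ("toxin_antitoxin_genes", "sporulation_genes", "nsti"):
        if (traits[col] < 0).any():
            rows = traits.index[traits[col] < 0].tolist()
            raise ValidationError(f"{col} must be >= 0; offending taxa: {rows}")
    return traits


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read the per-taxon trait table (operon copies, dormancy gene counts, NSTI)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return validate_traits(df)


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# function map
# ---------------------------------------------------------------------------

def read_function_map(path: str | Path) -> dict:
    """Parse the taxonomy-rule function map.

    Dialect: functions are blank-line separated stanzas. The first line of a
    stanza is the function name; each following line is ``Rank:value`` (an
    inclusion rule) or ``-Rank:value`` (an exclusion rule). ``#`` starts a
    comment. A taxon matches a function when any inclusion rule matches its
    lineage and no exclusion rule does.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_function_map(text)


def parse_function_map(text: str) -> dict:
    fmap: dict[str, dict[str, list[tuple[str, str]]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            current = None
            continue
        if current is None:
            if ":" in line:
                raise ValidationError(
                    f"function map line {lineno}: expected a function name, got rule {line!r}"
                )
            if line in fmap:
                raise ValidationError(f"duplicate function name {line!r} (line {lineno})")
            current = line
            fmap[current] = {"include": [], "exclude": []}
            continue
        kind = "include"
        rule = line
        if rule.startswith("-"):
            kind = "exclude"
            rule = rule[1:].strip()
        if ":" not in rule:
            raise ValidationError(f"function map line {lineno}: malformed rule {line!r}")
        rank, value = (part.strip() for part in rule.split(":", 1))
        if rank not in RANKS:
            raise ValidationError(
                f"function map line {lineno}: unknown rank {rank!r} (valid: {RANKS})"
            )
        fmap[current][kind].append((rank, value))
    for name, rules in fmap.items():
        if not rules["include"]:
            raise ValidationError(f"function {name!r} has no inclusion rules")
    return fmap


def write_function_map(fmap: dict, path: str | Path) -> None:
    lines = []
    for name, rules in fmap.items():
        lines.append(name)
        for rank, value in rules["include"]:
            lines.append(f"{rank}:{value}")
        for rank, value in rules["exclude"]:
            lines.append(f"-{rank}:{value}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------

def cross_validate(
    counts: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
    tree: TreeNode | None = None,
    traits: pd.DataFrame | None = None,
) -> dict:
    """Report taxa/samples present in the count table but missing from companions.

    Nothing is dropped here; every mismatch is returned and logged so the caller
    decides what to exclude.
    """
    report: dict[str, list[str]] = {}
    taxa = set(counts.columns)
    if metadata is not None:
        missing = sorted(set(counts.index) - set(metadata.index))
        if missing:
            report["samples_missing_metadata"] = missing
    if taxonomy is not None:
        missing = sorted(taxa - set(taxonomy.index))
        if missing:
            report["taxa_missing_taxonomy"] = missing
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = sorted(taxa - tips)
        if missing:
            report["taxa_missing_tree"] = missing
    if traits is not None:
        missing = sorted(taxa - set(traits.index))
        if missing:
            report["taxa_missing_traits"] = missing
    for key, ids in report.items():
        logger.warning("%s: %s", key, ", ".join(ids))
    return report
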